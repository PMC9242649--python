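"""Ensemble distograms of a 4-helix bundle with one mobile helix.

Generates five conformers of an ideal bundle in which helix TM3 is
rigidly displaced between conformers, computes Cβ distance matrices per
conformer, and aggregates mean / variance / normalized-variance
distograms.  The normalized variance (variance over squared mean) is
scale-free, so cells involving the moved helix stand out while pairs
within the static helices stay near zero.
"""

import numpy as np

from trpscan import (BundleSimSpec, SeqStructMap, distance_matrix,
                     distogram_stats, simulate_bundle_ensemble)

spec = BundleSimSpec(
    n_conformers=5,
    moved_helices={2: np.array([2.5, 0.0, 0.0])},   # helix index 2 == TM3
    noise_sigma=0.05,
    seed=42,
)
models, truth = simulate_bundle_ensemble(spec)
nums = [r.author_number for r in models[0].chains["A"]]
smap = SeqStructMap({k + 1: ("A", n) for k, n in enumerate(nums)})
positions = list(range(1, len(nums) + 1))
mats = [distance_matrix(m, smap, positions) for m in models]
dg = distogram_stats(mats, positions)

helix_of = {k: nums[k] // 100 for k in range(len(nums))}
nv = np.asarray(dg.norm_variance)
cells = {"static-static": [], "static-moved": []}
for i in range(len(nums)):
    for j in range(i + 1, len(nums)):
        hi, hj = helix_of[i], helix_of[j]
        if hi == hj:
            continue
        key = "static-moved" if (hi == 3) != (hj == 3) else "static-static"
        cells[key].append(nv[i, j])

print(f"{dg.n_structures} conformers, {len(positions)} positions")
print(f"mean distance range: {float(dg.mean.min()):.1f} – "
      f"{float(dg.mean.max()):.1f} Å")
for key, vals in cells.items():
    print(f"normalized variance, {key}: {np.mean(vals):.5f}")
print("(the moved helix dominates the normalized variance, as intended)")
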