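import numpy as np
import pytest

from trpscan.msa import MsaMatrix
from trpscan.synthetic import (BundleSimSpec, MsaSimSpec, SubfamilySpec,
                               simulate_bundle_ensemble, simulate_msa)


@pytest.fixture(scope="session")
def planted_msa():
    """300-row MSA with near-invariant columns and one subfamily indel."""
    spec = MsaSimSpec(
        n_seqs=300, length=80,
        conserved_columns={7: ("W", 0.97), 25: ("Φ", 0.96), 60: ("G", 0.99)},
        subfamilies=[SubfamilySpec("TRPX", 200, [(40, 49)], 0.05),
                     SubfamilySpec("TRPZ", 100, [], 0.02)],
        seed=11,
    )
    msa, truth = simulate_msa(spec)
    return msa, truth


@pytest.fixture(scope="session")
def tiny_msa():
    return MsaMatrix(
        ["s1", "s2", "s3", "s4"],
        ["GFAC", "GFA-", "GYC-", "G-CD"],
        {"s1": "A", "s2": "A", "s3": "B", "s4": "B"},
    )


@pytest.fixture(scope="session")
def bundle_ensemble():
    """5-conformer 4-helix bundle: planted aromatics, one helix displaced."""
    spec = BundleSimSpec(
        planted={(0, 8): "inward", (1, 9): "outward", (2, 7): "inward",
                 (3, 10): "inward", (0, 12): "outward"},
        n_conformers=5,
        moved_helices={3: np.array([2.5, 0.0, 0.0])},
        noise_sigma=0.05,
        seed=7,
    )
    return simulate_bundle_ensemble(spec)
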