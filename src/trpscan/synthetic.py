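"""Synthetic fixtures with planted ground truth.

Three generators, all pure functions of (spec, seed):

* structured MSAs with near-invariant (optionally Φ-class) columns,
  subfamily-specific indel blocks and controllable gap frequencies;
* MSAs Gibbs-sampled from a pairwise Potts model with planted couplings;
* coordinate ensembles of ideal 4- or 6-helix bundles with planted
  inward- or outward-pointing aromatic side chains, rigid per-conformer
  helix displacements and isotropic coordinate noise.

Each generator returns its ground truth alongside the data so downstream
tests never re-derive it.  Geometry is deliberately minimal: Cα traces on
ideal α-helices (1.5 Å rise, 100° per residue), Cβ plus a gamma
pseudo-atom and a six-atom ring template for aromatics — sufficient for
the facing test, minimal pair distances and distograms, with no
pretension of physical side-chain packing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa import AMINO_ACIDS, GAP, MsaMatrix, PHI_CLASS
from .structure import Residue, StructureModel

# --------------------------------------------------------------------------
# structured MSAs


@dataclass
class SubfamilySpec:
    label: str
    size: int
    indel_blocks: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive
    gap_level: float = 0.0


@dataclass
class MsaSimSpec:
    n_seqs: int
    length: int
    conserved_columns: dict[int, tuple[str, float]] = field(default_factory=dict)
    subfamilies: list[SubfamilySpec] = field(default_factory=list)
    background: np.ndarray | None = None   # length-20 distribution
    seed: int = 0

    def validate(self) -> None:
        if self.n_seqs < 1 or self.length < 1:
            raise ValueError("n_seqs and length must be >= 1")
        for col, (res, p) in self.conserved_columns.items():
            if not 1 <= col <= self.length:
                raise ValueError(f"conserved column {col} outside 1..{self.length}")
            if not 0 <= p <= 1:
                raise ValueError(f"conservation level {p} outside [0, 1]")
            if res != "Φ" and res not in AMINO_ACIDS:
                raise ValueError(f"unknown planted residue {res!r}")
        if self.subfamilies:
            if sum(s.size for s in self.subfamilies) != self.n_seqs:
                raise ValueError("subfamily sizes must sum to n_seqs")
            for s in self.subfamilies:
                for lo, hi in s.indel_blocks:
                    if not 1 <= lo <= hi <= self.length:
                        raise ValueError(f"indel block ({lo}, {hi}) invalid")


@dataclass
class MsaTruth:
    conserved_columns: dict[int, tuple[str, float]]
    indel_columns: dict[str, list[int]]   # subfamily → 1-based columns all-gap

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "conserved_columns": {str(k): list(v) for k, v in self.conserved_columns.items()},
            "indel_columns": self.indel_columns,
        }, ensure_ascii=False, indent=1))


def simulate_msa(spec: MsaSimSpec) -> tuple[MsaMatrix, MsaTruth]:
    """Sample an alignment with planted conserved columns and indels.

    A conserved column carries its designated residue with probability p
    (a Φ column draws Phe or Tyr with ratio 3:1) and a background residue
    otherwise; subfamily indel blocks are emitted as all-gap; remaining
    positions gap independently at the subfamily's ``gap_level``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = spec.background if spec.background is not None \
        else np.full(20, 1.0 / 20)
    bg = np.asarray(bg, dtype=float)
    bg = bg / bg.sum()
    aas = np.array(list(AMINO_ACIDS))

    subfams = spec.subfamilies or [SubfamilySpec("all", spec.n_seqs)]
    seq_ids, rows = [], []
    labels: dict[str, str] = {}
    indel_columns: dict[str, list[int]] = {}
    counter = 0
    for sf in subfams:
        blocked = sorted({c for lo, hi in sf.indel_blocks for c in range(lo, hi + 1)})
        indel_columns[sf.label] = blocked
        blocked_set = set(blocked)
        for _ in range(sf.size):
            sid = f"{sf.label}_{counter:05d}"
            counter += 1
            chars = list(rng.choice(aas, size=spec.length, p=bg))
            for col, (res, p) in spec.conserved_columns.items():
                if rng.random() < p:
                    if res == "Φ":
                        chars[col - 1] = "F" if rng.random() < 0.75 else "Y"
                    else:
                        chars[col - 1] = res
            if sf.gap_level > 0:
                gap_mask = rng.random(spec.length) < sf.gap_level
                for i in np.nonzero(gap_mask)[0]:
                    if (i + 1) not in spec.conserved_columns:
                        chars[i] = GAP
            for col in blocked_set:
                chars[col - 1] = GAP
            seq_ids.append(sid)
            rows.append("".join(chars))
            labels[sid] = sf.label
    msa = MsaMatrix(seq_ids, rows, labels if spec.subfamilies else None)
    return msa, MsaTruth(dict(spec.conserved_columns), indel_columns)


# --------------------------------------------------------------------------
# Potts-sampled MSAs


@dataclass
class PottsTruth:
    h: np.ndarray                       # (L, q)
    J: np.ndarray                       # (L, L, q, q)
    planted_pairs: list[tuple[int, int]]  # 0-based column pairs


def simulate_potts_msa(L: int, q: int, planted_pairs: list[tuple[int, int]],
                       n_seqs: int, coupling_strength: float = 1.0,
                       burn_in: int = 300, thin: int = 0, seed: int = 0,
                       field_scale: float = 0.0
                       ) -> tuple[MsaMatrix, PottsTruth]:
    """Gibbs-sample sequences from a Potts model with planted couplings.

    Each planted pair (i, j) receives a ferromagnetic coupling
    ``J_ij(a, b) = strength·(1[a = b] − 1/q)`` (zero-sum by construction);
    all other couplings are zero.  One independent chain per sequence is
    run for ``burn_in`` (+ ``thin``) full Gibbs sweeps from a uniform
    random start.  States are emitted as the first q amino-acid letters,
    so the output alignment is gap-free.
    """
    if q > 20:
        raise ValueError("q must be <= 20 (states are emitted as amino acids)")
    for i, j in planted_pairs:
        if not (0 <= i < L and 0 <= j < L and i != j):
            raise ValueError(f"invalid planted pair ({i}, {j})")
    rng = np.random.default_rng(seed)
    h = field_scale * rng.standard_normal((L, q))
    J = np.zeros((L, L, q, q))
    block = coupling_strength * (np.eye(q) - 1.0 / q)
    for i, j in planted_pairs:
        J[i, j] = block
        J[j, i] = block.T

    x = rng.integers(0, q, size=(n_seqs, L))
    n_sweeps = burn_in + thin
    for _ in range(n_sweeps):
        for i in range(L):
            logits = np.broadcast_to(h[i], (n_seqs, q)).copy()
            for j in range(L):
                if j == i or not J[i, j].any():
                    continue
                logits += J[i, j][:, x[:, j]].T
            gumbel = -np.log(-np.log(rng.random((n_seqs, q))))
            x[:, i] = np.argmax(logits + gumbel, axis=1)

    letters = np.array(list(AMINO_ACIDS[:q]))
    rows = ["".join(letters[row]) for row in x]
    ids = [f"potts_{k:05d}" for k in range(n_seqs)]
    return MsaMatrix(ids, rows), PottsTruth(h, J, list(planted_pairs))


# --------------------------------------------------------------------------
# helix-bundle ensembles

RISE_PER_RESIDUE = 1.5      # Å, ideal α-helix
TWIST_PER_RESIDUE = 100.0   # degrees
HELIX_RADIUS = 2.3          # Å, Cα radius around the helix axis
CB_OFFSET = 1.5             # Å, Cβ radially outward from the helix axis
CG_OFFSET = 2.5             # Å, planted gamma atom toward/away from bundle axis
RING_RADIUS = 1.4           # Å, aromatic ring template
RING_CENTER_OFFSET = 2.1    # Å, ring center beyond the gamma atom


@dataclass
class BundleSimSpec:
    n_helices: int = 4
    n_res_per_helix: int = 18
    bundle_radius: float = 8.5          # Å, helix axes on this circle
    planted: dict[tuple[int, int], str] = field(default_factory=dict)
    # (helix index 0-based, residue index 0-based) → "inward" | "outward"
    n_conformers: int = 1
    moved_helices: dict[int, np.ndarray] = field(default_factory=dict)
    # helix index → displacement vector applied with a per-conformer factor in [-1, 1]
    noise_sigma: float = 0.0            # Å, isotropic Gaussian on every atom
    tetramer: bool = False
    protomer_offset: float = 16.0       # Å, protomer center shift when tetramer
    seed: int = 0

    def validate(self) -> None:
        if self.n_helices not in (4, 6):
            raise ValueError("n_helices must be 4 or 6")
        if self.n_res_per_helix < 4:
            raise ValueError("need at least 4 residues per helix")
        for (hx, t), side in self.planted.items():
            if not (0 <= hx < self.n_helices and 0 <= t < self.n_res_per_helix):
                raise ValueError(f"planted residue ({hx}, {t}) out of range")
            if side not in ("inward", "outward"):
                raise ValueError(f"orientation must be inward/outward, got {side!r}")


@dataclass
class BundleTruth:
    facing: dict[tuple[str, int], bool]      # (chain, author_number) → planted inward?
    helix_ranges: dict[str, tuple[int, int]]  # TM label → residue number range
    moved_helices: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "facing": {f"{c}:{n}": v for (c, n), v in self.facing.items()},
            "helix_ranges": self.helix_ranges,
            "moved_helices": self.moved_helices,
        }, indent=1))


def _rotation_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ring_atoms(center: np.ndarray, normal_hint: np.ndarray) -> dict[str, np.ndarray]:
    """Regular pentagon-completed hexagon template for a Phe ring."""
    axis = np.array([0.0, 0.0, 1.0])
    u = normal_hint - normal_hint.dot(axis) * axis
    nu = np.linalg.norm(u)
    u = u / nu if nu > 1e-9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(axis, u)
    names = ["CD1", "CD2", "CE1", "CE2", "CZ"]
    angles = [60, -60, 120, -120, 180]
    return {
        name: center + RING_RADIUS * (math.cos(math.radians(a)) * u
                                      + math.sin(math.radians(a)) * v)
        for name, a in zip(names, angles)
    }


def _build_protomer(spec: BundleSimSpec) -> tuple[dict[int, list[Residue]],
                                                  dict[tuple[int, int], bool]]:
    """Ideal bundle protomer around the origin; returns helix → residues."""
    helices: dict[int, list[Residue]] = {}
    facing: dict[tuple[int, int], bool] = {}
    for hx in range(spec.n_helices):
        phi = 2.0 * math.pi * hx / spec.n_helices
        axis_xy = spec.bundle_radius * np.array([math.cos(phi), math.sin(phi), 0.0])
        residues = []
        for t in range(spec.n_res_per_helix):
            theta = math.radians(TWIST_PER_RESIDUE * t) + phi
            radial = np.array([math.cos(theta), math.sin(theta), 0.0])
            ca = axis_xy + HELIX_RADIUS * radial + np.array([0.0, 0.0, RISE_PER_RESIDUE * t])
            atoms = {"CA": ca, "CB": ca + CB_OFFSET * radial}
            side = spec.planted.get((hx, t))
            name = "ALA"
            if side is not None:
                inward_dir = -axis_xy / np.linalg.norm(axis_xy)  # toward bundle axis
                direction = inward_dir if side == "inward" else -inward_dir
                cg = ca + CG_OFFSET * direction
                atoms["CG"] = cg
                atoms.update(_ring_atoms(cg + RING_CENTER_OFFSET * direction, direction))
                name = "PHE"
                facing[(hx, t)] = side == "inward"
            residues.append(Residue("A", 100 * (hx + 1) + t + 1, "", name, atoms))
        helices[hx] = residues
    return helices, facing


def _check_clashes(helices: dict[int, list[Residue]]) -> None:
    cas = {hx: np.stack([r.atoms["CA"] for r in res]) for hx, res in helices.items()}
    for a in cas:
        for b in cas:
            if a >= b:
                continue
            diff = cas[a][:, None, :] - cas[b][None, :, :]
            dmin = np.sqrt((diff ** 2).sum(-1)).min()
            if dmin <= 3.0:
                raise ValueError(
                    f"helix geometry clashes: min inter-helix CA distance "
                    f"{dmin:.2f} Å between helices {a} and {b}"
                )


def simulate_bundle_ensemble(spec: BundleSimSpec
                             ) -> tuple[list[StructureModel], BundleTruth]:
    """Generate a conformational ensemble of ideal helix bundles.

    Conformer c translates each moved helix by ``factor_c · vector`` where
    the factors spread evenly over [-1, 1], then adds isotropic Gaussian
    noise of ``noise_sigma`` Å to every atom.  With ``tetramer``, the
    (noised) protomer is shifted radially and replicated by exact 4-fold
    rotation into chains A-D, so neighbor-protomer contact counts are exact
    multiples of four (opposite-protomer contact orbits have size two).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    helices, facing_idx = _build_protomer(spec)
    _check_clashes(helices)

    helix_ranges = {f"TM{hx + 1}": (100 * (hx + 1) + 1,
                                    100 * (hx + 1) + spec.n_res_per_helix)
                    for hx in range(spec.n_helices)}
    chains = ["A", "B", "C", "D"] if spec.tetramer else ["A"]
    facing = {(c, 100 * (hx + 1) + t + 1): inward
              for c in chains for (hx, t), inward in facing_idx.items()}

    if spec.n_conformers > 1:
        factors = np.linspace(-1.0, 1.0, spec.n_conformers)
    else:
        factors = np.zeros(1)

    models = []
    for c_idx in range(spec.n_conformers):
        chains_out: dict[str, list[Residue]] = {}
        protomer: list[Residue] = []
        for hx, residues in helices.items():
            shift = factors[c_idx] * np.asarray(spec.moved_helices.get(hx, np.zeros(3)))
            for res in residues:
                atoms = {n: xyz + shift + spec.noise_sigma * rng.standard_normal(3)
                         for n, xyz in res.atoms.items()}
                protomer.append(Residue("A", res.author_number, "", res.name, atoms))
        if spec.tetramer:
            offset = np.array([spec.protomer_offset, 0.0, 0.0])
            for k, chain_name in enumerate(chains):
                rot = _rotation_z(math.pi / 2 * k)
                chains_out[chain_name] = [
                    Residue(chain_name, r.author_number, "", r.name,
                            {n: rot @ (xyz + offset) for n, xyz in r.atoms.items()})
                    for r in protomer
                ]
        else:
            chains_out["A"] = protomer
        models.append(StructureModel(f"bundle_{c_idx:03d}", chains_out))
    return models, BundleTruth(facing, helix_ranges,
                               [f"TM{h + 1}" for h in spec.moved_helices])
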