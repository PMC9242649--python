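"""Aromatic-core detection and residue contacts in TM helix bundles.

Implements the core-cluster procedure: a residue on one helix of the
TM1–TM4 bundle "faces the core" when its gamma heavy atom sits closer to
the nearest opposing helix than its own alpha carbon does, i.e.
d(Cα_r, Cα_o) > d(Cγ_r, Cα_o) for the opposing residue o minimizing the
Cα–Cα distance.  Core-facing aromatics are then clustered by single
linkage on minimal all-heavy-atom pair distances with a 5 Å threshold.
A separate contact pass reports residue pairs below 4 Å (general) or 5 Å
(π–π, both residues aromatic), optionally across chains for inter-subunit
contacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .structure import Residue, StructureModel

#: residue name → gamma-position heavy atom
GAMMA_ATOM: dict[str, str] = {
    "PHE": "CG", "TYR": "CG", "TRP": "CG", "HIS": "CG",
    "LEU": "CG", "MET": "CG", "GLU": "CG", "GLN": "CG",
    "LYS": "CG", "ARG": "CG", "PRO": "CG", "ASP": "CG",
    "ASN": "CG",
    "ILE": "CG1", "VAL": "CG1",
    "SER": "OG", "THR": "OG1", "CYS": "SG",
    # ALA and GLY have no gamma atom → never core-facing
}

AROMATIC_RESIDUES_DEFAULT: frozenset[str] = frozenset({"PHE", "TYR", "TRP", "HIS"})

BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass
class HelixAnnotation:
    """Ordered residue lists per helix label for one protomer chain."""

    helices: dict[str, list[Residue]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for label, residues in self.helices.items():
            if len(residues) < 4:
                raise ValueError(f"helix {label} has fewer than 4 residues")
            keys = {r.key for r in residues}
            if keys & seen:
                raise ValueError(f"helix {label} overlaps another helix")
            seen |= keys

    @classmethod
    def from_ranges(cls, structure: StructureModel, chain: str,
                    ranges: dict[str, tuple[int, int]]) -> "HelixAnnotation":
        """Build from author-number ranges, e.g. ``{"TM1": (433, 460), ...}``."""
        residues = structure.chains.get(chain)
        if residues is None:
            raise ValueError(f"chain {chain!r} not in structure")
        helices = {}
        for label, (lo, hi) in ranges.items():
            helices[label] = [r for r in residues if lo <= r.author_number <= hi]
        return cls(helices)


@dataclass
class CoreFacingResult:
    residue: Residue
    nearest_opposing: Residue | None
    d_alpha_alpha: float
    d_alpha_gamma: float
    facing: bool
    helix: str


@dataclass
class AromaticCluster:
    members: list[Residue]
    pairwise_min_distances: dict[tuple[tuple[str, int, str], tuple[str, int, str]], float]
    threshold: float

    @property
    def size(self) -> int:
        return len(self.members)


def gamma_atom(residue: Residue) -> np.ndarray | None:
    name = GAMMA_ATOM.get(residue.name)
    if name is None:
        return None
    return residue.atoms.get(name)


def core_facing_residues(structure: StructureModel, helices: HelixAnnotation,
                         pairs: list[tuple[str, str]] | None = None
                         ) -> list[CoreFacingResult]:
    """Classify helix residues as facing the bundle core or not.

    For each residue r of helix A (against opposing helix B): find the
    residue o of B minimizing d(Cα_r, Cα_o); r faces the core iff that
    distance strictly exceeds d(Cγ_r, Cα_o).  Both orderings of each helix
    pair are evaluated (so every residue of both helices is tested against
    its opposing helix) and the union reported: a residue appearing under
    several helix pairs is facing when any direction says so.  Residues
    without a gamma atom (Gly, Ala, or missing side-chain atoms) are
    reported non-facing.
    """
    if pairs is None:
        pairs = [("TM1", "TM3"), ("TM2", "TM4")]
    directed: list[tuple[str, str]] = []
    for a, b in pairs:
        directed.append((a, b))
        directed.append((b, a))

    results: list[CoreFacingResult] = []
    for helix_a, helix_b in directed:
        if helix_a not in helices.helices or helix_b not in helices.helices:
            raise ValueError(f"missing helix annotation for pair ({helix_a}, {helix_b})")
        opposing = [r for r in helices.helices[helix_b] if "CA" in r.atoms]
        if not opposing:
            raise ValueError(f"helix {helix_b} has no residues with CA")
        opp_ca = np.stack([r.atoms["CA"] for r in opposing])
        for res in helices.helices[helix_a]:
            ca = res.atoms.get("CA")
            if ca is None:
                continue
            d_ca = np.linalg.norm(opp_ca - ca, axis=1)
            k = int(np.argmin(d_ca))
            o = opposing[k]
            d_aa = float(d_ca[k])
            cg = gamma_atom(res)
            if cg is None:
                results.append(CoreFacingResult(res, o, d_aa, np.inf, False, helix_a))
                continue
            d_ag = float(np.linalg.norm(o.atoms["CA"] - cg))
            results.append(CoreFacingResult(res, o, d_aa, d_ag, d_aa > d_ag, helix_a))
    merged: dict[tuple[str, int, str], CoreFacingResult] = {}
    for r in results:
        prev = merged.get(r.residue.key)
        if prev is None or (r.facing and not prev.facing):
            merged[r.residue.key] = r
    return list(merged.values())


def min_heavy_atom_distance(res_a: Residue, res_b: Residue,
                            side_chain_only: bool = False) -> float:
    """Minimum over all heavy-atom pairs of two residues (Å)."""
    def _atoms(res: Residue) -> np.ndarray:
        items = [xyz for name, xyz in res.atoms.items()
                 if not (side_chain_only and name in BACKBONE_ATOMS)]
        return np.stack(items) if items else np.empty((0, 3))

    a, b = _atoms(res_a), _atoms(res_b)
    if a.size == 0 or b.size == 0:
        return np.inf
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt(np.sum(diff * diff, axis=-1)).min())


def aromatic_pair_min_distances(residues: list[Residue],
                                side_chain_only: bool = False
                                ) -> dict[tuple[tuple, tuple], float]:
    """Minimal heavy-atom distance for every unordered residue pair."""
    out = {}
    for res_a, res_b in combinations(residues, 2):
        key = tuple(sorted((res_a.key, res_b.key)))
        out[key] = min_heavy_atom_distance(res_a, res_b, side_chain_only)
    return out


def cluster_aromatics(residues: list[Residue],
                      pair_distances: dict[tuple[tuple, tuple], float],
                      threshold: float = 5.0) -> list[AromaticCluster]:
    """Single-linkage clusters: connected components of the < threshold graph.

    Multi-residue clusters are returned largest-first; singletons are
    included as size-1 clusters at the end.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    by_key = {r.key: r for r in residues}
    parent = {k: k for k in by_key}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for (ka, kb), d in pair_distances.items():
        if ka in parent and kb in parent and d < threshold:
            parent[find(ka)] = find(kb)

    groups: dict[tuple, list[Residue]] = {}
    for k in by_key:
        groups.setdefault(find(k), []).append(by_key[k])

    clusters = []
    for members in groups.values():
        keys = {m.key for m in members}
        dists = {pair: d for pair, d in pair_distances.items()
                 if pair[0] in keys and pair[1] in keys}
        members = sorted(members, key=lambda r: (r.chain, r.author_number))
        clusters.append(AromaticCluster(members, dists, threshold))
    clusters.sort(key=lambda c: (-c.size, c.members[0].author_number))
    return clusters


def detect_aromatic_core(structure: StructureModel, helices: HelixAnnotation,
                         threshold: float = 5.0,
                         aromatic_set: frozenset[str] = AROMATIC_RESIDUES_DEFAULT,
                         ) -> tuple[list[AromaticCluster], list[CoreFacingResult]]:
    """Full pipeline: facing test → aromatic subset → 5 Å single linkage."""
    facing = core_facing_residues(structure, helices)
    aromatics = [r.residue for r in facing
                 if r.facing and r.residue.name in aromatic_set]
    dists = aromatic_pair_min_distances(aromatics)
    return cluster_aromatics(aromatics, dists, threshold), facing


@dataclass
class Contact:
    res_a: Residue
    res_b: Residue
    min_distance: float
    rule: str  # "general" or "pi-pi"


def residue_contacts(structure: StructureModel,
                     threshold_general: float = 4.0,
                     threshold_pipi: float = 5.0,
                     cross_chain: bool = False,
                     aromatic_set: frozenset[str] = AROMATIC_RESIDUES_DEFAULT,
                     chains: list[str] | None = None,
                     exclude_adjacent: bool = True) -> list[Contact]:
    """Residue pairs in contact by minimal heavy-atom distance.

    A pair is a contact when its minimal distance is below 4 Å, or below
    5 Å when both residues are aromatic (π–π rule, reported under the rule
    that fired with π–π taking precedence for aromatic pairs beyond 4 Å).
    ``cross_chain`` also evaluates inter-subunit pairs; otherwise pairs are
    within-chain only.  Sequence-adjacent within-chain pairs are excluded
    by default.
    """
    if threshold_general <= 0 or threshold_pipi <= 0:
        raise ValueError("thresholds must be positive")
    chain_names = chains or list(structure.chains)
    residues = [r for c in chain_names for r in structure.chains.get(c, [])]
    contacts = []
    for res_a, res_b in combinations(residues, 2):
        same_chain = res_a.chain == res_b.chain
        if not cross_chain and not same_chain:
            continue
        if exclude_adjacent and same_chain and \
                abs(res_a.author_number - res_b.author_number) <= 1:
            continue
        both_aromatic = res_a.name in aromatic_set and res_b.name in aromatic_set
        cutoff = max(threshold_general, threshold_pipi) if both_aromatic \
            else threshold_general
        d = min_heavy_atom_distance(res_a, res_b)
        if d < threshold_general:
            contacts.append(Contact(res_a, res_b, d, "general"))
        elif both_aromatic and d < threshold_pipi:
            contacts.append(Contact(res_a, res_b, d, "pi-pi"))
    return contacts
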