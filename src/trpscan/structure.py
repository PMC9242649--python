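"""Structure reading, Cβ distance matrices and ensemble distograms.

Residue–residue distances are measured between representative side-chain
anchors (Cβ, or Cα for glycine) on alignment-selected positions, producing
one P×P matrix per structure.  Across a conformational ensemble the
matrices are aggregated into a distogram: elementwise mean distance,
variance, and normalized variance (variance divided by the squared mean),
the latter highlighting variable pairs at short range.  The procedure is
superposition-free: distances are internal coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .msa import GAP, MsaMatrix

logger = logging.getLogger(__name__)


@dataclass
class Residue:
    chain: str
    author_number: int
    icode: str
    name: str
    atoms: dict[str, np.ndarray]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.author_number, self.icode)


@dataclass
class StructureModel:
    """One model of a protein structure: residues with atom coordinates."""

    structure_id: str
    chains: dict[str, list[Residue]]
    regions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def residue(self, chain: str, author_number: int, icode: str = ""
                ) -> Residue | None:
        for res in self.chains.get(chain, []):
            if res.author_number == author_number and res.icode == icode:
                return res
        return None

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())


@dataclass
class SeqStructMap:
    """Partial, bidirectionally injective map alignment column ↔ residue."""

    column_to_residue: dict[int, tuple[str, int]]

    def __post_init__(self) -> None:
        values = list(self.column_to_residue.values())
        if len(set(values)) != len(values):
            raise ValueError("sequence-structure map must be injective")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SeqStructMap":
        """Sidecar TSV with columns (column, chain, author_number)."""
        df = pd.read_csv(path, sep="\t", comment="#",
                         names=["column", "chain", "author_number"],
                         dtype={"column": int, "chain": str, "author_number": int},
                         header=None, skiprows=lambda i: i == 0 and _has_header(path))
        return cls({int(r.column): (str(r.chain), int(r.author_number))
                    for r in df.itertuples()})

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tchain\tauthor_number\n")
            for col in sorted(self.column_to_residue):
                ch, num = self.column_to_residue[col]
                fh.write(f"{col}\t{ch}\t{num}\n")


def _has_header(path: str | Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.lower().startswith("column")


@dataclass
class Distogram:
    """Ensemble distance statistics over a fixed position set."""

    positions: list[int]
    mean: np.ma.MaskedArray         # Å
    variance: np.ma.MaskedArray     # Å², population variance
    norm_variance: np.ma.MaskedArray
    n_per_cell: np.ndarray
    n_structures: int

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        P = len(self.positions)
        m_mask = np.ma.getmaskarray(self.mean)
        v_mask = np.ma.getmaskarray(self.variance)
        nv_mask = np.ma.getmaskarray(self.norm_variance)
        for i in range(P):
            for j in range(i + 1, P):
                if m_mask[i, j]:
                    continue
                rows.append((self.positions[i], self.positions[j],
                             float(self.mean[i, j]),
                             float(self.variance[i, j]) if not v_mask[i, j] else np.nan,
                             float(self.norm_variance[i, j]) if not nv_mask[i, j] else np.nan,
                             int(self.n_per_cell[i, j])))
        return pd.DataFrame(rows, columns=["pos_i", "pos_j", "mean", "variance",
                                           "norm_variance", "n"])


def read_structure(path: str | Path, model_index: int = 0,
                   structure_id: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    One model is extracted (the first by default); alternate locations are
    resolved to the highest-occupancy conformer (ties broken toward altloc
    'A'); HETATM/non-polymer residues are excluded.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if model_index >= len(st):
        raise ValueError(f"{path} has {len(st)} model(s); index {model_index} invalid")
    model = st[model_index]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and info.is_water():
                continue
            if res.het_flag == "H" and not (info is not None and info.is_amino_acid()):
                continue
            atoms: dict[str, np.ndarray] = {}
            best: dict[str, tuple[float, str]] = {}
            for atom in res:
                if atom.element == gemmi.Element("H"):
                    continue
                prev = best.get(atom.name)
                rank = (atom.occ, "" if atom.altloc in ("", "A") else atom.altloc)
                if prev is None or rank[0] > prev[0] or (rank[0] == prev[0] and rank[1] < prev[1]):
                    best[atom.name] = rank
                    atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if atoms:
                residues.append(Residue(chain.name, res.seqid.num,
                                        res.seqid.icode.strip(), res.name, atoms))
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ValueError(f"no polymer residues parsed from {path}")
    return StructureModel(structure_id or path.stem, chains)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB file via gemmi."""
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    for chain_name, residues in structure.chains.items():
        chain = gemmi.Chain(chain_name)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.author_number, res.icode or " ")
            for atom_name, xyz in res.atoms.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(atom_name[0])
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                gres.add_atom(atom)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def representative_coordinate(residue: Residue) -> np.ndarray | None:
    """Cβ coordinate; Cα for glycine; Cα fallback when Cβ is missing.

    Returns ``None`` (the residue is dropped from matrices) when neither
    atom exists.
    """
    if residue.name == "GLY":
        return residue.atoms.get("CA")
    cb = residue.atoms.get("CB")
    if cb is not None:
        return cb
    ca = residue.atoms.get("CA")
    if ca is not None:
        logger.warning("residue %s %s%d lacks CB; falling back to CA",
                       residue.name, residue.chain, residue.author_number)
    return ca


def feature_select_positions(msa: MsaMatrix, min_presence: float = 0.96,
                             region_columns: list[int] | None = None) -> list[int]:
    """Columns present (non-gap) in strictly more than ``min_presence`` of rows.

    ``region_columns`` optionally restricts the result to a knowledge-based
    set of alignment columns (e.g. transmembrane segments).
    """
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must lie in (0, 1]")
    n = msa.n_seqs
    allowed = set(region_columns) if region_columns is not None else None
    out = []
    for col in range(1, msa.length + 1):
        if allowed is not None and col not in allowed:
            continue
        presence = 1.0 - msa.column(col).count(GAP) / n
        if presence > min_presence:
            out.append(col)
    return out


def distance_matrix(structure: StructureModel, seqmap: SeqStructMap,
                    positions: list[int]) -> np.ma.MaskedArray:
    """P×P Euclidean distance matrix between representative coordinates.

    Unmapped positions (or residues lacking both Cβ and Cα) yield fully
    masked rows/columns; the matrix is symmetric with a zero diagonal.
    """
    P = len(positions)
    coords = np.full((P, 3), np.nan)
    for k, col in enumerate(positions):
        target = seqmap.column_to_residue.get(col)
        if target is None:
            continue
        res = structure.residue(target[0], target[1])
        if res is None:
            continue
        xyz = representative_coordinate(res)
        if xyz is not None:
            coords[k] = xyz
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=-1))
    mask = np.isnan(dist)
    return np.ma.MaskedArray(np.where(mask, 0.0, dist), mask=mask)


def distogram_stats(matrices: list[np.ma.MaskedArray], positions: list[int],
                    sample_variance: bool = False) -> Distogram:
    """Aggregate per-structure distance matrices into a distogram.

    Mean and (population, by default) variance are computed per cell over
    the structures where both positions are present; a cell observed in
    fewer than two structures has its variance masked.  Normalized
    variance is variance / mean² where the mean is positive (0 on the
    diagonal).
    """
    if len(matrices) < 2:
        raise ValueError("distogram_stats requires at least 2 matrices")
    P = len(positions)
    for m in matrices:
        if m.shape != (P, P):
            raise ValueError("all matrices must match the position set")
    stack = np.ma.stack(matrices)                 # (S, P, P)
    n = (~stack.mask).sum(axis=0) if stack.mask is not np.ma.nomask else \
        np.full((P, P), len(matrices))
    mean = stack.mean(axis=0)
    ddof = 1 if sample_variance else 0
    var = stack.var(axis=0, ddof=ddof)
    var = np.ma.masked_where(n < 2, var)
    mean = np.ma.masked_where(n < 1, np.ma.filled(mean, 0.0))

    denom = np.ma.filled(mean, 0.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        nv_data = np.where(denom > 0, np.ma.filled(var, 0.0) / np.where(denom > 0, denom, 1.0), 0.0)
    nv = np.ma.MaskedArray(nv_data, mask=np.ma.getmaskarray(var))
    np.fill_diagonal(nv_data, 0.0)
    return Distogram(list(positions), mean, var, nv, np.asarray(n), len(matrices))


def align_map_fallback(msa_row: str, structure: StructureModel, chain: str
                       ) -> SeqStructMap:
    """Global-alignment fallback when no sidecar map is supplied.

    Aligns the structure's one-letter sequence to the (ungapped) MSA row
    and maps matched states back to alignment columns.  Emits a warning:
    curated sidecar maps are preferred.
    """
    from Bio.Align import PairwiseAligner
    from Bio.Data.IUPACData import protein_letters_3to1

    logger.warning("deriving sequence-structure map by pairwise alignment; "
                   "supply a curated sidecar TSV when available")
    residues = structure.chains[chain]
    struct_seq = "".join(
        protein_letters_3to1.get(r.name.capitalize(), "X") for r in residues
    )
    # positions of non-gap characters in the alignment row
    col_of_index = [i + 1 for i, ch in enumerate(msa_row) if ch != GAP]
    seq = msa_row.replace(GAP, "")
    aligner = PairwiseAligner(mode="global", match_score=2,
                              mismatch_score=-1, open_gap_score=-5,
                              extend_gap_score=-0.5)
    aln = aligner.align(seq, struct_seq)[0]
    mapping: dict[int, tuple[str, int]] = {}
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for k in range(a_end - a_start):
            mapping[col_of_index[a_start + k]] = \
                (chain, residues[b_start + k].author_number)
    return SeqStructMap(mapping)
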