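"""Aligned-MSA container and per-column conservation statistics.

The central object is :class:`MsaMatrix`, a rectangular alignment over the
20-letter amino-acid alphabet plus the unknown code ``X`` and the gap ``-``.
On top of it this module computes per-column residue profiles, scans for
highly conserved positions (with optional grouping of the six-carbon
aromatics Phe/Tyr into a single Φ class), profiles gap patterns per
subfamily, and exports sequence-logo data (letter frequencies plus
information content in bits).

Columns are 1-based throughout so that published alignment coordinates can
be used directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
UNKNOWN: str = "X"
ALPHABET: frozenset[str] = frozenset(AMINO_ACIDS + UNKNOWN + GAP)

#: the Φ class: six-carbon aromatics (Trp deliberately excluded)
PHI_CLASS: frozenset[str] = frozenset("FY")

LOG2_20: float = math.log2(20.0)


@dataclass
class MsaMatrix:
    """Rectangular multiple sequence alignment.

    Parameters
    ----------
    seq_ids
        Unique identifier per row.
    rows
        Equal-length aligned sequences over ``AMINO_ACIDS + 'X' + '-'``.
    labels
        Optional map of ``seq_id`` to a subfamily tag (e.g. ``TRPV``).
    """

    seq_ids: list[str]
    rows: list[str]
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one sequence")
        if len(self.seq_ids) != len(self.rows):
            raise ValueError("seq_ids and rows must have equal length")
        if len(set(self.seq_ids)) != len(self.seq_ids):
            raise ValueError("seq_ids must be unique")
        L = len(self.rows[0])
        if L < 1:
            raise ValueError("alignment length must be >= 1")
        for sid, row in zip(self.seq_ids, self.rows):
            if len(row) != L:
                raise ValueError(
                    f"ragged alignment: record {sid!r} has length {len(row)}, expected {L}"
                )
        if self.labels is not None:
            unknown = set(self.labels) - set(self.seq_ids)
            if unknown:
                raise ValueError(f"labels reference unknown seq_ids: {sorted(unknown)}")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, col: int) -> str:
        """Return alignment column ``col`` (1-based) as a string of length N."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} outside 1..{self.length}")
        i = col - 1
        return "".join(row[i] for row in self.rows)

    def subset(self, seq_ids: Iterable[str]) -> "MsaMatrix":
        """Row subset preserving order of ``seq_ids``."""
        index = {sid: i for i, sid in enumerate(self.seq_ids)}
        ids = list(seq_ids)
        rows = [self.rows[index[sid]] for sid in ids]
        labels = None
        if self.labels is not None:
            labels = {sid: self.labels[sid] for sid in ids if sid in self.labels}
        return MsaMatrix(ids, rows, labels)


@dataclass
class ColumnProfile:
    """Residue statistics of one alignment column."""

    column_index: int
    counts: dict[str, int]
    gap_fraction: float
    consensus: str
    identity: float
    phi_identity: float


@dataclass
class ConservedPosition:
    """A column passing the conservation scan."""

    column_index: int
    consensus: str
    identity_percent: float
    class_used: str  # "exact" or "phi"


def _sanitize(seq: str, seq_id: str) -> str:
    out = []
    warned = False
    for ch in seq.upper():
        if ch in ALPHABET:
            out.append(ch)
        else:
            if not warned:
                logger.warning(
                    "record %r: character(s) outside alphabet mapped to 'X' (first: %r)",
                    seq_id, ch,
                )
                warned = True
            out.append(UNKNOWN)
    return "".join(out)


def read_msa(path: str | Path, labels: str | Path | None = None) -> MsaMatrix:
    """Read an aligned FASTA file (and optional subfamily-label sidecar TSV).

    Characters outside the alphabet are mapped to ``X`` with a logged
    warning.  A ragged alignment raises ``ValueError`` naming the offending
    record; an empty file raises ``ValueError``.
    """
    path = Path(path)
    seq_ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_ids.append(rec.id)
        rows.append(_sanitize(str(rec.seq), rec.id))
    if not rows:
        raise ValueError(f"no FASTA records found in {path}")
    label_map = read_labels(labels) if labels is not None else None
    if label_map is not None:
        label_map = {k: v for k, v in label_map.items() if k in set(seq_ids)}
    return MsaMatrix(seq_ids, rows, label_map)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (seq_id, subfamily) TSV with no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["seq_id", "subfamily"],
                     dtype=str, comment="#")
    return dict(zip(df["seq_id"], df["subfamily"]))


def write_msa(msa: MsaMatrix, path: str | Path) -> None:
    """Write the alignment back to FASTA (byte-stable round trip)."""
    records = [SeqRecord(Seq(row), id=sid, description="")
               for sid, row in zip(msa.seq_ids, msa.rows)]
    SeqIO.write(records, str(path), "fasta")


def column_profiles(msa: MsaMatrix, exclude_gaps_from_denominator: bool = False
                    ) -> list[ColumnProfile]:
    """Per-column counts, gap fraction, consensus and identity fractions.

    Identity denominators include gapped sequences by default (gaps count
    against conservation); ``exclude_gaps_from_denominator=True`` restricts
    the denominator to non-gap rows for sensitivity analysis.  ``X`` counts
    in the denominator but is never reported as consensus.
    """
    n = msa.n_seqs
    profiles = []
    for col in range(1, msa.length + 1):
        column = msa.column(col)
        counts: dict[str, int] = {}
        gaps = 0
        for ch in column:
            if ch == GAP:
                gaps += 1
            else:
                counts[ch] = counts.get(ch, 0) + 1
        denom = n if not exclude_gaps_from_denominator else max(n - gaps, 1)
        residue_counts = {a: c for a, c in counts.items() if a != UNKNOWN}
        if residue_counts:
            consensus = max(sorted(residue_counts), key=lambda a: residue_counts[a])
            identity = residue_counts[consensus] / denom
        else:
            consensus = GAP
            identity = 0.0
        phi = (counts.get("F", 0) + counts.get("Y", 0)) / denom
        profiles.append(ColumnProfile(
            column_index=col,
            counts=counts,
            gap_fraction=gaps / n,
            consensus=consensus,
            identity=identity,
            phi_identity=phi,
        ))
    return profiles


def conservation_scan(msa: MsaMatrix, threshold: float = 0.90,
                      use_phi: bool = True,
                      exclude_gaps_from_denominator: bool = False
                      ) -> list[ConservedPosition]:
    """Return columns whose identity strictly exceeds ``threshold``.

    With ``use_phi``, a column also qualifies when its combined Phe+Tyr
    fraction strictly exceeds the threshold; exact identity takes
    precedence when both criteria fire.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    out: list[ConservedPosition] = []
    for p in column_profiles(msa, exclude_gaps_from_denominator):
        if p.consensus == GAP:
            continue
        if p.identity > threshold:
            out.append(ConservedPosition(p.column_index, p.consensus,
                                         100.0 * p.identity, "exact"))
        elif use_phi and p.phi_identity > threshold:
            out.append(ConservedPosition(p.column_index, "Φ",
                                         100.0 * p.phi_identity, "phi"))
    return out


def gap_pattern_profile(msa: MsaMatrix) -> pd.DataFrame:
    """Per-subfamily gap fraction per column.

    Returns a DataFrame indexed by subfamily label with one column per
    alignment position (1-based).  Requires ``msa.labels``.
    """
    if msa.labels is None:
        raise ValueError("gap_pattern_profile requires subfamily labels")
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(msa.seq_ids):
        tag = msa.labels.get(sid)
        if tag is not None:
            groups.setdefault(tag, []).append(i)
    data = {}
    for tag, idxs in sorted(groups.items()):
        fracs = []
        for col in range(msa.length):
            gaps = sum(1 for i in idxs if msa.rows[i][col] == GAP)
            fracs.append(gaps / len(idxs))
        data[tag] = fracs
    df = pd.DataFrame.from_dict(data, orient="index",
                                columns=range(1, msa.length + 1))
    df.index.name = "subfamily"
    return df


def shannon_entropy_bits(freqs: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon entropy in bits with the 0·log 0 = 0 convention."""
    values = freqs.values() if isinstance(freqs, Mapping) else freqs
    return -sum(p * math.log2(p) for p in values if p > 0)


def export_logo_data(msa: MsaMatrix, start: int = 1, stop: int | None = None
                     ) -> pd.DataFrame:
    """Per-column letter frequencies and information content in bits.

    Frequencies are over non-gap residues and sum to 1 per column;
    information content is ``log2(20) - H`` where ``H`` is the Shannon
    entropy of the non-gap distribution.  An all-gap column yields a
    zero-information row flagged ``all_gap=True``.

    Returns a long-format DataFrame (column, residue, frequency, bits,
    all_gap); the ``bits`` and ``all_gap`` values repeat within a column.
    """
    stop = msa.length if stop is None else stop
    if not 1 <= start <= stop <= msa.length:
        raise ValueError(f"invalid column interval [{start}, {stop}]")
    records = []
    for p in column_profiles(msa):
        if not start <= p.column_index <= stop:
            continue
        total = sum(p.counts.values())
        if total == 0:
            records.append((p.column_index, GAP, 0.0, 0.0, True))
            continue
        freqs = {a: c / total for a, c in p.counts.items()}
        bits = LOG2_20 - shannon_entropy_bits(freqs)
        for a in sorted(freqs):
            records.append((p.column_index, a, freqs[a], bits, False))
    return pd.DataFrame(records,
                        columns=["column", "residue", "frequency", "bits", "all_gap"])
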