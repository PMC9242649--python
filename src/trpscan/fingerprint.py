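"""The 12-slot Group-I TRP channel fingerprint and its scoring.

The fingerprint is the ordered signature ``W F Φ G Φ Φ Φ N L I A W`` at
fixed alignment columns, where Φ denotes the six-carbon aromatic class
{Phe, Tyr}.  Sequences (or printed consensus rows) are scored slot by
slot: a slot matches when the residue is a member of the slot's allowed
set; the display character ``Φ`` is accepted on input and matches Φ slots
only; gaps never match.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .msa import MsaMatrix, PHI_CLASS

PHI_SYMBOL = "Φ"

#: (label, allowed set, alignment column, rTRPV1 position)
_DEFAULT_SLOTS = [
    ("W", "W", 81, 426),
    ("F", "F", 320, 434),
    (PHI_SYMBOL, "FY", 331, 441),
    ("G", "G", 633, 563),
    (PHI_SYMBOL, "FY", 662, 591),
    (PHI_SYMBOL, "FY", 755, 638),
    (PHI_SYMBOL, "FY", 852, 666),
    ("N", "N", 862, 676),
    ("L", "L", 864, 678),
    ("I", "I", 865, 679),
    ("A", "A", 866, 680),
    ("W", "W", 883, 697),
]


@dataclass(frozen=True)
class FingerprintSlot:
    allowed: frozenset[str]
    label: str
    align_col: int
    rtrpv1_pos: int

    @property
    def is_phi(self) -> bool:
        return self.allowed == PHI_CLASS


@dataclass(frozen=True)
class FingerprintDefinition:
    """Ordered 12-slot residue-class signature with column anchors."""

    slots: tuple[FingerprintSlot, ...]

    def __post_init__(self) -> None:
        if len(self.slots) != 12:
            raise ValueError(f"fingerprint must have exactly 12 slots, got {len(self.slots)}")
        cols = [s.align_col for s in self.slots]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("alignment columns must be strictly increasing")

    @property
    def align_cols(self) -> tuple[int, ...]:
        return tuple(s.align_col for s in self.slots)

    @property
    def signature(self) -> str:
        return " ".join(s.label for s in self.slots)

    @classmethod
    def default(cls, slot2_phi: bool = False) -> "FingerprintDefinition":
        """The canonical W F Φ G Φ Φ Φ N L I A W signature.

        ``slot2_phi`` relaxes the second slot from strict Phe to {Phe, Tyr};
        all standard scoring uses the strict default.
        """
        slots = []
        for i, (label, allowed, col, pos) in enumerate(_DEFAULT_SLOTS):
            if i == 1 and slot2_phi:
                label, allowed = PHI_SYMBOL, "FY"
            slots.append(FingerprintSlot(frozenset(allowed), label, col, pos))
        return cls(tuple(slots))

    @classmethod
    def from_json(cls, path: str | Path) -> "FingerprintDefinition":
        """Load a signature from a JSON list of 12 slot objects."""
        with open(path) as fh:
            raw = json.load(fh)
        slots = tuple(
            FingerprintSlot(frozenset(d["allowed"]), d["label"],
                            int(d["align_col"]), int(d["rtrpv1_pos"]))
            for d in raw
        )
        return cls(slots)

    def to_json(self, path: str | Path) -> None:
        raw = [{"allowed": sorted(s.allowed), "label": s.label,
                "align_col": s.align_col, "rtrpv1_pos": s.rtrpv1_pos}
               for s in self.slots]
        Path(path).write_text(json.dumps(raw, indent=1, ensure_ascii=False) + "\n")


@dataclass
class FingerprintScore:
    seq_id: str
    residues_at_slots: list[str]
    match_mask: list[bool]

    @property
    def count(self) -> int:
        return sum(self.match_mask)


def default_definition_path() -> Path:
    """Path of the shipped JSON definition (matches the default signature)."""
    return Path(str(resources.files("trpscan").joinpath("data/fingerprint_default.json")))


def score_residues(residues: Sequence[str], fp: FingerprintDefinition | None = None,
                   seq_id: str = "") -> FingerprintScore:
    """Score an explicit 12-character residue tuple against the fingerprint.

    A slot matches iff the character is in the slot's allowed set, or the
    character is the class symbol ``Φ`` and the slot is a Φ slot.  Gaps
    (``-``) never match.
    """
    fp = fp or FingerprintDefinition.default()
    if len(residues) != 12:
        raise ValueError(f"expected exactly 12 residues, got {len(residues)}")
    chars = [str(r).upper() if str(r) != PHI_SYMBOL else PHI_SYMBOL for r in residues]
    mask = []
    for ch, slot in zip(chars, fp.slots):
        if ch == PHI_SYMBOL:
            mask.append(slot.is_phi)
        else:
            mask.append(ch in slot.allowed)
    return FingerprintScore(seq_id, chars, mask)


def score_msa(msa: MsaMatrix, fp: FingerprintDefinition | None = None
              ) -> list[FingerprintScore]:
    """Score every alignment row by extracting residues at the slot columns."""
    fp = fp or FingerprintDefinition.default()
    if fp.align_cols[-1] > msa.length:
        raise ValueError(
            f"fingerprint column {fp.align_cols[-1]} exceeds alignment length {msa.length}"
        )
    idx = [c - 1 for c in fp.align_cols]
    return [
        score_residues([row[i] for i in idx], fp, seq_id=sid)
        for sid, row in zip(msa.seq_ids, msa.rows)
    ]


def census(scores: Iterable[FingerprintScore]) -> pd.DataFrame:
    """Population census over match counts k = 0..12.

    Returns a DataFrame indexed by k with columns ``fraction_eq`` (share of
    sequences with exactly k matches) and ``fraction_ge`` (share with at
    least k; non-increasing in k).
    """
    counts = [s.count for s in scores]
    if not counts:
        raise ValueError("census requires a non-empty score list")
    n = len(counts)
    rows = []
    for k in range(13):
        eq = sum(1 for c in counts if c == k) / n
        ge = sum(1 for c in counts if c >= k) / n
        rows.append((k, eq, ge))
    df = pd.DataFrame(rows, columns=["count", "fraction_eq", "fraction_ge"])
    return df.set_index("count")


def scores_to_frame(scores: Iterable[FingerprintScore]) -> pd.DataFrame:
    """Tabulate scores (seq_id, the 12 extracted residues, match count)."""
    rows = [
        {"seq_id": s.seq_id, "residues": "".join(s.residues_at_slots), "count": s.count}
        for s in scores
    ]
    return pd.DataFrame(rows)
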