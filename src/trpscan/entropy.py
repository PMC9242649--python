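"""Profile-emission estimation and entropy ranking of alignment columns.

A profile HMM's match-state emissions form a categorical (generalized
Bernoulli) distribution per column; strongly conserved columns are peaked
and therefore low-entropy.  Instead of running a full HMM builder, this
module estimates emissions directly from non-gap column counts with a
single tunable pseudocount toward a background distribution, and ranks
columns by Shannon entropy in bits.  Match columns are those with fewer
than 50% gaps, following the usual match-state convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fingerprint import FingerprintDefinition
from .msa import AMINO_ACIDS, GAP, LOG2_20, MsaMatrix

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class EmissionProfile:
    """Per-column emission distributions over the 20 amino acids."""

    match_columns: list[int]          # 1-based
    emissions: np.ndarray             # (n_columns, 20), rows sum to 1
    entropy_bits: np.ndarray          # (n_columns,)


def select_match_columns(msa: MsaMatrix, max_gap: float = 0.5) -> list[int]:
    """Columns with gap fraction strictly below ``max_gap``, ascending."""
    if not 0 < max_gap <= 1:
        raise ValueError("max_gap must lie in (0, 1]")
    n = msa.n_seqs
    out = []
    for col in range(1, msa.length + 1):
        gaps = msa.column(col).count(GAP)
        if gaps / n < max_gap:
            out.append(col)
    return out


def emission_probabilities(msa: MsaMatrix, columns: list[int],
                           pseudocount: float = 1.0,
                           weights: np.ndarray | None = None,
                           background: np.ndarray | None = None
                           ) -> EmissionProfile:
    """Estimate per-column emission probabilities over the 20 amino acids.

    ``emissions[c, a] = (weighted count of a + pseudocount * background[a])
    / (weighted non-gap total + pseudocount)``.  Gaps and unknown residues
    are excluded from the counts.  The background defaults to uniform 1/20.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if weights is None:
        weights = np.ones(msa.n_seqs)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (msa.n_seqs,):
        raise ValueError("weights must have one entry per sequence")
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)

    emissions = np.empty((len(columns), 20))
    for k, col in enumerate(columns):
        counts = np.zeros(20)
        column = msa.column(col)
        for w, ch in zip(weights, column):
            i = _AA_INDEX.get(ch)
            if i is not None:
                counts[i] += w
        total = counts.sum()
        if total == 0 and pseudocount == 0:
            raise ValueError(
                f"column {col} has no residues and pseudocount is 0: "
                "emission distribution undefined"
            )
        emissions[k] = (counts + pseudocount * background) / (total + pseudocount)

    logp = np.zeros_like(emissions)
    np.log2(emissions, out=logp, where=emissions > 0)
    entropy = -np.sum(emissions * logp, axis=1)
    return EmissionProfile(list(columns), emissions, entropy)


def entropy_scan(profile: EmissionProfile) -> pd.DataFrame:
    """Columns ranked ascending by emission entropy (bits)."""
    df = pd.DataFrame({
        "column": profile.match_columns,
        "entropy_bits": profile.entropy_bits,
    })
    return df.sort_values(["entropy_bits", "column"], kind="mergesort",
                          ignore_index=True)


def fingerprint_rank_check(scan: pd.DataFrame,
                           fp: FingerprintDefinition | None = None
                           ) -> pd.DataFrame:
    """Entropy percentile of each fingerprint slot among match columns.

    The percentile is the fraction of match columns with entropy strictly
    below the slot's (0 = most conserved).  A fingerprint column absent
    from the match set is flagged ``in_match_columns=False`` with NaN
    percentile rather than raising.
    """
    fp = fp or FingerprintDefinition.default()
    entropies = scan.set_index("column")["entropy_bits"]
    values = entropies.to_numpy()
    rows = []
    for slot in fp.slots:
        col = slot.align_col
        if col in entropies.index:
            h = float(entropies.loc[col])
            pct = float(np.mean(values < h))
            rows.append((col, slot.label, h, pct, True))
        else:
            rows.append((col, slot.label, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["align_col", "label", "entropy_bits",
                                       "percentile", "in_match_columns"])


def entropy_table(msa: MsaMatrix, max_gap: float = 0.5, pseudocount: float = 1.0,
                  weights: np.ndarray | None = None) -> pd.DataFrame:
    """One-call summary: column, consensus, gap fraction, entropy, percentile."""
    from .msa import column_profiles

    cols = select_match_columns(msa, max_gap)
    prof = emission_probabilities(msa, cols, pseudocount, weights)
    by_col = {p.column_index: p for p in column_profiles(msa)}
    h = prof.entropy_bits
    order = np.argsort(np.argsort(h, kind="mergesort"), kind="mergesort")
    pct = order / max(len(h) - 1, 1)
    rows = [
        (c, by_col[c].consensus, by_col[c].gap_fraction, float(h[k]), float(pct[k]))
        for k, c in enumerate(cols)
    ]
    return pd.DataFrame(rows, columns=["column", "consensus", "gap_fraction",
                                       "entropy_bits", "percentile"])
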