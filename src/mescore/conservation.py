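"""Shenkin diversity and within-family conservation classes.

The Shenkin score of an alignment column is V = 6 * 2**H, where H is the
Shannon entropy (bits) of the column's residue composition. A monomorphic
column scores 6; a column with all twenty amino acids equally represented
scores 120. Because the score's absolute range depends on alignment depth,
classification is relative: each column gets a percent rank of its score
within the family, and columns at or above the threshold (default: the 50%
most diverse) are *unconserved*, the rest *conserved*.

Gaps are excluded from the composition by default, so the score reflects
amino-acid diversity among the residues actually present; an alternative
mode counts the gap as a 21st symbol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .msa_io import GAP_CHARS, DomainAlignment, column_residues

SHENKIN_MIN = 6.0
SHENKIN_MAX = 120.0


@dataclass(frozen=True)
class ColumnConservation:
    column: int
    shenkin: float  # NaN for all-gap columns
    normalised_shenkin: float
    percent_rank: float
    conservation_class: str  # "conserved" | "unconserved" | "unranked"


def shenkin_score(column_residues: Iterable[str], count_gaps: bool = False) -> float:
    """Shenkin diversity 6 * 2**H of a column's residue multiset.

    Returns NaN for an empty (all-gap) column; such columns are excluded
    from ranking. With ``count_gaps`` the gap is a 21st symbol.
    """
    counts: dict[str, int] = {}
    for ch in column_residues:
        ch = ch.upper()
        if ch in GAP_CHARS:
            if not count_gaps:
                continue
            ch = "-"
        counts[ch] = counts.get(ch, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return math.nan
    h = 0.0
    for n in counts.values():
        p = n / total
        h -= p * math.log2(p)
    return 6.0 * 2.0**h


def normalised_shenkin(v: float) -> float:
    """Map V from [6, 120] to a 0-100 scale (plotting aid only)."""
    return (v - SHENKIN_MIN) / (SHENKIN_MAX - SHENKIN_MIN) * 100.0


def percent_ranks(scores: Sequence[float]) -> np.ndarray:
    """Percent rank of each score within the family, ties resolved high.

    rank(s) = 100 * (#{scores <= s} - 1) / n over the non-NaN scores, so a
    tied block shares the rank of its highest member and the single most
    diverse column ranks 100 * (n-1)/n. NaN scores get NaN ranks.
    """
    arr = np.asarray(scores, dtype=float)
    out = np.full(arr.shape, np.nan)
    valid = ~np.isnan(arr)
    vals = arr[valid]
    n = vals.size
    if n == 0:
        return out
    le_counts = np.array([(vals <= v).sum() for v in vals], dtype=float)
    out[valid] = 100.0 * (le_counts - 1.0) / n
    return out


def rank_and_classify(
    scores: Sequence[float], threshold_percent: float = 50.0
) -> list[ColumnConservation]:
    """Rank Shenkin scores within a family and assign conservation classes.

    Columns with percent rank >= ``threshold_percent`` are unconserved,
    the rest conserved. All-gap (NaN) columns come back "unranked".
    Requires at least two scored columns.
    """
    arr = np.asarray(scores, dtype=float)
    if (~np.isnan(arr)).sum() < 2:
        raise ValueError("need at least two scored columns to rank within a family")
    ranks = percent_ranks(arr)
    out = []
    for i, (v, r) in enumerate(zip(arr, ranks), start=1):
        if math.isnan(v):
            cls = "unranked"
        elif r >= threshold_percent:
            cls = "unconserved"
        else:
            cls = "conserved"
        out.append(
            ColumnConservation(
                column=i,
                shenkin=float(v),
                normalised_shenkin=normalised_shenkin(v) if not math.isnan(v) else math.nan,
                percent_rank=float(r),
                conservation_class=cls,
            )
        )
    return out


def top_n_conserved(scores: Sequence[float], n: int) -> set[int]:
    """The n most conserved columns (lowest Shenkin), ties to the lower index.

    This gives a within-family conserved set whose size matches an external
    count (e.g. the family's number of missense-depleted columns), the
    rank-matched alternative to a fixed score cutoff.
    """
    arr = np.asarray(scores, dtype=float)
    scored = [(v, i + 1) for i, v in enumerate(arr) if not math.isnan(v)]
    if n < 0 or n > len(scored):
        raise ValueError(f"n must be in [0, {len(scored)}], got {n}")
    scored.sort()
    return {col for _, col in scored[:n]}


def profile_alignment(
    alignment: DomainAlignment,
    threshold_percent: float = 50.0,
    count_gaps: bool = False,
) -> list[ColumnConservation]:
    """Per-column Shenkin profile of an alignment, over all sequences."""
    scores = [
        shenkin_score(column_residues(alignment, col), count_gaps=count_gaps)
        for col in range(1, alignment.n_columns + 1)
    ]
    return rank_and_classify(scores, threshold_percent)


def profile_frame(profile: Sequence[ColumnConservation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "column": [c.column for c in profile],
            "shenkin": [c.shenkin for c in profile],
            "normalised_shenkin": [c.normalised_shenkin for c in profile],
            "percent_rank": [c.percent_rank for c in profile],
            "conservation_class": [c.conservation_class for c in profile],
        }
    )
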