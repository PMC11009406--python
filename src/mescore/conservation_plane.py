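"""The conservation plane: crossing evolutionary and population constraint.

Each alignment column has a conservation class (conserved / unconserved,
from the within-family Shenkin percent rank) and a missense-constraint call
(depleted / enriched / neutral, from the MES). Their cross gives six site
categories:

    CMD  conserved,   missense depleted     UMD  unconserved, depleted
    CME  conserved,   missense enriched     UME  unconserved, enriched
    CMN  conserved,   missense neutral      UMN  unconserved, neutral

Concordant CMD and UME sites reflect the overall correlation between
evolutionary and population variation; the discordant UMD class is the
candidate pool for specificity-determining positions, and CME for sites
polymorphic in human despite family-wide conservation. Columns lacking
either input are reported as "unclassified" rather than dropped.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

CATEGORIES = ("CMD", "CME", "CMN", "UMD", "UME", "UMN")

_GRID = {
    ("conserved", "depleted"): "CMD",
    ("conserved", "enriched"): "CME",
    ("conserved", "neutral"): "CMN",
    ("unconserved", "depleted"): "UMD",
    ("unconserved", "enriched"): "UME",
    ("unconserved", "neutral"): "UMN",
}


def classify_site(conservation_class: str | None, mes_call: str | None) -> str:
    """One of the six categories, or "unclassified" when either input is missing."""
    key = (conservation_class, mes_call)
    if key in _GRID:
        return _GRID[key]
    return "unclassified"


def classify_columns(
    conservation_classes: Mapping[int, str],
    mes_calls: Mapping[int, str],
    columns: Sequence[int],
) -> dict[int, str]:
    return {
        col: classify_site(conservation_classes.get(col), mes_calls.get(col))
        for col in columns
    }


def category_summary(
    categories: Mapping[int, str],
    occupancy_human: Mapping[int, int],
) -> pd.DataFrame:
    """Site- and residue-level counts and proportions per category.

    Residue counts weight each column by its human occupancy, so deep
    columns contribute more residues than shallow ones; site and residue
    proportions therefore generally differ.
    """
    labels = list(CATEGORIES) + ["unclassified"]
    sites = {lab: 0 for lab in labels}
    residues = {lab: 0 for lab in labels}
    for col, cat in categories.items():
        sites[cat] += 1
        residues[cat] += int(occupancy_human.get(col, 0))
    total_sites = sum(sites.values())
    total_residues = sum(residues.values())
    return pd.DataFrame(
        {
            "category": labels,
            "n_sites": [sites[lab] for lab in labels],
            "prop_sites": [
                sites[lab] / total_sites if total_sites else 0.0 for lab in labels
            ],
            "n_residues": [residues[lab] for lab in labels],
            "prop_residues": [
                residues[lab] / total_residues if total_residues else 0.0
                for lab in labels
            ],
        }
    )
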