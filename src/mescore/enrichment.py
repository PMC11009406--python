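"""Feature-enrichment statistics over site classes.

Given a set of alignment columns (sites), a site class (e.g. the missense
depleted columns, or a conservation-plane category) and a binary structural
or clinical feature (ligand contact, domain contact, pathogenic variant), a
2x2 table of feature presence vs class membership is built — optionally
within one solvent-exposure stratum — and summarised with an odds ratio,
a two-sided Fisher's exact p-value and a 95% confidence interval. The
default interval is the conditional exact (test-inversion) interval that R's
``fisher.test`` reports; a Woolf log-OR normal approximation is available
for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .mes import (
    ContingencyTable,
    conditional_exact_ci,
    conditional_mle_odds_ratio,
    fisher_two_sided,
    sample_odds_ratio,
)


@dataclass(frozen=True)
class EnrichmentResult:
    stratum: str  # exposure class or "all"
    site_class: str
    feature: str
    table: ContingencyTable | None
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    estimable: bool = True


def woolf_ci(table: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Woolf (log-OR normal) interval with Haldane-Anscombe 0.5 correction."""
    a, b, c, d = (v + 0.5 for v in table.as_tuple())
    z = norm.ppf(0.5 + level / 2.0)
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def enrich(
    feature_flags,
    class_membership,
    stratum_mask=None,
    stratum: str = "all",
    site_class: str = "class",
    feature: str = "feature",
    estimator: str = "conditional_mle",
    ci_method: str = "conditional_exact",
) -> EnrichmentResult:
    """Enrichment of a boolean feature within a boolean site class.

    ``feature_flags`` and ``class_membership`` are per-site booleans;
    ``stratum_mask`` restricts the universe (e.g. to surface sites). The
    table is (feature+/feature-) x (in-class/out-of-class). A stratum with
    an empty margin yields an inestimable result rather than a statistic.
    """
    f = np.asarray(feature_flags, dtype=bool)
    m = np.asarray(class_membership, dtype=bool)
    if f.shape != m.shape:
        raise ValueError("feature and class vectors must have the same length")
    if stratum_mask is not None:
        keep = np.asarray(stratum_mask, dtype=bool)
        f, m = f[keep], m[keep]
    a = int((f & m).sum())
    b = int((f & ~m).sum())
    c = int((~f & m).sum())
    d = int((~f & ~m).sum())
    table = ContingencyTable(a=a, b=b, c=c, d=d)
    if f.size == 0 or (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return EnrichmentResult(
            stratum=stratum, site_class=site_class, feature=feature,
            table=table if f.size else None,
            odds_ratio=math.nan, ci_low=math.nan, ci_high=math.nan,
            p_value=math.nan, estimable=False,
        )
    if estimator == "sample":
        or_ = sample_odds_ratio(table)
    else:
        or_ = conditional_mle_odds_ratio(table)
    if ci_method == "woolf":
        ci_low, ci_high = woolf_ci(table)
    else:
        ci_low, ci_high = conditional_exact_ci(table)
    return EnrichmentResult(
        stratum=stratum,
        site_class=site_class,
        feature=feature,
        table=table,
        odds_ratio=or_,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=fisher_two_sided(table),
    )


def pathogenic_proportion(n_pathogenic: int, n_population: int) -> float:
    """Pathogenic-to-population variant percentage, to one decimal place."""
    if n_population <= 0:
        return math.nan
    return round(100.0 * n_pathogenic / n_population, 1)


def enrichment_frame(results) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    rows = []
    for r in results:
        t = r.table.as_tuple() if r.table else (None,) * 4
        rows.append(
            {
                "stratum": r.stratum,
                "site_class": r.site_class,
                "feature": r.feature,
                "a": t[0], "b": t[1], "c": t[2], "d": t[3],
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "estimable": r.estimable,
            }
        )
    return pd.DataFrame(rows)
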