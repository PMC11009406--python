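"""Per-domain regression of column missense totals on occupancy and diversity.

The model, fitted independently for each family with ordinary least squares
and no intercept, is

    sum_missense = beta1 * n_human + beta12 * n_human * V_Shenkin

beta1 is the family's average number of missense variants per human residue;
beta12 measures how sensitive that rate is to evolutionary divergence (a
positive beta12 means divergent columns carry more variants per residue).
Columns with no human residues contribute no information and are dropped
before fitting. beta12 p-values are adjusted across families with the
Benjamini-Hochberg step-up FDR procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


class SingularModelError(ValueError):
    """Raised when the two regressors are collinear (e.g. constant diversity)."""


@dataclass(frozen=True)
class RegressionInput:
    """Per-column data for one family."""

    sum_missense: tuple[float, ...]
    n_human: tuple[int, ...]
    v_shenkin: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.sum_missense) == len(self.n_human) == len(self.v_shenkin)):
            raise ValueError("per-column vectors must have equal length")
        if any(n < 0 for n in self.n_human):
            raise ValueError("n_human must be nonnegative")


@dataclass(frozen=True)
class RegressionResult:
    family_id: str
    beta1: float
    beta12: float
    p_beta1: float
    p_beta12: float
    n_columns_used: int
    fdr_beta12: float = float("nan")


def fit_domain(data: RegressionInput, family_id: str = "") -> RegressionResult:
    """No-intercept OLS of sum_missense on (n_human, n_human * V_Shenkin)."""
    y = np.asarray(data.sum_missense, dtype=float)
    n = np.asarray(data.n_human, dtype=float)
    v = np.asarray(data.v_shenkin, dtype=float)
    keep = (n > 0) & ~np.isnan(v)
    y, n, v = y[keep], n[keep], v[keep]
    if y.size < 3:
        raise ValueError(f"need >= 3 columns with human residues, got {y.size}")
    X = np.column_stack([n, n * v])
    if np.linalg.matrix_rank(X) < 2:
        raise SingularModelError(
            "regressors are collinear (constant V_Shenkin across columns?); "
            "the divergence term cannot be identified"
        )
    model = sm.OLS(y, X).fit()
    return RegressionResult(
        family_id=family_id,
        beta1=float(model.params[0]),
        beta12=float(model.params[1]),
        p_beta1=float(model.pvalues[0]),
        p_beta12=float(model.pvalues[1]),
        n_columns_used=int(y.size),
    )


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_families(inputs: dict[str, RegressionInput]) -> pd.DataFrame:
    """Fit every family and BH-adjust the beta12 p-values across families."""
    results = [fit_domain(data, family_id=fam) for fam, data in inputs.items()]
    fdr = adjust_fdr([r.p_beta12 for r in results])
    return pd.DataFrame(
        {
            "family_id": [r.family_id for r in results],
            "beta1": [r.beta1 for r in results],
            "beta12": [r.beta12 for r in results],
            "p_beta1": [r.p_beta1 for r in results],
            "p_beta12": [r.p_beta12 for r in results],
            "fdr_beta12": fdr,
            "n_columns_used": [r.n_columns_used for r in results],
        }
    )
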