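"""The Missense Enrichment Score (MES): per-column population constraint.

For each alignment column x a 2x2 table is built:

    a  variants mapped to column x        b  variants in all other columns
    c  human residues in column x         d  human residues elsewhere

The odds ratio compares the column's missense-per-human-residue rate with the
rest of the domain (OR > 1: more variants than the domain average; OR < 1:
fewer). Significance comes from the two-sided Fisher's exact test, with the
minimum-likelihood summation convention: the p-value is the sum of
hypergeometric point probabilities, at fixed margins, over all tables at most
as probable as the observed one (relative tolerance 1 + 1e-7, so that exactly
tied probabilities on the opposite tail are always included).

Columns with p below the threshold (default 0.1) are called *depleted*
(OR < 1) or *enriched* (OR > 1); the rest are *neutral*. No multiple-testing
correction is applied across the columns of one family: the column tests
share the same margins and are strongly interdependent (in a two-column
domain the two odds ratios are exact reciprocals and the p-values identical),
which violates the premises of standard corrections.

Two odds-ratio estimators are provided. ``sample`` is (a*d)/(b*c). The
default, ``conditional_mle``, maximises the Fisher noncentral hypergeometric
likelihood conditioned on the margins, matching the estimate printed by R's
``fisher.test``. Either way, a column with no variants has MES = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .variant_map import ColumnVariantCounts

_REL_TOL = 1.0 + 1e-7

Estimator = Literal["sample", "conditional_mle"]
Call = Literal["depleted", "enriched", "neutral"]


class UnscorableColumn(ValueError):
    """Raised when a column's 2x2 table is degenerate (no human residues)."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table (a, b | c, d); see module docstring for cell meanings."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    @property
    def scorable(self) -> bool:
        return self.c > 0

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class MesConfig:
    """Thresholds and estimator choices for scoring a domain."""

    estimator: Estimator = "conditional_mle"
    p_threshold: float = 0.1
    variant_kind: Literal["missense", "synonymous"] = "missense"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError(f"p_threshold must be in (0, 1), got {self.p_threshold}")


@dataclass(frozen=True)
class MesResult:
    column: int
    table: ContingencyTable
    mes: float
    p_value: float
    call: Call
    estimator: Estimator


def build_table(
    counts: ColumnVariantCounts,
    domain_totals: tuple[int, int],
    variant_kind: Literal["missense", "synonymous"] = "missense",
) -> ContingencyTable:
    """Build the column-vs-rest 2x2 table from per-column tallies.

    ``domain_totals`` is (total variants of the chosen kind, total human
    residues) over the whole domain.
    """
    total_variants, total_residues = domain_totals
    a = counts.n_missense if variant_kind == "missense" else counts.n_synonymous
    c = counts.n_human_residues
    if a > total_variants or c > total_residues:
        raise ValueError(
            f"column {counts.column}: column counts ({a}, {c}) exceed domain totals "
            f"({total_variants}, {total_residues})"
        )
    return ContingencyTable(a=a, b=total_variants - a, c=c, d=total_residues - c)


def _canonical(t: ContingencyTable) -> tuple[int, int, int, int]:
    """Orientation-invariant representative of the table.

    Row swaps, column swaps and transposition all preserve the Fisher
    p-value; computing on a canonical representative makes that invariance
    exact in floating point (e.g. the two columns of a two-site domain get
    bit-identical p-values).
    """
    a, b, c, d = t.as_tuple()
    forms = [
        (a, b, c, d), (b, a, d, c), (c, d, a, b), (d, c, b, a),
        (a, c, b, d), (c, a, d, b), (b, d, a, c), (d, b, c, a),
    ]
    return min(forms)


def _log_support_pmf(a: int, b: int, c: int, d: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Log hypergeometric pmf over the support of cell `a` at fixed margins.

    Returns (support values, log pmf, index of observed a).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    logpmf -= logsumexp(logpmf)  # renormalise to tame rounding on long supports
    return ks, logpmf, a - lo


def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p by minimum-likelihood summation.

    Degenerate tables (an all-zero row or column) have p = 1.
    """
    a, b, c, d = _canonical(table)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    ks, logpmf, i_obs = _log_support_pmf(a, b, c, d)
    pmf = np.exp(logpmf)
    p = float(pmf[pmf <= pmf[i_obs] * _REL_TOL].sum())
    return min(p, 1.0)


def sample_odds_ratio(table: ContingencyTable) -> float:
    """(a*d)/(b*c), with a = 0 giving 0 and a zero denominator giving +inf."""
    a, b, c, d = table.as_tuple()
    if a == 0:
        return 0.0
    if b * c == 0:
        return math.inf
    return (a * d) / (b * c)


def _conditional_mean(log_psi: float, ks: np.ndarray, log_coeff: np.ndarray) -> float:
    logw = log_coeff + ks * log_psi
    w = np.exp(logw - logw.max())
    return float((ks * w).sum() / w.sum())


def conditional_mle_odds_ratio(table: ContingencyTable) -> float:
    """Conditional maximum-likelihood odds ratio (R ``fisher.test`` estimate).

    Maximises the Fisher noncentral hypergeometric likelihood of cell `a`
    given the margins; the maximiser solves E[A | psi] = a, with psi = 0 when
    `a` sits at the lower end of its support and +inf at the upper end.
    """
    a, b, c, d = table.as_tuple()
    r1, r2 = a + b, c + d
    c1 = a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    if lo == hi:
        return math.nan  # margins fix the table; the OR is unidentified
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf
    ks = np.arange(lo, hi + 1)
    log_coeff = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
    )

    def mean_gap(log_psi: float) -> float:
        return _conditional_mean(log_psi, ks, log_coeff) - a

    span = 1.0
    while mean_gap(-span) > 0 or mean_gap(span) < 0:
        span *= 2.0
        if span > 700:  # conditional mean saturates; treat as boundary
            return 0.0 if mean_gap(0.0) > 0 else math.inf
    log_psi = brentq(mean_gap, -span, span, xtol=1e-12, rtol=8.9e-16)
    return math.exp(log_psi)


def conditional_exact_ci(table: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Exact conditional CI for the odds ratio by tail-probability inversion."""
    a, b, c, d = table.as_tuple()
    r1, r2 = a + b, c + d
    c1 = a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    alpha = (1.0 - level) / 2.0
    if lo == hi:
        return (0.0, math.inf)
    ks = np.arange(lo, hi + 1)
    log_coeff = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
    )

    def upper_tail(log_psi: float) -> float:  # P(A >= a | psi)
        logw = log_coeff + ks * log_psi
        logw -= logsumexp(logw)
        return float(np.exp(logsumexp(logw[ks >= a])))

    def lower_tail(log_psi: float) -> float:  # P(A <= a | psi)
        logw = log_coeff + ks * log_psi
        logw -= logsumexp(logw)
        return float(np.exp(logsumexp(logw[ks <= a])))

    def solve(f, target) -> float:
        g = lambda x: f(x) - target
        span = 1.0
        while g(-span) * g(span) > 0:
            span *= 2.0
            if span > 700:
                return math.copysign(math.inf, span)
        return brentq(g, -span, span, xtol=1e-10)

    ci_low = 0.0 if a == lo else math.exp(solve(upper_tail, alpha))
    ci_high = math.inf if a == hi else math.exp(solve(lower_tail, alpha))
    return (ci_low, ci_high)


def odds_ratio(table: ContingencyTable, estimator: Estimator = "conditional_mle") -> float:
    if not table.scorable:
        raise UnscorableColumn(f"table {table.as_tuple()} has no human residues (c = 0)")
    if estimator == "sample":
        return sample_odds_ratio(table)
    if estimator == "conditional_mle":
        if table.a == 0:
            return 0.0
        return conditional_mle_odds_ratio(table)
    raise ValueError(f"unknown estimator: {estimator!r}")


def classify(mes: float, p_value: float, p_threshold: float = 0.1) -> Call:
    """Depleted / enriched / neutral call from the OR and p-value."""
    if p_value >= p_threshold or mes == 1.0 or math.isnan(mes):
        return "neutral"
    return "depleted" if mes < 1.0 else "enriched"


def score_column(
    counts: ColumnVariantCounts,
    domain_totals: tuple[int, int],
    config: MesConfig = MesConfig(),
) -> MesResult:
    table = build_table(counts, domain_totals, config.variant_kind)
    if not table.scorable:
        raise UnscorableColumn(f"column {counts.column} has no human residues")
    p = fisher_two_sided(table)
    or_ = odds_ratio(table, config.estimator)
    return MesResult(
        column=counts.column,
        table=table,
        mes=or_,
        p_value=p,
        call=classify(or_, p, config.p_threshold),
        estimator=config.estimator,
    )


def score_domain(
    tallies: Sequence[ColumnVariantCounts],
    config: MesConfig = MesConfig(),
) -> tuple[list[MesResult], list[int]]:
    """Score every scorable column of a domain.

    Returns (results, unscorable column indices). Columns with no human
    residues cannot form a valid table and are reported rather than scored.
    Requires at least two scorable columns, otherwise there is no "rest of
    the domain" to compare against.
    """
    scorable = [t for t in tallies if t.n_human_residues > 0]
    unscorable = [t.column for t in tallies if t.n_human_residues == 0]
    if len(scorable) < 2:
        raise ValueError(
            f"need >= 2 scorable columns, got {len(scorable)} "
            f"({len(unscorable)} columns without human residues)"
        )
    kind = config.variant_kind
    total_var = sum(
        (t.n_missense if kind == "missense" else t.n_synonymous) for t in scorable
    )
    total_res = sum(t.n_human_residues for t in scorable)
    results = [score_column(t, (total_var, total_res), config) for t in scorable]
    return results, unscorable


def results_frame(results: Iterable[MesResult]):
    """Long-format DataFrame of MES results (inf serialised as 'inf' on write)."""
    import pandas as pd

    rows = [
        {
            "column": r.column,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "mes": r.mes,
            "p_value": r.p_value,
            "call": r.call,
            "estimator": r.estimator,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
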