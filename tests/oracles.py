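"""Independent reference implementations used only to check the package.

These deliberately share no code with :mod:`mescore`: the Fisher p-value is
an exact-integer hypergeometric enumeration, and the conditional odds-ratio
MLE is a direct numeric maximisation of scipy's noncentral hypergeometric
log-likelihood.
"""

from __future__ import annotations

import math
from fractions import Fraction


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration in exact integer arithmetic.

    The pmf numerators C(r1, k) * C(r2, c1 - k) share the denominator
    C(n, c1), so the minimum-likelihood rule pmf_k <= pmf_obs * (1 + 1e-7)
    becomes the exact integer comparison num_k * 10^7 <= num_obs * (10^7 + 1).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    num_obs = nums[a - lo]
    total = sum(nums)
    kept = sum(v for v in nums if v * 10_000_000 <= num_obs * 10_000_001)
    return float(Fraction(kept, total))


def conditional_mle_maximisation(a: int, b: int, c: int, d: int) -> float:
    """Conditional odds-ratio MLE by direct likelihood maximisation.

    Coarse grid over log psi, then Brent refinement of scipy's
    nchypergeom_fisher log-pmf. Boundary cases return 0 / inf.
    """
    import numpy as np
    from scipy.optimize import minimize_scalar
    from scipy.stats import nchypergeom_fisher

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if lo == hi:
        return math.nan
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf

    def negll(log_psi: float) -> float:
        return -nchypergeom_fisher.logpmf(a, n, c1, r1, math.exp(log_psi))

    grid = np.linspace(-15, 15, 241)
    vals = [negll(x) for x in grid]
    i = int(np.argmin(vals))
    lo_b, hi_b = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(negll, bracket=(lo_b, grid[i], hi_b), method="brent",
                          options={"xtol": 1e-14})
    return math.exp(res.x)


def bh_adjust(p_values):
    """Benjamini-Hochberg by the direct formula min_{j >= i} p_(j) * m / j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = math.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        adjusted[i] = min(running_min, 1.0)
    return adjusted
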