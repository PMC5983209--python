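"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and libraries) they are checking:
the Fisher oracle enumerates hypergeometric tables with exact integer
binomial weights, and the OLS oracle solves the normal equations by hand.
"""

from fractions import Fraction
from math import comb


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full enumeration over fixed margins.

    Sum-of-small-p's convention: total probability of all tables (with the
    observed margins) whose hypergeometric probability is at most the
    observed table's.  Exact integer weights, so ties are exact.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    numer = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(numer, total))


def ols_closed_form(x, y):
    """Slope, intercept, and R^2 from the normal equations, no library calls."""
    n = len(x)
    mean_x = sum(x) / n
    mean_y = sum(y) / n
    sxx = sum((xi - mean_x) ** 2 for xi in x)
    sxy = sum((xi - mean_x) * (yi - mean_y) for xi, yi in zip(x, y))
    syy = sum((yi - mean_y) ** 2 for yi in y)
    slope = sxy / sxx
    intercept = mean_y - slope * mean_x
    r_squared = (sxy * sxy) / (sxx * syy) if syy > 0 else 1.0
    return slope, intercept, r_squared
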