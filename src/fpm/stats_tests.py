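"""Exact binomial sign test, two-cell chi-squared goodness of fit, Z scores.

These two tests carry the headline significance claims, so they are
implemented from first principles here (exact pmf summation, explicit
two-term chi-squared) rather than delegated; scipy supplies only the
chi-squared survival function for the p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.stats import chi2 as chi2_dist


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: int | None = None
    detail: dict = field(default_factory=dict)


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> TestResult:
    """Exact two-sided binomial test by tail doubling.

    p = min(1, 2 * min(P[X <= k], P[X >= k])) under Binomial(n, p0), summed
    exactly from the pmf. At p0 = 0.5 (the only case used here) tail
    doubling coincides with the sum-of-less-probable-outcomes convention by
    symmetry.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be strictly between 0 and 1")
    pmf = [comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)]
    lower = sum(pmf[: k + 1])
    upper = sum(pmf[k:])
    p = min(1.0, 2.0 * min(lower, upper))
    return TestResult(float(k), p, None, {"k": k, "n": n, "p0": p0})


def chi2_gof_two_cell(observed: int, expected: float, total: int) -> TestResult:
    """Two-cell goodness of fit: observed vs expected within a known total.

    chi2 = (O-E)^2/E + (O-E)^2/(T-E), df = 1, no continuity correction.
    """
    if not 0 < expected < total:
        raise ValueError("expected must lie strictly between 0 and total")
    d = observed - expected
    stat = d * d / expected + d * d / (total - expected)
    p = float(chi2_dist.sf(stat, df=1))
    return TestResult(float(stat), p, 1, {"observed": observed, "expected": expected, "total": total})


def z_normalize(values) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (ddof = 1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return (x - x.mean()) / sd
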