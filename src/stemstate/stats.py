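"""Large-sample Z-tests and significance labels for timepoint comparisons.

With 150-300 cells per condition the normal approximation is appropriate,
so differences in feature means (e.g. a2 peak, mean lipid grey value) and
in cluster proportions between induction days are tested with two-sided
Z-tests.  Labels follow the usual convention (NS, *, **, ***); no
multiple-testing correction is applied, which is noted as a limitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import isinf, sqrt

from scipy.stats import norm

__all__ = [
    "ZTestResult",
    "ztest_two_means",
    "ztest_two_proportions",
    "significance_labels",
    "LARGE_SAMPLE_N",
]

#: below this group size the large-sample approximation is shaky
LARGE_SAMPLE_N = 30


@dataclass(frozen=True)
class ZTestResult:
    statistic: float
    p_value: float
    test_kind: str  # "two_mean" | "two_proportion"
    n1: int
    n2: int
    infinite_z: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def _two_sided_p(z: float) -> float:
    return float(2.0 * norm.sf(abs(z)))


def _warn_small(n1: int, n2: int) -> None:
    if n1 < LARGE_SAMPLE_N or n2 < LARGE_SAMPLE_N:
        warnings.warn(
            f"group sizes ({n1}, {n2}) below the large-sample rule of thumb "
            f"({LARGE_SAMPLE_N}); the normal approximation may be poor",
            stacklevel=3,
        )


def ztest_two_means(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> ZTestResult:
    """Two-sided Z-test for a difference of means from summary statistics.

    z = (mean1 - mean2) / sqrt(sd1^2/n1 + sd2^2/n2); with both variances
    zero the test degenerates: equal means give z = 0, p = 1, unequal means
    are flagged as an infinite-z comparison with p = 0.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    _warn_small(n1, n2)
    se = sqrt(sd1**2 / n1 + sd2**2 / n2)
    if se == 0.0:
        if mean1 == mean2:
            return ZTestResult(0.0, 1.0, "two_mean", n1, n2)
        z = float("inf") if mean1 > mean2 else float("-inf")
        return ZTestResult(z, 0.0, "two_mean", n1, n2, infinite_z=True)
    z = (mean1 - mean2) / se
    return ZTestResult(float(z), _two_sided_p(z), "two_mean", n1, n2)


def ztest_two_proportions(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Two-sided pooled-proportion Z-test.

    z = (p1 - p2) / sqrt(p*(1-p)*(1/n1 + 1/n2)) with p the pooled
    proportion (x1 + x2)/(n1 + n2).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    _warn_small(n1, n2)
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        if p1 == p2:
            return ZTestResult(0.0, 1.0, "two_proportion", n1, n2)
        z = float("inf") if p1 > p2 else float("-inf")
        return ZTestResult(z, 0.0, "two_proportion", n1, n2, infinite_z=True)
    z = (p1 - p2) / se
    return ZTestResult(float(z), _two_sided_p(z), "two_proportion", n1, n2)


def significance_labels(p: float) -> str:
    """Standard significance bands: NS (p >= 0.05), *, **, *** (p < 0.001)."""
    if isinf(p) or not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"
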