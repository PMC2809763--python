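"""Two-sample inference from summary statistics (mean, sd, n) alone.

TEM section counts are often reported only as a mean, standard deviation
and number of sections per genotype.  These routines perform the standard
two-sample computations directly from such triples: the unequal-variance
(Welch) t-test with Satterthwaite fractional degrees of freedom, the
matching one-sided confidence bound for the mean difference, and the
variance-ratio F-test.  A pooled-variance t is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "SummaryStats",
    "TestResult",
    "IntervalEstimate",
    "welch_t_summary",
    "mean_diff_ci_summary",
    "variance_ratio_test",
]

_ALTERNATIVES = ("greater", "less", "two-sided")


@dataclass(frozen=True)
class SummaryStats:
    """Sample mean, standard deviation and size of one group of sections."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def variance(self) -> float:
        return self.sd**2


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: object  # float (t) or (df1, df2) pair (F)
    p_value: float
    alternative: str
    note: str = ""


@dataclass(frozen=True)
class IntervalEstimate:
    lower: float
    upper: float
    confidence: float
    sided: str


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def _se_df(a: SummaryStats, b: SummaryStats, equal_var: bool) -> tuple[float, float]:
    """Standard error of (mean_b - mean_a) and its degrees of freedom."""
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2 for a two-sample t procedure")
    va, vb = a.variance / a.n, b.variance / b.n
    if equal_var:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.variance + (b.n - 1) * b.variance) / df
        se = math.sqrt(sp2 * (1 / a.n + 1 / b.n))
        return se, float(df)
    se = math.sqrt(va + vb)
    if se == 0.0:
        return 0.0, float(a.n + b.n - 2)
    # Welch–Satterthwaite, kept fractional
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return se, df


def welch_t_summary(
    a: SummaryStats,
    b: SummaryStats,
    alternative: str = "greater",
    equal_var: bool = False,
) -> TestResult:
    """Two-sample t-test of the difference ``mean_b - mean_a`` from summaries.

    ``alternative='greater'`` tests mean_b > mean_a.  Welch by default;
    ``equal_var=True`` uses the pooled-variance statistic.  The degenerate
    case of two exactly constant equal samples returns t = 0 with the
    neutral p (0.5 one-sided, 1 two-sided) and a note.
    """
    _check_alternative(alternative)
    se, df = _se_df(a, b, equal_var)
    diff = b.mean - a.mean
    if se == 0.0:
        if diff == 0.0:
            p = 1.0 if alternative == "two-sided" else 0.5
            return TestResult(0.0, df, p, alternative,
                              note="degenerate: both groups constant and equal")
        t = math.inf if diff > 0 else -math.inf
    else:
        t = diff / se
    dist = stats.t(df)
    if alternative == "greater":
        p = float(dist.sf(t))
    elif alternative == "less":
        p = float(dist.cdf(t))
    else:
        p = float(2 * dist.sf(abs(t)))
    return TestResult(float(t), df, p, alternative)


def mean_diff_ci_summary(
    a: SummaryStats,
    b: SummaryStats,
    confidence: float = 0.95,
    sided: str = "one",
    equal_var: bool = False,
) -> IntervalEstimate:
    """Confidence interval for ``mean_b - mean_a`` from summaries.

    One-sided (default): ``[diff - t_{conf,df}·SE, +inf)``, the bound dual
    to the one-sided 'greater' test.  Two-sided: the usual symmetric
    interval.  Bounds are not rounded.
    """
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")
    se, df = _se_df(a, b, equal_var)
    diff = b.mean - a.mean
    if sided == "one":
        tcrit = float(stats.t(df).ppf(confidence))
        return IntervalEstimate(diff - tcrit * se, math.inf, confidence, sided)
    tcrit = float(stats.t(df).ppf((1 + confidence) / 2))
    return IntervalEstimate(diff - tcrit * se, diff + tcrit * se, confidence, sided)


def variance_ratio_test(
    a: SummaryStats, b: SummaryStats, alternative: str = "greater"
) -> TestResult:
    """F-test of variance homogeneity from summaries.

    The statistic is always ``F = sd_a² / sd_b²`` with df ``(n_a-1, n_b-1)``
    — the groups are never silently reordered.  ``alternative='greater'``
    tests σ²_a > σ²_b, ``'less'`` tests σ²_a < σ²_b, ``'two-sided'`` doubles
    the smaller tail.  Assumes normal samples.
    """
    _check_alternative(alternative)
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2 for the variance-ratio test")
    if a.sd == 0 or b.sd == 0:
        bad = "first" if a.sd == 0 else "second"
        raise ValueError(f"variance-ratio test undefined: sd of the {bad} group is 0")
    F = a.variance / b.variance
    df = (a.n - 1, b.n - 1)
    dist = stats.f(*df)
    if alternative == "greater":
        p = float(dist.sf(F))
    elif alternative == "less":
        p = float(dist.cdf(F))
    else:
        p = float(2 * min(dist.sf(F), dist.cdf(F)))
    return TestResult(float(F), df, min(p, 1.0), alternative)
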