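"""Branching two-group significance protocol.

The protocol used throughout the stability comparisons: each group is
screened for normality (Kolmogorov–Smirnov with Lilliefors-corrected
critical values, since the reference normal is estimated from the sample),
the variance ratio is tested with a two-sided F-test, and the two-tailed
Student's t-test (pooled variance) or Welch's t-test is applied for equal or
unequal variances respectively.  A normality failure is recorded as a flag,
never a hard stop.

A summary-statistics route (:func:`compare_from_summary`) applies the same
F-test / t-branch to printed mean ± s.e.m. tables where raw replicates are
unavailable; there the normality screen is marked untested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupSummary",
    "NormalityResult",
    "VarianceTestResult",
    "StatComparison",
    "ks_normality",
    "f_test_variances",
    "compare_groups",
    "compare_from_summary",
]


@dataclass
class GroupSummary:
    """Mean ± s.e.m. of a replicate group, optionally with the raw values."""

    mean: float
    sem: float
    n: int
    values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a group needs n >= 2")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            m = float(np.mean(self.values))
            s = float(np.std(self.values, ddof=1) / np.sqrt(len(self.values)))
            if len(self.values) != self.n:
                raise ValueError("values length does not match n")
            if abs(m - self.mean) > 1e-9 or abs(s - self.sem) > 1e-9:
                raise ValueError("stored mean/sem inconsistent with raw values")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(mean=float(np.mean(v)),
                   sem=float(np.std(v, ddof=1) / np.sqrt(len(v))),
                   n=len(v), values=v)

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @property
    def var(self) -> float:
        return self.sd ** 2


@dataclass
class NormalityResult:
    passed: bool
    statistic: float
    p_value: float
    method: str


@dataclass
class VarianceTestResult:
    equal: bool
    f: float
    df: tuple[int, int]
    p_value: float


@dataclass
class StatComparison:
    """Outcome of the branching comparison of two groups."""

    normality_pass: tuple[Optional[bool], Optional[bool]]
    variances_equal: bool
    test_used: str  # "student" or "welch"
    t: float
    df: float
    p_two_tailed: float
    f_p_value: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_two_tailed < 0.05


def ks_normality(values: Sequence[float], alpha: float = 0.05,
                 method: str = "lilliefors") -> NormalityResult:
    """Kolmogorov–Smirnov normality screen with estimated parameters.

    ``method="lilliefors"`` (default) uses critical values corrected for the
    mean and sd being estimated from the sample; ``method="asymptotic"``
    applies the naive KS test against N(mean, sd), which is anti-conservative
    but offered for comparability.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("normality screen needs at least 3 values")
    if np.ptp(v) == 0:
        raise ValueError("constant input: normality screen undefined")
    if method == "lilliefors":
        stat, p = lilliefors(v, dist="norm", pvalmethod="table")
    elif method == "asymptotic":
        stat, p = stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return NormalityResult(passed=bool(p >= alpha), statistic=float(stat),
                           p_value=float(p), method=method)


def f_test_variances(g1: GroupSummary, g2: GroupSummary,
                     alpha: float = 0.05) -> VarianceTestResult:
    """Two-sided F-test on the variance ratio; equal iff p >= alpha.

    Two-sidedness: p = 2 * min(P(F <= f), P(F >= f)) with the larger
    variance in the numerator.
    """
    if g1.sd <= 0 or g2.sd <= 0:
        raise ValueError("zero variance in a group: F-test undefined")
    if g1.var >= g2.var:
        f = g1.var / g2.var
        df = (g1.n - 1, g2.n - 1)
    else:
        f = g2.var / g1.var
        df = (g2.n - 1, g1.n - 1)
    p = 2.0 * min(stats.f.cdf(f, *df), stats.f.sf(f, *df))
    p = min(p, 1.0)
    return VarianceTestResult(equal=bool(p >= alpha), f=float(f), df=df,
                              p_value=float(p))


def _branch_from_summary(g1: GroupSummary, g2: GroupSummary, alpha: float):
    ftest = f_test_variances(g1, g2, alpha)
    delta = g1.mean - g2.mean
    if ftest.equal:
        # Student's t with pooled variance
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * g1.var + (g2.n - 1) * g2.var) / df
        se = np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
        test = "student"
    else:
        # Welch's t with Welch–Satterthwaite degrees of freedom
        a, b = g1.var / g1.n, g2.var / g2.n
        se = np.sqrt(a + b)
        df = (a + b) ** 2 / (a ** 2 / (g1.n - 1) + b ** 2 / (g2.n - 1))
        test = "welch"
    if se == 0:
        t = 0.0 if delta == 0 else np.inf * np.sign(delta)
    else:
        t = delta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return ftest, test, float(t), float(df), p


def compare_groups(g1: GroupSummary, g2: GroupSummary,
                   alpha: float = 0.05,
                   normality_method: str = "lilliefors") -> StatComparison:
    """Full protocol on raw replicate groups.

    Requires raw values in both groups (the normality screen needs them).
    Identical groups yield t = 0, p = 1.
    """
    if g1.values is None or g2.values is None:
        raise ValueError("compare_groups needs raw values; "
                         "use compare_from_summary for printed tables")
    norm = []
    for g in (g1, g2):
        try:
            norm.append(ks_normality(g.values, alpha, normality_method).passed)
        except ValueError:
            norm.append(None)  # degenerate (constant) group: screen undefined
    try:
        ftest, test, t, df, p = _branch_from_summary(g1, g2, alpha)
    except ValueError:
        # zero variance in both groups: identical-constant comparison
        if g1.sd == 0 and g2.sd == 0 and g1.mean == g2.mean:
            return StatComparison((norm[0], norm[1]), True, "student",
                                  0.0, g1.n + g2.n - 2, 1.0)
        raise
    return StatComparison(normality_pass=(norm[0], norm[1]),
                          variances_equal=ftest.equal, test_used=test,
                          t=t, df=df, p_two_tailed=p, f_p_value=ftest.p_value)


def compare_from_summary(m1: float, sem1: float, n1: int,
                         m2: float, sem2: float, n2: int,
                         alpha: float = 0.05) -> StatComparison:
    """Protocol applied to printed mean ± s.e.m. summaries.

    Standard deviations are reconstructed as sd = sem·√n; the normality
    screen cannot be run and is flagged untested (None, None).
    """
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("sems must be positive")
    g1 = GroupSummary(mean=m1, sem=sem1, n=n1)
    g2 = GroupSummary(mean=m2, sem=sem2, n=n2)
    ftest, test, t, df, p = _branch_from_summary(g1, g2, alpha)
    return StatComparison(normality_pass=(None, None),
                          variances_equal=ftest.equal, test_used=test,
                          t=t, df=df, p_two_tailed=p, f_p_value=ftest.p_value)
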