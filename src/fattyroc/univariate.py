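"""Two-sample tests, the test-selection decision tree, multiplicity
correction and the power/sample-size calculation.

The routing logic: each cohort's sample is first checked for normality
with the Anderson-Darling test (gate level 0.05).  If both cohorts look
normal, an F-test for equal variances picks between Student's t (equal
variances) and Welch's t.  If either cohort rejects normality, a
two-sample Kolmogorov-Smirnov test asks whether the two distributions
share a shape: same shape -> Mann-Whitney U on medians; different shape
-> Welch's t on means, flagged with a note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestDecision",
    "PowerSpec",
    "anderson_darling",
    "f_test_equal_var",
    "student_t",
    "welch_t",
    "ks_two_sample",
    "mann_whitney_u",
    "select_and_test",
    "multiplicity_correct",
    "min_sample_size",
]


def _as_vector(x, min_n: int, name: str = "sample") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} finite values, got {arr.size}")
    return arr


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------


class AdResult(NamedTuple):
    a2_star: float
    p: float
    reject: bool


def anderson_darling(x, alpha: float = 0.05) -> AdResult:
    """Anderson-Darling normality test with estimated mean and variance.

    Returns the small-sample-corrected statistic
    ``A*^2 = A^2 (1 + 0.75/n + 2.25/n^2)`` and a p-value from the
    D'Agostino-Stephens piecewise-exponential approximation for the
    composite-normality case.  Samples below n=8 trigger a warning; a
    constant sample (zero variance) is an error.
    """
    arr = _as_vector(x, 3)
    n = arr.size
    if n < 8:
        warnings.warn(f"Anderson-Darling on n={n} < 8 is unreliable", stacklevel=2)
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ValueError("Anderson-Darling: sample has zero variance")
    w = np.sort((arr - arr.mean()) / sd)
    logcdf = stats.norm.logcdf(w)
    logsf = stats.norm.logsf(w)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (logcdf + logsf[::-1])) / n
    a2_star = a2 * (1 + 0.75 / n + 2.25 / n**2)

    if a2_star >= 0.6:
        p = math.exp(1.2937 - 5.709 * a2_star + 0.0186 * a2_star**2)
    elif a2_star > 0.34:
        p = math.exp(0.9177 - 4.279 * a2_star - 1.38 * a2_star**2)
    elif a2_star > 0.2:
        p = 1 - math.exp(-8.318 + 42.796 * a2_star - 59.938 * a2_star**2)
    else:
        p = 1 - math.exp(-13.436 + 101.14 * a2_star - 223.73 * a2_star**2)
    p = min(max(p, 0.0), 1.0)
    return AdResult(float(a2_star), float(p), p < alpha)


# ---------------------------------------------------------------------------
# The individual two-sample tests
# ---------------------------------------------------------------------------


class FResult(NamedTuple):
    statistic: float
    p: float


def f_test_equal_var(x, y) -> FResult:
    """Variance-ratio F-test, two-sided: ``F = s1^2/s2^2`` against
    ``F(n1-1, n2-1)`` with ``p = 2 min(P(F' <= F), P(F' >= F))``."""
    x = _as_vector(x, 2, "x")
    y = _as_vector(y, 2, "y")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 or v2 == 0:
        raise ValueError("F-test: zero variance in a group")
    f = v1 / v2
    dist = stats.f(x.size - 1, y.size - 1)
    p = 2 * min(dist.cdf(f), dist.sf(f))
    return FResult(float(f), float(min(p, 1.0)))


class TResult(NamedTuple):
    statistic: float
    df: float
    p: float


def student_t(x, y) -> TResult:
    """Pooled-variance two-sample t-test, df = n1 + n2 - 2."""
    x = _as_vector(x, 2, "x")
    y = _as_vector(y, 2, "y")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("t-test: zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TResult(float(res.statistic), float(x.size + y.size - 2), float(res.pvalue))


def welch_t(x, y) -> TResult:
    """Unequal-variance t-test with Welch-Satterthwaite df."""
    x = _as_vector(x, 2, "x")
    y = _as_vector(y, 2, "y")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("t-test: zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    return TResult(float(res.statistic), float(res.df), float(res.pvalue))


class KsResult(NamedTuple):
    statistic: float
    p: float


def ks_two_sample(x, y) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test of equal distribution shape.

    D is the supremum ECDF distance over the pooled sample; the p-value
    is the asymptotic Kolmogorov distribution evaluated at effective
    sample size n1*n2/(n1+n2).
    """
    x = _as_vector(x, 3, "x")
    y = _as_vector(y, 3, "y")
    res = stats.ks_2samp(x, y, method="asymp")
    return KsResult(float(res.statistic), float(res.pvalue))


class UResult(NamedTuple):
    u: float
    p: float
    median_x: float
    median_y: float
    auc: float


def mann_whitney_u(x, y) -> UResult:
    """Mann-Whitney U via midranks; reports medians and the empirical AUC.

    ``auc = U / (n1 n2)`` is the fraction of (x, y) pairs with x > y,
    ties counted half.  Exact enumeration is used for small tie-free
    samples (n1 + n2 <= 12), otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    x = _as_vector(x, 3, "x")
    y = _as_vector(y, 3, "y")
    pooled = np.concatenate([x, y])
    exact = (x.size + y.size <= 12) and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u = float(res.statistic)
    return UResult(
        u,
        float(res.pvalue),
        float(np.median(x)),
        float(np.median(y)),
        u / (x.size * y.size),
    )


# ---------------------------------------------------------------------------
# Selection tree
# ---------------------------------------------------------------------------

ROUTES = (
    "AD_pass_F_pass",   # both normal, equal variances      -> Student's t
    "AD_pass_F_fail",   # both normal, unequal variances    -> Welch
    "AD_fail_KS_pass",  # non-normal, same shape            -> Mann-Whitney U
    "AD_fail_KS_fail",  # non-normal, different shapes      -> Welch (note)
)

_FINAL = {
    "AD_pass_F_pass": "Student's t-test",
    "AD_pass_F_fail": "Welch's test",
    "AD_fail_KS_pass": "Mann-Whitney U test",
    "AD_fail_KS_fail": "Welch's test",
}

SHAPE_NOTE = "Welch's test was used after the distributions were found to not be of the same shape"


@dataclass
class TestDecision:
    """Outcome of the selection tree for one analyte (one report row)."""

    analyte: str
    route: str
    ad_p_asd: float
    ad_p_neu: float
    gate_name: str          # "F" or "KS"
    gate_p: float
    final_test: str
    statistic: float
    df: float | None        # t-family only; Welch-Satterthwaite for Welch
    p_value: float
    central_asd: float      # mean for t-family, median for Mann-Whitney
    central_neu: float
    n_asd: int
    n_neu: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}")
        if _FINAL[self.route] != self.final_test:
            raise ValueError(
                f"route {self.route} implies {_FINAL[self.route]}, got {self.final_test}"
            )
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")


def select_and_test(x, y, alpha_gate: float = 0.05, analyte: str = "") -> TestDecision:
    """Route one analyte through the decision tree and run the final test.

    ``x`` is the case (ASD) sample, ``y`` the control (NEU) sample.  All
    gates use two-sided tests at ``alpha_gate``.
    """
    x = _as_vector(x, 3, "x (ASD)")
    y = _as_vector(y, 3, "y (NEU)")
    ad_x = anderson_darling(x, alpha_gate)
    ad_y = anderson_darling(y, alpha_gate)
    note = ""
    if not ad_x.reject and not ad_y.reject:
        gate_name = "F"
        gate = f_test_equal_var(x, y)
        if gate.p >= alpha_gate:
            route = "AD_pass_F_pass"
            t = student_t(x, y)
        else:
            route = "AD_pass_F_fail"
            t = welch_t(x, y)
        stat, df, p = t.statistic, t.df, t.p
        central = (float(x.mean()), float(y.mean()))
    else:
        gate_name = "KS"
        gate = ks_two_sample(x, y)
        if gate.p >= alpha_gate:
            route = "AD_fail_KS_pass"
            u = mann_whitney_u(x, y)
            stat, df, p = u.u, None, u.p
            central = (u.median_x, u.median_y)
        else:
            route = "AD_fail_KS_fail"
            t = welch_t(x, y)
            stat, df, p = t.statistic, t.df, t.p
            central = (float(x.mean()), float(y.mean()))
            note = SHAPE_NOTE
    return TestDecision(
        analyte=analyte,
        route=route,
        ad_p_asd=ad_x.p,
        ad_p_neu=ad_y.p,
        gate_name=gate_name,
        gate_p=gate.p,
        final_test=_FINAL[route],
        statistic=float(stat),
        df=df,
        p_value=float(p),
        central_asd=central[0],
        central_neu=central[1],
        n_asd=int(x.size),
        n_neu=int(y.size),
        note=note,
    )


# ---------------------------------------------------------------------------
# Multiplicity and power
# ---------------------------------------------------------------------------


def multiplicity_correct(p_values, method: str = "bonferroni") -> np.ndarray:
    """Adjusted p-values (capped at 1) for ``method`` in
    {'bonferroni', 'holm'}."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bonferroni", "holm"):
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=method)[1]


@dataclass
class PowerSpec:
    """Inputs to the two-sample sample-size calculation.

    ``d`` is Cohen's d (standardized mean difference), ``alpha`` the
    significance level, ``power`` the target power (1 - type-II rate).
    """

    d: float
    alpha: float = 0.1
    power: float = 0.8
    sided: str = "two"

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("d must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


def min_sample_size(spec: PowerSpec) -> int:
    """Per-group n for a two-sample comparison at effect size d.

    Normal approximation: ``n = 2 ((z_{1-a/2} + z_{power}) / d)^2``,
    rounded to the nearest integer.  With d=0.5, alpha=0.1 (two-sided)
    and power 0.8 this gives 49 per group.
    """
    z_a = stats.norm.ppf(1 - spec.alpha / (2 if spec.sided == "two" else 1))
    z_b = stats.norm.ppf(spec.power)
    n = 2 * ((z_a + z_b) / spec.d) ** 2
    return max(2, int(math.floor(n + 0.5)))
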