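"""Assumption checking and classical test selection.

Decision tree for group comparisons on the summary statistics:

* two groups — Student t when normality and homoscedasticity hold, Welch
  when only normality holds, Mann-Whitney otherwise;
* three or more groups — one-way ANOVA when assumptions hold, otherwise
  Kruskal-Wallis, with pairwise Mann-Whitney follow-ups attached when the
  Kruskal-Wallis p-value is at most 0.05;
* correlations — Pearson under bivariate normality, Spearman otherwise.

Normality is assessed per group with Shapiro-Wilk (an automated stand-in
for visual QQ inspection; the alpha is configurable and explicit flags can
override the automation).  Homoscedasticity uses a two-sided F variance
test for two groups and Bartlett's test for more.  When heteroscedastic and
all values are positive, the check is retried on log-transformed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AssumptionReport",
    "TestResult",
    "check_assumptions",
    "two_group_test",
    "multi_group_test",
    "correlation_test",
    "f_variance_test",
    "select_two_group_test",
]


@dataclass
class AssumptionReport:
    normal: bool
    homoscedastic: bool
    transform: str = "none"  # "none" or "log"
    details: dict = field(default_factory=dict)


@dataclass
class TestResult:
    name: str
    statistic: float
    pvalue: float
    df: float | tuple | None = None  # parametric tests only
    transform: str = "none"
    pairwise: dict = field(default_factory=dict)  # follow-up Mann-Whitney results


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    out = [g[np.isfinite(g)] for g in out]
    return out


def f_variance_test(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided F test for equality of two variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group for the variance test")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0 and va == 0:
        return TestResult("F-variance", 1.0, 1.0, df=(a.size - 1, b.size - 1))
    if vb == 0:
        return TestResult("F-variance", float("inf"), 0.0, df=(a.size - 1, b.size - 1))
    F = va / vb
    dfn, dfd = a.size - 1, b.size - 1
    p = 2.0 * min(stats.f.sf(F, dfn, dfd), stats.f.cdf(F, dfn, dfd))
    return TestResult("F-variance", float(F), float(min(p, 1.0)), df=(dfn, dfd))


def _homoscedastic(groups: list[np.ndarray], alpha: float) -> tuple[bool, dict]:
    if len(groups) == 2:
        res = f_variance_test(groups[0], groups[1])
        return res.pvalue > alpha, {"variance_test": res}
    stat, p = stats.bartlett(*groups)
    return p > alpha, {"variance_test": TestResult("Bartlett", float(stat), float(p))}


def _all_normal(groups: list[np.ndarray], alpha: float) -> bool:
    for g in groups:
        if g.size < 3:
            return False
        if stats.shapiro(g).pvalue <= alpha:
            return False
    return True


def check_assumptions(
    groups,
    alpha: float = 0.05,
    try_log: bool = True,
    normal: bool | None = None,
    homoscedastic: bool | None = None,
) -> AssumptionReport:
    """Normality + homoscedasticity checks with an optional log-transform retry.

    ``normal``/``homoscedastic`` override the automated checks when given
    (to reproduce manual, plot-based decisions exactly).  When the raw data
    are heteroscedastic, strictly positive, and ``try_log`` is set, the
    checks are repeated on log-transformed data; ``transform="log"`` is
    reported when the transformed data pass the variance check.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < 3:
            raise ValueError("need n >= 3 per group to check assumptions")
    details: dict = {}
    auto_normal = _all_normal(gs, alpha) if normal is None else bool(normal)
    if homoscedastic is None:
        auto_homo, det = _homoscedastic(gs, alpha)
        details.update(det)
    else:
        auto_homo = bool(homoscedastic)
    transform = "none"
    if not auto_homo and try_log:
        if all(np.all(g > 0) for g in gs):
            logs = [np.log(g) for g in gs]
            log_homo, det_log = _homoscedastic(logs, alpha)
            details["log_variance_test"] = det_log.get("variance_test")
            if log_homo:
                transform = "log"
                auto_homo = True
                if normal is None:
                    auto_normal = _all_normal(logs, alpha)
        else:
            details["log_transform"] = "unavailable (non-positive values)"
    return AssumptionReport(
        normal=auto_normal,
        homoscedastic=auto_homo,
        transform=transform,
        details=details,
    )


def select_two_group_test(normal: bool, homoscedastic: bool) -> str:
    """Pure decision function: assumption flags -> test name."""
    if normal and homoscedastic:
        return "t"
    if normal:
        return "Welch"
    return "Mann-Whitney"


def two_group_test(groups, assumptions: AssumptionReport) -> TestResult:
    """t / Welch / Mann-Whitney according to the assumption flags (two-sided)."""
    gs = _as_groups(groups)
    if len(gs) != 2:
        raise ValueError("two_group_test requires exactly 2 groups")
    if any(g.size < 2 for g in gs):
        raise ValueError("need n >= 2 per group")
    a, b = gs
    if assumptions.transform == "log":
        if not (np.all(a > 0) and np.all(b > 0)):
            raise ValueError("log transform requested on non-positive data")
        a, b = np.log(a), np.log(b)
    name = select_two_group_test(assumptions.normal, assumptions.homoscedastic)
    if name == "t":
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
    elif name == "Welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        stat, p = res.statistic, res.pvalue
        df = float(res.df)
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        df = None
    return TestResult(
        name=name,
        statistic=float(stat),
        pvalue=float(p),
        df=df,
        transform=assumptions.transform,
    )


def multi_group_test(
    groups,
    assumptions: AssumptionReport,
    labels: list | None = None,
    followup_alpha: float = 0.05,
) -> TestResult:
    """One-way ANOVA or Kruskal-Wallis for three or more groups.

    When Kruskal-Wallis is selected and its p-value is <= ``followup_alpha``
    all pairwise Mann-Whitney tests are attached.  Exactly two groups are
    rejected (route them to :func:`two_group_test`).
    """
    gs = _as_groups(groups)
    if len(gs) < 3:
        raise ValueError("multi_group_test requires >= 3 groups; use two_group_test")
    if any(g.size < 2 for g in gs):
        raise ValueError("need n >= 2 per group")
    if labels is None:
        labels = [str(i) for i in range(len(gs))]
    if assumptions.transform == "log":
        if not all(np.all(g > 0) for g in gs):
            raise ValueError("log transform requested on non-positive data")
        gs = [np.log(g) for g in gs]
    if assumptions.normal and assumptions.homoscedastic:
        stat, p = stats.f_oneway(*gs)
        k = len(gs)
        n = sum(g.size for g in gs)
        if not np.isfinite(p):  # guards tiny negative F from rounding
            stat = max(float(stat), 0.0)
            p = stats.f.sf(stat, k - 1, n - k)
        return TestResult(
            name="ANOVA",
            statistic=float(stat),
            pvalue=float(p),
            df=(k - 1, n - k),
            transform=assumptions.transform,
        )
    stat, p = stats.kruskal(*gs)
    result = TestResult(
        name="Kruskal-Wallis",
        statistic=float(stat),
        pvalue=float(p),
        df=None,
        transform=assumptions.transform,
    )
    if p <= followup_alpha:
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                u, pu = stats.mannwhitneyu(gs[i], gs[j], alternative="two-sided")
                result.pairwise[(labels[i], labels[j])] = TestResult(
                    name="Mann-Whitney", statistic=float(u), pvalue=float(pu)
                )
    return result


def correlation_test(x, y, bivariate_normal: bool) -> TestResult:
    """Pearson when bivariate normality is assumed, Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    valid = np.isfinite(x) & np.isfinite(y)
    x, y = x[valid], y[valid]
    if x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in x or y")
    if bivariate_normal:
        r, p = stats.pearsonr(x, y)
        return TestResult("Pearson", float(r), float(p), df=x.size - 2)
    rho, p = stats.spearmanr(x, y)
    return TestResult("Spearman", float(rho), float(p))
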