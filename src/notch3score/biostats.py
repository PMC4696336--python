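"""Statistical layer for NOTCH3-score progression analyses.

Covers the comparisons used when the score serves as a biomarker:

* pooled-variance two-sample t-test on group summaries (strain vs
  strain at one time point), with Welch as an option;
* one-way ANOVA across time points with Fisher's LSD post-hoc pairwise
  tests (unadjusted p-values using the pooled error term);
* ordinary least-squares progression fits (score vs age in weeks) and a
  slope-equality test via the age-by-group interaction of a common
  model;
* two-sample power and sample-size calculation for detecting a
  fractional treatment effect on progression, using a normal
  approximation refined by exact noncentral-t power iteration.

"Unpaired Student's t-test" is implemented as the pooled-variance test
(the common default of interactive statistics packages), not Welch.
LSD p-values are deliberately unadjusted -- that is what Fisher's LSD
is -- so interpretation across many pairs needs external care.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "GroupSummary",
    "TestResult",
    "RegressionFit",
    "t_test_from_summary",
    "t_test",
    "anova_lsd",
    "fit_progression",
    "compare_slopes",
    "power_two_sample_t",
    "sample_size_progression",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group (strain, age or diagnosis)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError(f"group {self.label!r}: n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise ParameterError(f"group {self.label!r}: sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test (two-sided unless noted in method)."""

    statistic: float
    df: float | tuple[float, float]
    p_value: float
    method: str
    estimate: float | None = None


@dataclass(frozen=True)
class RegressionFit:
    """OLS progression fit: score units per week."""

    slope: float
    intercept: float
    slope_se: float
    df_resid: int


def t_test_from_summary(
    a: GroupSummary, b: GroupSummary, *, welch: bool = False
) -> TestResult:
    """Two-sample t-test from group means and SDs.

    Pooled-variance by default (df = n_a + n_b - 2); ``welch=True``
    switches to the unequal-variance test with Satterthwaite df.
    """
    if a.n < 2 or b.n < 2:
        raise DegenerateInputError("t-test needs n >= 2 in both groups")
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=not welch
    )
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        method = "welch t-test (summary)"
    else:
        df = a.n + b.n - 2
        method = "pooled t-test (summary)"
    return TestResult(
        statistic=float(t), df=float(df), p_value=float(p), method=method,
        estimate=a.mean - b.mean,
    )


def t_test(x, y, *, welch: bool = False, labels=("a", "b")) -> TestResult:
    """Two-sample t-test on raw data via the summary pathway."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return t_test_from_summary(
        GroupSummary(labels[0], x.size, float(x.mean()), float(x.std(ddof=1))),
        GroupSummary(labels[1], y.size, float(y.mean()), float(y.std(ddof=1))),
        welch=welch,
    )


def anova_lsd(groups, labels=None) -> tuple[TestResult, pd.DataFrame]:
    """One-way ANOVA with Fisher's LSD post-hoc pairwise tests.

    Parameters
    ----------
    groups : list of 1-D samples, each with n >= 2.
    labels : optional group names for the pairwise table.

    Returns
    -------
    (omnibus, pairwise) where ``pairwise`` has one row per group pair
    with the LSD t statistic (pooled MSE, MSE degrees of freedom) and
    its unadjusted two-sided p-value.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    k = len(samples)
    if k < 2:
        raise DegenerateInputError("ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in samples):
        raise DegenerateInputError("every group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]

    ns = np.array([g.size for g in samples])
    means = np.array([g.mean() for g in samples])
    n_total = int(ns.sum())
    grand = float(np.concatenate(samples).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(samples, means)))
    df_between, df_within = k - 1, n_total - k
    ms_within = ss_within / df_within
    if ms_within == 0:
        f_stat = 0.0 if ss_between == 0 else math.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = (ss_between / df_between) / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))
    omnibus = TestResult(
        statistic=f_stat, df=(df_between, df_within), p_value=p, method="one-way ANOVA"
    )

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = math.sqrt(ms_within * (1 / ns[i] + 1 / ns[j])) if ms_within > 0 else 0.0
            if se > 0:
                t = diff / se
                p_ij = float(2 * stats.t.sf(abs(t), df_within))
            else:
                t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
                p_ij = 1.0 if diff == 0 else 0.0
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "mean_diff": diff,
                    "t": t,
                    "df": df_within,
                    "p_unadjusted": p_ij,
                }
            )
    return omnibus, pd.DataFrame(rows)


def fit_progression(ages, scores) -> RegressionFit:
    """OLS fit of score against age (weeks); slope SE from residuals."""
    x = np.asarray(ages, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DegenerateInputError("progression fit needs >= 3 (age, score) points")
    if np.unique(x).size < 2:
        raise DegenerateInputError("progression fit needs >= 2 distinct ages")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        df_resid=x.size - 2,
    )


def compare_slopes(ages_a, scores_a, ages_b, scores_b) -> TestResult:
    """Test equality of progression slopes between two groups.

    Fits the common model ``score ~ age + group + age:group`` by OLS
    and tests the interaction coefficient (two-sided t with pooled
    residual variance).  ``estimate`` is the slope difference (b - a).
    """
    import statsmodels.api as sm

    xa = np.asarray(ages_a, dtype=float)
    ya = np.asarray(scores_a, dtype=float)
    xb = np.asarray(ages_b, dtype=float)
    yb = np.asarray(scores_b, dtype=float)
    # both groups must individually support a slope fit
    for x in (xa, xb):
        if x.size < 3 or np.unique(x).size < 2:
            raise DegenerateInputError("each group needs >= 3 points at >= 2 ages")
    age = np.concatenate([xa, xb])
    grp = np.concatenate([np.zeros(xa.size), np.ones(xb.size)])
    design = np.column_stack([np.ones(age.size), age, grp, age * grp])
    fit = sm.OLS(np.concatenate([ya, yb]), design).fit()
    return TestResult(
        statistic=float(fit.tvalues[3]),
        df=float(fit.df_resid),
        p_value=float(fit.pvalues[3]),
        method="slope equality (age x group interaction)",
        estimate=float(fit.params[3]),
    )


def power_two_sample_t(n: int, delta: float, sd: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided pooled t-test, n per group."""
    if n < 2:
        return 0.0
    df = 2 * n - 2
    ncp = delta / (sd * math.sqrt(2.0 / n))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def sample_size_progression(
    effect_fraction: float,
    baseline_progression: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
) -> int:
    """Smallest per-group n detecting a fractional effect on progression.

    The detectable difference is ``delta = effect_fraction *
    baseline_progression`` in score units (e.g. the score increase over
    a treatment window, or a slope difference, with ``sd`` on the same
    scale).  Starts from the normal-approximation formula
    ``n = 2 (z_{1-alpha/2} + z_{power})^2 sd^2 / delta^2`` and iterates
    the exact noncentral-t power to the smallest n meeting the target.
    Defaults alpha = 0.05 two-sided, power = 0.80.
    """
    if not (0 < effect_fraction <= 1):
        raise ParameterError(f"effect_fraction must be in (0, 1], got {effect_fraction}")
    if sd <= 0:
        raise ParameterError(f"sd must be > 0, got {sd}")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ParameterError("alpha and power must be in (0, 1)")
    delta = effect_fraction * baseline_progression
    if delta <= 0:
        raise ParameterError("baseline progression must be > 0")

    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    n = max(2, math.ceil(2 * (z * sd / delta) ** 2))
    while power_two_sample_t(n, delta, sd, alpha) < power:
        n += 1
    while n > 2 and power_two_sample_t(n - 1, delta, sd, alpha) >= power:
        n -= 1
    return n
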