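"""Statistical layer: t-tests, ANOVA/LSD, slopes, power."""

import math

import numpy as np
import pytest
from scipy import stats

from notch3score import (
    DegenerateInputError,
    GroupSummary,
    ParameterError,
    anova_lsd,
    compare_slopes,
    fit_progression,
    power_two_sample_t,
    sample_size_progression,
    t_test,
    t_test_from_summary,
)

from _oracles import ols_interaction_pvalue


def _data_with_exact_summary(mean, sd, n, seed):
    """Sample standardized to hit the requested mean/SD exactly."""
    z = np.random.default_rng(seed).normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


class TestTTest:
    def test_strain_comparison_at_twenty_months(self):
        """Lower- vs higher-expressing strain summaries: t ~ 7.17, p ~ 0.002."""
        res = t_test_from_summary(
            GroupSummary("tgN3MUT150", 3, 659, 51),
            GroupSummary("tgN3MUT350", 3, 1150, 107),
        )
        assert res.df == 4
        assert abs(res.statistic) == pytest.approx(7.17, abs=0.01)
        assert round(res.p_value, 3) == 0.002

    def test_identical_groups_null(self):
        g = GroupSummary("a", 5, 10.0, 2.0)
        res = t_test_from_summary(g, g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_summary_equals_raw_to_high_precision(self):
        x = _data_with_exact_summary(659, 51, 6, seed=1)
        y = _data_with_exact_summary(1150, 107, 7, seed=2)
        raw = t_test(x, y)
        summ = t_test_from_summary(
            GroupSummary("a", 6, 659, 51), GroupSummary("b", 7, 1150, 107)
        )
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        assert raw.p_value == pytest.approx(summ.p_value, rel=1e-10)

    def test_welch_option_differs_with_unequal_variance(self):
        a = GroupSummary("a", 4, 0.0, 1.0)
        b = GroupSummary("b", 12, 1.0, 5.0)
        pooled = t_test_from_summary(a, b)
        welch = t_test_from_summary(a, b, welch=True)
        assert pooled.df == 14 and welch.df < 14
        assert pooled.p_value != pytest.approx(welch.p_value)

    def test_small_groups_rejected(self):
        with pytest.raises(DegenerateInputError):
            t_test_from_summary(
                GroupSummary("a", 1, 0.0, 0.0), GroupSummary("b", 3, 1.0, 1.0)
            )


class TestAnovaLSD:
    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(0, 1, 6)
        y = rng.normal(1, 1, 8)
        omnibus, _ = anova_lsd([x, y])
        t = t_test(x, y)
        assert omnibus.statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert omnibus.p_value == pytest.approx(t.p_value, rel=1e-12)

    def test_identical_groups_null(self):
        g = [1.0, 2.0, 3.0]
        omnibus, pairwise = anova_lsd([g, g, g])
        assert omnibus.statistic == 0.0 and omnibus.p_value == 1.0
        assert (pairwise["p_unadjusted"] == 1.0).all()

    def test_three_group_toy_matches_library_oracle(self):
        groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [6.0, 7.0, 8.0]]
        omnibus, pairwise = anova_lsd(groups, labels=["w6", "w24", "w52"])
        f, p = stats.f_oneway(*groups)
        assert omnibus.statistic == pytest.approx(f, rel=1e-12)
        assert omnibus.p_value == pytest.approx(p, rel=1e-12)
        assert omnibus.df == (2, 6)
        # LSD row for the widest pair, against the defining formula
        row = pairwise[(pairwise.group_a == "w6") & (pairwise.group_b == "w52")].iloc[0]
        mse = 1.0  # within-group variance of each toy group is 1
        t = (2.0 - 7.0) / math.sqrt(mse * (1 / 3 + 1 / 3))
        assert row.t == pytest.approx(t, rel=1e-12)
        assert row.p_unadjusted == pytest.approx(2 * stats.t.sf(abs(t), 6), rel=1e-12)

    def test_undersized_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            anova_lsd([[1.0, 2.0], [3.0]])


class TestProgressionFit:
    def test_exact_line_recovered(self):
        ages = np.array([6.0, 24.0, 52.0, 82.0])
        fit = fit_progression(ages, 2.0 * ages + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.slope_se == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self, rng):
        ages = np.repeat([6.0, 24.0, 52.0, 82.0], 3)
        scores = 11.1 * ages + rng.normal(0, 40, ages.size)
        fit = fit_progression(ages, scores)
        x = np.column_stack([np.ones_like(ages), ages])
        beta = np.linalg.solve(x.T @ x, x.T @ scores)
        assert fit.slope == pytest.approx(beta[1], rel=1e-10)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-10)

    def test_duplication_shrinks_slope_se(self, rng):
        ages = np.repeat([6.0, 24.0, 52.0], 2)
        scores = 3.0 * ages + rng.normal(0, 5, ages.size)
        base = fit_progression(ages, scores)
        doubled = fit_progression(np.tile(ages, 2), np.tile(scores, 2))
        assert doubled.slope == pytest.approx(base.slope)
        assert doubled.slope_se < base.slope_se

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_progression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            fit_progression([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])


class TestCompareSlopes:
    def test_identical_datasets_give_null(self, rng):
        ages = np.repeat([6.0, 24.0, 52.0, 82.0], 3)
        scores = 11.1 * ages + rng.normal(0, 30, ages.size)
        res = compare_slopes(ages, scores, ages, scores)
        assert res.estimate == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_design_matrix_oracle(self, rng):
        ages = np.repeat([6.0, 24.0, 52.0, 82.0], 3)
        sa = 11.1 * ages + rng.normal(0, 30, ages.size)
        sb = 6.2 * ages + rng.normal(0, 30, ages.size)
        res = compare_slopes(ages, sa, ages, sb)
        est, p = ols_interaction_pvalue(ages, sa, ages, sb)
        assert res.estimate == pytest.approx(est, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-8)

    def test_detects_two_fold_slope_difference(self):
        rng = np.random.default_rng(42)
        ages = np.repeat([6.0, 24.0, 52.0, 82.0], 3)
        sa = 11.1 * ages + rng.normal(0, 5, ages.size)
        sb = 5.55 * ages + rng.normal(0, 5, ages.size)
        res = compare_slopes(ages, sa, ages, sb)
        assert res.p_value < 0.001


class TestPower:
    def test_unit_effect_needs_seventeen_per_group(self):
        assert sample_size_progression(1.0, 10.0, 10.0) == 17

    def test_matches_statsmodels_power_solver(self):
        from statsmodels.stats.power import TTestIndPower

        for effect in [0.5, 0.8, 1.2]:
            n = sample_size_progression(1.0, effect, 1.0)
            n_sm = math.ceil(
                TTestIndPower().solve_power(effect_size=effect, alpha=0.05, power=0.8)
            )
            assert n == n_sm

    def test_doubling_effect_shrinks_n_about_fourfold(self):
        n1 = sample_size_progression(0.5, 10.0, 10.0)
        n2 = sample_size_progression(1.0, 10.0, 10.0)
        assert n2 <= math.ceil(n1 / 4) + 2

    def test_returned_n_achieves_power_in_monte_carlo(self):
        delta, sd, alpha, target = 1.0, 1.0, 0.05, 0.80
        n = sample_size_progression(1.0, delta, sd, alpha=alpha, power=target)
        rng = np.random.default_rng(123)

        def mc_power(n, reps=20000):
            a = rng.normal(0.0, sd, size=(reps, n))
            b = rng.normal(delta, sd, size=(reps, n))
            sp2 = (a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1)) / 2
            t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(sp2 * 2 / n)
            crit = stats.t.ppf(1 - alpha / 2, 2 * n - 2)
            return float(np.mean(np.abs(t) > crit))

        mc_err = 3 * math.sqrt(target * (1 - target) / 20000)
        assert mc_power(n) >= target - mc_err
        assert mc_power(n - 1) < target

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            sample_size_progression(0.0, 10.0, 10.0)
        with pytest.raises(ParameterError):
            sample_size_progression(0.5, 10.0, -1.0)


def test_group_summary_validation():
    with pytest.raises(ParameterError):
        GroupSummary("bad", 0, 1.0, 1.0)
    with pytest.raises(ParameterError):
        GroupSummary("bad", 3, 1.0, -0.5)
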