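"""The statistical battery: summary/raw t tests, rank tests, chi-square,
normality gating, effect sizes and the noncentral-t power calculation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from baumtest.errors import DegenerateInputError, InsufficientDataError, SchemaError
from baumtest.stats import (
    chi_square,
    cohens_d,
    compare_groups,
    correlate_with_scale,
    mann_whitney,
    power_two_sample_t,
    required_sample_size,
    shapiro_normality,
    spearman,
    stars,
    t_test_raw,
    t_test_summary,
)


class TestShapiro:
    def test_normal_samples_usually_pass(self, rng):
        passed = sum(
            shapiro_normality(rng.normal(size=100))[1] > 0.05 for _ in range(100)
        )
        assert passed >= 90

    def test_exponential_samples_usually_fail(self, rng):
        rejected = sum(
            shapiro_normality(rng.exponential(size=100))[1] < 0.05 for _ in range(100)
        )
        assert rejected >= 90

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateInputError):
            shapiro_normality([2.0, 2.0, 2.0, 2.0])

    def test_too_small_sample(self):
        with pytest.raises(InsufficientDataError):
            shapiro_normality([1.0, 2.0])


class TestTTestSummary:
    def test_identical_groups_give_zero(self):
        r = t_test_summary(5.0, 1.0, 30, 5.0, 1.0, 30)
        assert r.statistic == 0.0
        assert r.p == pytest.approx(1.0)

    def test_welch_df_below_pooled_when_variances_differ(self):
        pooled = t_test_summary(1.0, 1.0, 20, 0.0, 4.0, 40, variant="pooled")
        welch = t_test_summary(1.0, 1.0, 20, 0.0, 4.0, 40, variant="welch")
        assert pooled.df == 58
        assert welch.df < pooled.df

    def test_both_zero_sds_degenerate(self):
        with pytest.raises(DegenerateInputError):
            t_test_summary(1.0, 0.0, 10, 2.0, 0.0, 10)

    def test_group_swap_flips_sign_only(self):
        a = t_test_summary(3.0, 1.2, 25, 2.0, 0.9, 30)
        b = t_test_summary(2.0, 0.9, 30, 3.0, 1.2, 25)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)


class TestTTestRaw:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), variant=st.sampled_from(["pooled", "welch"]))
    def test_matches_summary_form_exactly(self, seed, variant):
        r = np.random.default_rng(seed)
        x = r.normal(0, 1, r.integers(5, 40))
        y = r.normal(0.5, 1.5, r.integers(5, 40))
        raw = t_test_raw(x, y, variant=variant)
        summ = t_test_summary(
            x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size,
            variant=variant,
        )
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.p == pytest.approx(summ.p, abs=1e-12)
        assert raw.df == pytest.approx(summ.df, abs=1e-9)

    def test_identical_samples_give_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = t_test_raw(x, x)
        assert r.statistic == 0.0

    def test_singleton_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            t_test_raw([1.0], [1.0, 2.0])


def exact_mw_p(x, y):
    """Brute-force two-sided Mann-Whitney p by enumerating group labelings."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_obs = sps.rankdata(pooled)[:n1].sum() - n1 * (n1 + 1) / 2
    n1n2 = n1 * len(y)
    lo = min(u_obs, n1n2 - u_obs)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(min(u, n1n2 - u))
    us = np.asarray(us)
    return float(np.mean(us <= lo + 1e-12))


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_enumeration(self, seed):
        r = np.random.default_rng(seed)
        x = r.normal(0, 1, int(r.integers(3, 8)))
        y = r.normal(0.8, 1, int(r.integers(3, 8)))
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(exact_mw_p(x, y), abs=1e-12)

    def test_identical_large_samples_near_one(self, rng):
        x = rng.normal(size=50)
        _, p = mann_whitney(x, x)
        assert p > 0.9


class TestChiSquare:
    def test_study_sex_by_group_counts_are_balanced(self):
        chi2, df, p = chi_square([[38, 20, 29], [44, 23, 30]])
        assert df == 2
        assert p > 0.05

    def test_proportional_table_is_zero(self):
        chi2, _, p = chi_square([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_two_by_two(self):
        chi2, df, p = chi_square([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert p < 0.001

    def test_zero_marginal_degenerate(self):
        with pytest.raises(DegenerateInputError):
            chi_square([[5, 0], [3, 0]])


def exact_spearman_p(x, y):
    """Brute-force two-sided permutation p for Spearman's rho."""
    rho_obs = sps.spearmanr(x, y).statistic
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        rho = sps.spearmanr(x, perm).statistic
        count += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


class TestSpearman:
    def test_monotone_increase_is_one(self):
        r = spearman([1, 2, 3, 5, 9], [2, 4, 8, 16, 32])
        assert r.rho == pytest.approx(1.0)

    def test_monotone_transform_of_negation_is_minus_one(self):
        x = np.array([0.3, 1.2, 2.2, 3.9, 5.1, 6.0])
        r = spearman(x, np.exp(-x))
        assert r.rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_small_sample_p_matches_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 8))
        x = r.normal(size=n)
        y = 0.5 * x + r.normal(size=n)
        res = spearman(x, y)
        assert res.p == pytest.approx(exact_spearman_p(x, y), abs=1e-12)

    def test_large_sample_uses_t_approximation(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d(4.0, 1.0, 20, 4.0, 2.0, 20) == 0.0

    def test_unit_case(self):
        assert cohens_d(1.0, 1.0, 50, 0.0, 1.0, 50) == pytest.approx(1.0)

    def test_published_severity_gap_is_a_large_effect(self):
        # depression-scale summaries of patient vs control groups
        assert abs(cohens_d(39.63, 3.31, 43, 4.80, 2.83, 59)) > 0.8


class TestPower:
    def test_medium_effect_needs_64_per_group(self):
        assert required_sample_size(0.5, alpha=0.05, power=0.80, two_sided=True) == 64

    def test_large_effect_needs_26_per_group(self):
        assert required_sample_size(0.8, alpha=0.05, power=0.80, two_sided=True) == 26

    def test_required_n_decreases_with_effect_size(self):
        assert required_sample_size(0.5) > required_sample_size(0.8)

    def test_noncentral_power_matches_monte_carlo(self, rng):
        # 10,000 simulated two-sample t tests at the returned n for d = 0.8
        d, n, reps = 0.8, 26, 10_000
        x = rng.normal(d, 1.0, size=(reps, n))
        y = rng.normal(0.0, 1.0, size=(reps, n))
        sp = np.sqrt((x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2)
        t = (x.mean(axis=1) - y.mean(axis=1)) / (sp * math.sqrt(2 / n))
        crit = sps.t.ppf(0.975, 2 * n - 2)
        mc_power = np.mean(np.abs(t) > crit)
        assert power_two_sample_t(d, n) == pytest.approx(mc_power, abs=0.02)
        assert power_two_sample_t(d, n) >= 0.80
        assert power_two_sample_t(d, n - 1) < 0.80


def toy_roster(rng, n=40, gap=2.0):
    rows = []
    for g, shift in (("a", gap), ("b", 0.0)):
        for i in range(n):
            rows.append({"group": g, "value": rng.normal(shift, 1.0),
                         "flat": 1.0 if g == "a" else rng.normal()})
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_built_in_gap_direction_recovered(self, rng):
        roster = toy_roster(rng)
        (res,) = compare_groups(roster, ["value"], "a", "b")
        assert res.statistic > 0 and res.p < 0.001
        assert res.stars == "***"

    def test_same_group_against_itself_is_null(self, rng):
        roster = toy_roster(rng, n=60, gap=0.0)
        (res,) = compare_groups(roster, ["value"], "a", "b")
        assert res.p > 0.001

    def test_constant_group_routed_to_rank_test(self, rng):
        roster = toy_roster(rng)
        (res,) = compare_groups(roster, ["flat"], "a", "b")
        assert res.test == "mann-whitney"
        assert res.df is None

    def test_missing_variable_is_schema_error(self, rng):
        with pytest.raises(SchemaError):
            compare_groups(toy_roster(rng), ["nope"], "a", "b")


class TestCorrelateWithScale:
    def test_recovers_negative_association(self, rng):
        n = 180
        x = rng.normal(size=n)
        roster = pd.DataFrame({"area": 50 - 3 * x + rng.normal(size=n),
                               "hdrs": 25 + 8 * x + rng.normal(size=n)})
        (res,) = correlate_with_scale(roster, ["area"], "hdrs")
        assert res.rho < -0.5 and res.n == n

    def test_listwise_deletion_reported(self, rng):
        roster = pd.DataFrame({"area": [1.0, 2, 3, 4, np.nan, 6],
                               "hdrs": [6.0, 5, 4, np.nan, 2, 1]})
        (res,) = correlate_with_scale(roster, ["area"], "hdrs")
        assert res.n == 4

    def test_constant_scale_degenerate(self):
        roster = pd.DataFrame({"area": [1.0, 2, 3, 4], "hdrs": [7.0, 7, 7, 7]})
        with pytest.raises(DegenerateInputError):
            correlate_with_scale(roster, ["area"], "hdrs")


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, ""), (0.02, ""), (0.009, "**"), (0.001, "**"), (0.0009, "***")],
    )
    def test_footnote_convention(self, p, expected):
        assert stars(p) == expected
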