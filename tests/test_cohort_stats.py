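import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from motorseg.cohort_stats import (
    descriptives,
    dunn_pairwise_bonferroni,
    effect_size_r,
    friedman_chi2,
    friedman_stepdown,
    kruskal_wallis,
    mann_whitney,
    prevalence_test,
)


class TestPrevalence:
    def test_reported_cohort_numbers(self):
        # 39 segmented of 57: 68%, p = 0.008, CI [0.55, 0.80]
        r = prevalence_test(39, 57)
        assert round(100 * r.phat) == 68
        assert round(r.p_two_sided, 3) == 0.008
        assert round(r.ci_low, 2) == 0.55
        assert round(r.ci_high, 2) == 0.80

    def test_exact_enumeration_7_of_10(self):
        # doubled tail: 2 * P(X >= 7) = 2 * 176/1024
        r = prevalence_test(7, 10)
        assert r.p_two_sided == pytest.approx(2 * 176 / 1024)

    def test_boundary_intervals(self):
        assert prevalence_test(57, 57).ci_high == 1.0
        assert prevalence_test(0, 57).ci_low == 0.0

    def test_balanced_split_p_one(self):
        assert prevalence_test(10, 20).p_two_sided == pytest.approx(1.0)

    def test_matches_scipy_clopper_pearson(self):
        r = prevalence_test(39, 57)
        ci = stats.binomtest(39, 57, 0.5).proportion_ci(0.95, method="exact")
        assert r.ci_low == pytest.approx(ci.low, abs=1e-12)
        assert r.ci_high == pytest.approx(ci.high, abs=1e-12)

    def test_clopper_pearson_monotone_in_k(self):
        lows, highs = [], []
        for k in range(58):
            r = prevalence_test(k, 57)
            lows.append(r.ci_low)
            highs.append(r.ci_high)
        assert all(a <= b + 1e-12 for a, b in zip(lows, lows[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(highs, highs[1:]))

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            prevalence_test(5, 3)


class TestKruskalWallis:
    def test_hand_computed_three_groups(self):
        # ranks 1..9, rank sums 6/15/24 -> H = 7.2
        r = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert r.H == pytest.approx(7.2)
        assert r.df == 2

    def test_identical_groups_degenerate(self):
        r = kruskal_wallis([[5.0, 5.0], [5.0, 5.0], [5.0]])
        assert r.H == 0.0 and r.p == 1.0

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.normal(size=8), rng.normal(1, 1, 9), rng.normal(2, 1, 7)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([np.exp(g) for g in groups])
        assert a.H == pytest.approx(b.H, rel=1e-12)

    def test_two_groups_equals_mw_z_squared(self, rng):
        for _ in range(10):
            g1 = rng.normal(size=rng.integers(5, 12))
            g2 = rng.normal(0.5, 1, rng.integers(5, 12))
            H = kruskal_wallis([g1, g2]).H
            z = mann_whitney(g1, g2).z
            assert H == pytest.approx(z**2, abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_type_one_error_small_slice(self, seed):
        # smoke slice of the calibration property (full check in acceptance)
        rng = np.random.default_rng(seed)
        r = kruskal_wallis([rng.normal(size=15) for _ in range(3)])
        assert 0.0 <= r.p <= 1.0


def brute_dunn_z(groups, i, j):
    """Independent Dunn z from pooled ranks, written from the definition."""
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    starts = np.cumsum([0] + sizes)
    mean_i = ranks[starts[i] : starts[i + 1]].mean()
    mean_j = ranks[starts[j] : starts[j + 1]].mean()
    _, counts = np.unique(pooled, return_counts=True)
    T = np.sum(counts**3 - counts)
    var = (N * (N + 1) / 12 - T / (12 * (N - 1))) * (1 / sizes[i] + 1 / sizes[j])
    return (mean_i - mean_j) / np.sqrt(var)


class TestDunn:
    def test_identical_groups_null(self):
        res = dunn_pairwise_bonferroni([[1, 2, 3]] * 3, ["a", "b", "c"])
        assert len(res) == 3
        for pr in res:
            assert pr.z == pytest.approx(0.0)
            assert pr.p_adj == 1.0

    def test_matches_independent_formula(self, rng):
        groups = [list(rng.normal(size=5)), list(rng.normal(3, 1, 5))]
        res = dunn_pairwise_bonferroni(groups, ["lo", "hi"])
        assert abs(res[0].z) == pytest.approx(abs(brute_dunn_z(groups, 0, 1)), abs=1e-9)

    def test_bonferroni_multiplier_is_pair_count(self, rng):
        groups = [list(rng.normal(size=6)) for _ in range(4)]
        res = dunn_pairwise_bonferroni(groups, list("abcd"))
        assert len(res) == 6
        for pr in res:
            assert pr.p_adj == pytest.approx(min(1.0, pr.p_unadj * 6))


class TestEffectSize:
    @pytest.mark.parametrize(
        "z,n,expected", [(6.60, 57, 0.87), (4.38, 57, 0.58), (0.0, 10, 0.0)]
    )
    def test_z_to_r(self, z, n, expected):
        assert round(effect_size_r(z, n), 2) == expected

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            effect_size_r(1.0, 1)


class TestMannWhitney:
    def test_exact_enumeration_two_vs_two(self):
        r = mann_whitney([1, 2], [3, 4])
        assert r.U == 0
        assert r.p_exact == pytest.approx(1 / 3)

    def test_exact_enumeration_three_vs_three(self):
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.U == 0
        assert r.p_exact == pytest.approx(0.1)

    def test_identical_samples_centered(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.U == pytest.approx(4.5)
        assert r.z == pytest.approx(0.0)

    def test_exact_matches_scipy_without_ties(self, rng):
        g1 = rng.normal(size=5)
        g2 = rng.normal(1, 1, 6)
        r = mann_whitney(g1, g2)
        sp = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="exact")
        assert r.p_exact == pytest.approx(sp.pvalue, abs=1e-12)

    def test_large_samples_skip_enumeration(self, rng):
        r = mann_whitney(rng.normal(size=10), rng.normal(size=10))
        assert r.p_exact is None


class TestFriedman:
    def test_identical_rows_null(self):
        r = friedman_stepdown(np.tile([1.0, 1.0, 1.0], (5, 1)))
        assert r.chi2 == 0.0 and r.p == 1.0
        assert r.homogeneous_subsets == ((0, 1, 2),)

    def test_fully_concordant_rows(self):
        # 5 rows x 3 conditions, same strict order: rank sums 5/10/15 -> 10
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        assert friedman_chi2(X).chi2 == pytest.approx(10.0)

    def test_matches_scipy_on_random_data(self, rng):
        X = rng.normal(size=(12, 4))
        ours = friedman_chi2(X)
        chi2, p = stats.friedmanchisquare(*X.T)
        assert ours.chi2 == pytest.approx(chi2, rel=1e-9)
        assert ours.p == pytest.approx(p, rel=1e-9)

    def test_two_conditions_equals_sign_test_statistic(self, rng):
        # with k=2 and no ties, chi2 = (B - A)^2 / n where B,A are the
        # counts of rows preferring each condition (enumeration argument)
        for _ in range(5):
            X = rng.normal(size=(8, 2))
            b = int(np.sum(X[:, 1] > X[:, 0]))
            a = X.shape[0] - b
            expected = (b - a) ** 2 / X.shape[0]
            assert friedman_chi2(X).chi2 == pytest.approx(expected, abs=1e-9)

    def test_incomplete_rows_dropped(self):
        X = np.array([[1, 2, 3], [2, 3, 1], [np.nan, 1, 2], [3, 1, 2]], float)
        with pytest.warns(UserWarning, match="dropped 1"):
            r = friedman_stepdown(X)
        assert r.n_rows == 3 and r.n_dropped == 1

    def test_stepdown_separates_distinct_condition(self, rng):
        # two interchangeable conditions plus one clearly larger one
        n = 20
        X = np.column_stack(
            [rng.normal(0, 1, n), rng.normal(0, 1, n), rng.normal(5, 1, n)]
        )
        r = friedman_stepdown(X, alpha=0.05)
        assert (2,) in r.homogeneous_subsets
        assert any(set(s) == {0, 1} for s in r.homogeneous_subsets)

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            friedman_chi2(np.ones((1, 3)))
        with pytest.raises(ValueError):
            friedman_chi2(np.ones((5, 1)))


class TestDescriptives:
    def test_constant_values_zero_cv(self):
        d = descriptives([86.0, 86.0, 86.0])
        assert d.cv_percent == 0.0

    def test_hand_computed_cv(self):
        # SD 10, mean 90 -> 11.1%
        d = descriptives([80.0, 90.0, 100.0])
        assert d.cv_percent == pytest.approx(100 * 10 / 90, rel=1e-9)

    def test_quantile_convention(self):
        d = descriptives([1, 2, 3, 4, 5])
        assert d.median == 3
        assert d.iqr == pytest.approx(2.0)

    def test_zero_mean_cv_flagged(self):
        with pytest.warns(UserWarning, match="CV undefined"):
            d = descriptives([-1.0, 1.0])
        assert d.cv_percent is None
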