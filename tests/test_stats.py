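"""Nonparametric test battery against hand-computed and enumeration oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from ektopo.stats import (
    chi2_test,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney_u,
    pearson_r,
    wilcoxon_signed_rank,
)


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        # U = 0; exact two-sided p = 2 * 1/C(6,3) = 0.1 (enumeration of 20
        # rank assignments, the two extreme ones at least as extreme)
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_exact_p_matches_enumeration_oracle(self):
        x, y = [1.0, 5.0, 7.0], [2.0, 3.0, 9.0]
        res = mann_whitney_u(x, y)
        # oracle: enumerate all assignments of the pooled ranks to group x
        pooled = np.array(x + y)
        ranks = sps.rankdata(pooled)
        u_obs = sum(1 for xi in x for yi in y if xi > yi)
        n = len(x)
        us = []
        for combo in itertools.combinations(range(len(pooled)), n):
            rx = ranks[list(combo)]
            us.append(rx.sum() - n * (n + 1) / 2)
        us = np.array(us)
        mean_u = len(x) * len(y) / 2
        p_oracle = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)
        assert res.p_value == pytest.approx(p_oracle)

    def test_identical_samples_maximal_p(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value > 0.9

    def test_large_shift_detected(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200) + 1.0
        assert mann_whitney_u(x, y).p_value < 1e-3

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_positive_differences_exact_p(self):
        # n = 6, all differences one sign: p = 2/2^6 = 0.03125
        pre = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        post = [1.5, 2.7, 3.9, 4.4, 5.8, 6.6]
        assert wilcoxon_signed_rank(pre, post).p_value == pytest.approx(2 / 64)

    def test_all_zero_differences_flagged(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_antisymmetric_differences_at_null_center(self):
        pre = np.zeros(6)
        post = np.array([-4.0, -2.0, -1.0, 1.0, 2.0, 4.0])
        res = wilcoxon_signed_rank(pre, post)
        # W+ at its null expectation n(n+1)/4 = 10.5
        assert res.statistic == pytest.approx(10.5)
        assert res.p_value > 0.9

    def test_zero_differences_dropped(self):
        pre = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        post = [1.5, 2.7, 3.9, 4.4, 5.8, 6.6, 7.0]  # last pair ties
        assert wilcoxon_signed_rank(pre, post).p_value == pytest.approx(2 / 64)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])


class TestKruskalWallis:
    def test_identical_groups_null(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_h(self):
        # ranks 1..6, rank sums 3/7/11:
        # H = 12/(6*7) * (9/2 + 49/2 + 121/2) - 3*7 = 32/7
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32.0 / 7.0)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.standard_normal(8) for _ in range(3)]
        res1 = kruskal_wallis(groups)
        res2 = kruskal_wallis([np.exp(g) for g in groups])
        assert res2.statistic == pytest.approx(res1.statistic)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDunn:
    def test_identical_pair_has_unit_p(self):
        res = dunn_posthoc([[1, 2, 3], [1, 2, 3], [10, 11, 12]], ("a", "b", "c"))
        pair = next(r for r in res if set(r.group_labels) == {"a", "b"})
        assert abs(pair.statistic) < 1e-12
        assert pair.p_value == pytest.approx(1.0)

    def test_bonferroni_multiplies_and_caps(self, rng):
        groups = [rng.standard_normal(6) + d for d in (0.0, 0.3, 3.0)]
        raw = dunn_posthoc(groups, adjust="none")
        adj = dunn_posthoc(groups, adjust="bonferroni")
        for r, a in zip(raw, adj):
            assert a.p_value == pytest.approx(min(1.0, 3 * r.p_value))
            assert a.p_value >= r.p_value
            assert a.adjusted and not r.adjusted

    def test_z_ordering_matches_permutation_oracle(self, rng):
        groups = [rng.standard_normal(5) + d for d in (0.0, 0.8, 2.0)]
        res = dunn_posthoc(groups, adjust="none")

        # oracle: permutation distribution of pairwise mean-rank gaps
        pooled = np.concatenate(groups)
        sizes = [len(g) for g in groups]
        obs_ranks = sps.rankdata(pooled)
        bounds = np.cumsum([0] + sizes)

        def gaps(ranks):
            means = [ranks[bounds[i]: bounds[i + 1]].mean() for i in range(3)]
            return [abs(means[i] - means[j]) for i, j in itertools.combinations(range(3), 2)]

        obs = gaps(obs_ranks)
        perm_rng = np.random.default_rng(0)
        exceed = np.zeros(3)
        reps = 3000
        for _ in range(reps):
            perm = perm_rng.permutation(obs_ranks)
            exceed += np.array(gaps(perm)) >= np.array(obs) - 1e-12
        p_perm = exceed / reps
        p_dunn = np.array([r.p_value for r in res])
        # same ordering of evidence across the three pairs
        assert list(np.argsort(p_dunn)) == list(np.argsort(p_perm))
        assert np.abs(p_dunn - p_perm).max() < 0.1


class TestChi2:
    def test_no_association(self):
        res = chi2_test([[5, 5], [5, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_study_demographic_tables(self):
        # right/left eye by group: 14/4, 13/6, 14/9 -> p = 0.513 as published
        res = chi2_test([[14, 4], [13, 6], [14, 9]])
        assert res.p_value == pytest.approx(0.513, abs=5e-3)
        # male/female by group: hand-computed Pearson chi2 = 0.955, p = 0.620
        res = chi2_test([[6, 12], [4, 15], [5, 18]])
        assert res.statistic == pytest.approx(0.9552, abs=2e-3)
        assert res.p_value == pytest.approx(0.6203, abs=2e-3)

    def test_doubling_counts_doubles_statistic(self):
        t = np.array([[6, 12], [4, 15], [5, 18]])
        assert chi2_test(2 * t).statistic == pytest.approx(2 * chi2_test(t).statistic)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_test([[0, 0], [3, 4]])


class TestPearson:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_r(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_worked_set(self):
        # cov = 0.75 per pair sum 3; sd products 5 -> r = 3/5
        res = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)

    def test_independent_near_zero(self, rng):
        res = pearson_r(rng.standard_normal(2000), rng.standard_normal(2000))
        assert abs(res.r) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1.0, 2.0], [1.0, 2.0])


class TestResultContainers:
    def test_p_value_range_enforced(self):
        from ektopo.stats import ComparisonResult, CorrelationResult

        with pytest.raises(ValueError):
            ComparisonResult("t", 0.0, 1.5, ("a", "b"), (3, 3))
        with pytest.raises(ValueError):
            ComparisonResult("t", 0.0, 0.5, ("a", "b"), (0, 3))
        with pytest.raises(ValueError):
            CorrelationResult(("x", "y"), 1.2, 0.5)
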