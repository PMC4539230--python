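"""Rank tests, Spearman, and the correlation-difference permutation test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from sexdisc.stats import (
    corr_diff_statistic,
    exhaustive_corr_diff_null,
    median_iqr,
    permutation_corr_diff,
    rank_with_ties,
    spearman,
    wilcoxon_rank_sum,
)


def exact_rank_sum_p(a, b):
    """Exhaustive two-sided rank-sum p: enumerate every group assignment."""
    pooled = np.concatenate([a, b])
    ranks = rank_with_ties(pooled)
    n, n_a = pooled.size, len(a)
    expected = n_a * (n + 1) / 2.0
    observed = abs(ranks[:n_a].sum() - expected)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - expected) >= observed - 1e-9:
            hits += 1
    return hits / total


class TestRanking:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((10, 20, 30), (1, 2, 3)),
            ((5, 5), (1.5, 1.5)),
            ((1, 2, 2, 3), (1, 2.5, 2.5, 4)),
        ],
    )
    def test_average_ranks(self, values, expected):
        assert np.allclose(rank_with_ties(values), expected)

    def test_ranks_sum_to_triangular_number(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 5, size=30)  # heavy ties
        assert rank_with_ties(vals).sum() == pytest.approx(30 * 31 / 2)


class TestWilcoxon:
    def test_fully_separated_small_groups(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        # W = 6, E = 10.5, var = 5.25
        assert res.z == pytest.approx(-4.5 / math.sqrt(5.25), abs=1e-9)
        assert res.z == pytest.approx(-1.964, abs=1e-3)

    def test_exact_enumeration_of_separated_groups(self):
        assert exact_rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.100)

    def test_identical_groups_give_null_result(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.z == 0.0 and res.p_two_sided == 1.0

    def test_degenerate_all_tied_warns(self):
        with pytest.warns(UserWarning, match="identical"):
            res = wilcoxon_rank_sum([2, 2, 2], [2, 2, 2])
        assert res.z == 0.0 and res.p_two_sided == 1.0

    def test_swap_negates_z_and_mean_rank_diff(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(10), rng.random(12) + 0.2
        r1 = wilcoxon_rank_sum(a, b)
        r2 = wilcoxon_rank_sum(b, a)
        assert r1.z == pytest.approx(-r2.z)
        assert r1.mean_rank_diff == pytest.approx(-r2.mean_rank_diff)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)

    @pytest.mark.parametrize("n_a,n_b,seed", [(3, 3, 4), (4, 4, 0), (5, 4, 1), (6, 6, 2), (5, 6, 3)])
    def test_normal_approximation_tracks_exact_distribution(self, n_a, n_b, seed):
        # at these sizes the W lattice spacing is ~0.09 sd, so the
        # half-lattice continuity correction is what keeps the normal
        # approximation within 0.05 of the exact discrete distribution
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n_a)
        b = rng.normal(loc=0.8, size=n_b)  # all-distinct samples
        approx = wilcoxon_rank_sum(a, b, continuity=True).p_two_sided
        assert abs(approx - exact_rank_sum_p(a, b)) <= 0.05

    def test_tie_correction_matches_mann_whitney(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 6, size=40)
        b = rng.integers(1, 7, size=35)
        ours = wilcoxon_rank_sum(a, b).p_two_sided
        ref = sps.mannwhitneyu(a, b, use_continuity=False, method="asymptotic").pvalue
        assert ours == pytest.approx(ref, abs=1e-10)


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 5, 9]
        assert spearman(x, [2, 4, 8, 9]).rho == pytest.approx(1.0)
        assert spearman(x, [9, 8, 4, 2]).rho == pytest.approx(-1.0)

    def test_hand_computed_rho(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]).rho == pytest.approx(0.8)

    def test_equals_pearson_on_ranks_and_no_ties_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.random(25)
        y = rng.random(25)
        res = spearman(x, y)
        rx, ry = rank_with_ties(x), rank_with_ties(y)
        assert res.rho == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)
        n = len(x)
        d2 = np.sum((rx - ry) ** 2)
        assert res.rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)), abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 8, size=60)
        y = rng.integers(0, 8, size=60)
        res = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)

    def test_constant_vector_flagged_undefined(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.defined and math.isnan(res.rho)


class TestCorrDiff:
    def test_identical_groups_zero(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        assert corr_diff_statistic(x, y, x, y) == 0.0

    def test_concordant_minus_discordant_is_two(self):
        assert corr_diff_statistic([1, 2, 3], [1, 2, 3], [1, 2, 3], [3, 2, 1]) == pytest.approx(2.0)

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(9)
        xa, ya = rng.random(8), rng.random(8)
        xb, yb = rng.random(10), rng.random(10)
        assert corr_diff_statistic(xa, ya, xb, yb) == pytest.approx(
            -corr_diff_statistic(xb, yb, xa, ya)
        )


class TestExhaustiveNull:
    def test_identical_groups_p_is_one(self):
        x, y = [1, 2, 3], [3, 1, 2]
        assert exhaustive_corr_diff_null(x, y, x, y).p_two_sided == 1.0

    def test_concordant_vs_discordant_hand_count(self):
        # pooled pairs contain (2,2) twice, so 4 of the C(6,3)=20 splits
        # reach |rho_A - rho_B| = 2: the observed split, its mirror, and the
        # two obtained by exchanging the duplicated pair
        res = exhaustive_corr_diff_null([1, 2, 3], [1, 2, 3], [1, 2, 3], [3, 2, 1])
        assert res.exhaustive and res.n_resamples == 20
        assert res.p_two_sided == pytest.approx(4 / 20)

    def test_invariant_under_group_swap(self):
        rng = np.random.default_rng(2)
        xa, ya = rng.random(4), rng.random(4)
        xb, yb = rng.random(5), rng.random(5)
        p1 = exhaustive_corr_diff_null(xa, ya, xb, yb).p_two_sided
        p2 = exhaustive_corr_diff_null(xb, yb, xa, ya).p_two_sided
        assert p1 == pytest.approx(p2)

    def test_bound_on_combinations_enforced(self):
        x = np.arange(40.0)
        with pytest.raises(ValueError, match="exceed"):
            exhaustive_corr_diff_null(x, x, x, x[::-1])


class TestPermutationTest:
    def test_identical_pair_sets_give_p_one(self):
        x, y = [1, 2, 3, 4], [2, 4, 1, 3]
        res = permutation_corr_diff(x, y, x, y, n_resamples=500, seed=0)
        assert res.observed_diff == 0.0 and res.p_two_sided == 1.0

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(12)
        xa, ya = rng.random(20), rng.random(20)
        xb, yb = rng.random(25), rng.random(25)
        r1 = permutation_corr_diff(xa, ya, xb, yb, n_resamples=2_000, seed=42)
        r2 = permutation_corr_diff(xa, ya, xb, yb, n_resamples=2_000, seed=42)
        assert r1 == r2

    def test_monte_carlo_converges_to_exhaustive_small_n(self):
        xa, ya = [1, 2, 3], [1, 2, 3]
        xb, yb = [1, 2, 3], [3, 2, 1]
        exact = exhaustive_corr_diff_null(xa, ya, xb, yb).p_two_sided
        mc = permutation_corr_diff(xa, ya, xb, yb, n_resamples=100_000, seed=5).p_two_sided
        assert abs(mc - exact) <= 0.01

    def test_row_order_of_inputs_is_irrelevant(self):
        rng = np.random.default_rng(21)
        xa, ya = rng.random(12), rng.random(12)
        xb, yb = rng.random(12), rng.random(12)
        r1 = permutation_corr_diff(xa, ya, xb, yb, n_resamples=3_000, seed=9)
        perm = rng.permutation(12)
        r2 = permutation_corr_diff(xa[perm], ya[perm], xb, yb, n_resamples=3_000, seed=9)
        assert r1.p_two_sided == r2.p_two_sided

    def test_two_sided_p_stable_under_group_swap(self):
        rng = np.random.default_rng(13)
        xa, ya = rng.random(15), rng.random(15)
        xb = rng.random(15)
        yb = 0.5 * xb + 0.5 * rng.random(15)
        r1 = permutation_corr_diff(xa, ya, xb, yb, n_resamples=40_000, seed=3)
        r2 = permutation_corr_diff(xb, yb, xa, ya, n_resamples=40_000, seed=3)
        assert abs(r1.p_two_sided - r2.p_two_sided) <= 0.01  # Monte-Carlo jitter only

    def test_degenerate_observed_group_propagates_error(self):
        xa, ya = [1.0, 2.0, 3.0], [5.0, 5.0, 5.0]  # constant y: rho undefined
        xb, yb = [1.0, 2.0, 3.0], [5.0, 5.0, 7.0]
        with pytest.raises(ValueError, match="zero rank variance"):
            permutation_corr_diff(xa, ya, xb, yb, n_resamples=100, seed=0)

    def test_degenerate_resamples_counted_and_zeroed(self):
        # pooled y holds four 5s: relabelings that gather three of them in
        # one group make that group's correlation undefined
        xa, ya = [1.0, 2.0, 3.0], [5.0, 5.0, 7.0]
        xb, yb = [1.0, 2.0, 3.0], [5.0, 5.0, 6.0]
        exact = exhaustive_corr_diff_null(xa, ya, xb, yb)
        assert exact.n_degenerate > 0
        mc = permutation_corr_diff(xa, ya, xb, yb, n_resamples=50_000, seed=1)
        assert mc.n_degenerate > 0
        assert abs(mc.p_two_sided - exact.p_two_sided) <= 0.01

    def test_plus_one_estimator_never_zero(self):
        xa, ya = [1, 2, 3, 4], [1, 2, 3, 4]
        xb, yb = [1, 2, 3, 4], [4, 3, 2, 1]
        res = permutation_corr_diff(xa, ya, xb, yb, n_resamples=50, seed=0, plus_one=True)
        assert res.p_two_sided > 0


class TestMedianIQR:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((1, 2, 3, 4, 5), (3, 2, 4)),
            ((7,), (7, 7, 7)),
            ((1, 2, 3, 4), (2.5, 1.75, 3.25)),
        ],
    )
    def test_linear_interpolation_convention(self, values, expected):
        assert median_iqr(values) == pytest.approx(expected)
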