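"""Statistical machinery: permutation test, 2D KS, Spearman, Holm."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from dreamppl import (
    holm_adjust,
    ks2d_pvalue,
    ks2d_statistic,
    ks2d_test,
    permutation_test_1d,
    spearman,
)
from dreamppl.errors import InvalidArgumentError

from .oracles import exhaustive_perm_pvalue, holm_oracle, ks2d_oracle, spearman_oracle


class TestPermutation1D:
    def test_identical_samples_give_zero_stat_and_p_one(self):
        a = [1.0, 2.0, 3.0]
        res = permutation_test_1d(a, list(a), n_permutations=200, seed=1)
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_label_swap_symmetry(self):
        a, b = [0.0, 1.0, 2.0], [5.0, 6.0, 7.0, 8.0]
        # swapping labels leaves the pooled values and group sizes' roles
        # symmetric: statistics agree exactly, p-values agree in distribution
        r1 = permutation_test_1d(a, b, n_permutations=500, seed=3)
        r2 = permutation_test_1d(b, a, n_permutations=500, seed=3)
        assert r1.statistic == r2.statistic
        assert abs(r1.p_raw - r2.p_raw) <= 0.05

    def test_exact_mode_matches_exhaustive_oracle(self):
        a, b = [0.0, 0.0, 0.0], [1.0, 1.0, 1.0]
        res = permutation_test_1d(a, b, method="exact")
        assert res.n_permutations == 20  # C(6, 3)
        assert res.p_raw == pytest.approx(exhaustive_perm_pvalue(a, b))
        assert res.p_raw == pytest.approx(2 / 20)

    def test_exact_mode_random_inputs_match_oracle(self, rng):
        for _ in range(5):
            a = list(rng.normal(size=4))
            b = list(rng.normal(size=3))
            res = permutation_test_1d(a, b, method="exact")
            assert res.p_raw == pytest.approx(exhaustive_perm_pvalue(a, b))

    def test_seed_reproducibility(self):
        a, b = [1.0, 2.0], [2.5, 3.5, 1.0]
        r1 = permutation_test_1d(a, b, n_permutations=300, seed=42)
        r2 = permutation_test_1d(a, b, n_permutations=300, seed=42)
        assert r1.p_raw == r2.p_raw

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            permutation_test_1d([], [1.0], n_permutations=10, seed=0)

    def test_type_one_error_calibrated(self, rng):
        """Null rejection rate at alpha=0.05 stays near nominal."""
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            a = rng.normal(size=30)
            b = rng.normal(size=30)
            res = permutation_test_1d(
                a, b, n_permutations=199, seed=int(rng.integers(2**31))
            )
            rejections += res.p_raw <= 0.05
        assert 0.025 <= rejections / n_rep <= 0.075

    def test_power_against_one_sd_shift(self, rng):
        """A 1-SD mean shift at n=50 is detected almost always."""
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(size=50)
            b = rng.normal(loc=1.0, size=50)
            res = permutation_test_1d(
                a, b, n_permutations=199, seed=int(rng.integers(2**31))
            )
            rejections += res.p_raw <= 0.05
        assert rejections / n_rep > 0.9


class TestKS2D:
    def test_identical_samples_give_zero(self, rng):
        s = rng.normal(size=(12, 2))
        assert ks2d_statistic(s, s.copy()) == 0.0

    def test_fully_separated_clouds_give_one(self):
        # anti-diagonal separation (s1 upper-left, s2 lower-right): each
        # sample has a center whose off-diagonal quadrant holds the entire
        # other sample and none of its own, so D reaches its maximum of 1
        s1 = [(-float(i), float(i)) for i in range(1, 11)]
        s2 = [(float(i), -float(i)) for i in range(1, 11)]
        assert ks2d_statistic(s1, s2) == pytest.approx(1.0)

    def test_same_quadrant_separation_approaches_one(self, rng):
        # opposite-diagonal clouds: the center always sits in its own
        # closed lower-left quadrant, so D = 1 - 1/(2n) exactly, -> 1
        s1 = [(-float(i), -float(i)) for i in range(1, 11)]
        s2 = [(float(i), float(i)) for i in range(1, 11)]
        assert ks2d_statistic(s1, s2) == pytest.approx(1.0 - 1 / 20)

    def test_toy_clouds_match_double_loop_oracle(self):
        s1 = [(0.0, 0.0), (1.0, 1.0), (2.0, 0.5), (0.5, 2.0), (1.5, 1.5)]
        s2 = [(0.2, 0.1), (0.9, 1.2), (2.1, 0.4), (3.0, 3.0), (1.4, 1.6)]
        assert ks2d_statistic(s1, s2) == pytest.approx(ks2d_oracle(s1, s2), abs=1e-12)

    def test_random_samples_match_oracle(self, rng):
        """Vectorised statistic equals the brute-force quadrant loop,
        including on integer-valued (tie-heavy) coordinates."""
        for trial in range(30):
            n, m = int(rng.integers(2, 31)), int(rng.integers(2, 31))
            if trial % 2:
                s1 = rng.integers(0, 5, size=(n, 2)).astype(float)
                s2 = rng.integers(0, 5, size=(m, 2)).astype(float)
            else:
                s1 = rng.normal(size=(n, 2))
                s2 = rng.normal(size=(m, 2))
            assert ks2d_statistic(s1, s2) == pytest.approx(
                ks2d_oracle(s1.tolist(), s2.tolist()), abs=1e-12
            )

    def test_symmetry(self, rng):
        s1, s2 = rng.normal(size=(15, 2)), rng.normal(size=(9, 2))
        assert ks2d_statistic(s1, s2) == ks2d_statistic(s2, s1)

    def test_monotone_transform_invariance(self, rng):
        s1, s2 = rng.normal(size=(20, 2)), rng.normal(size=(20, 2))
        d0 = ks2d_statistic(s1, s2)
        t1, t2 = s1.copy(), s2.copy()
        t1[:, 0] = np.exp(t1[:, 0])
        t2[:, 0] = np.exp(t2[:, 0])
        assert ks2d_statistic(t1, t2) == pytest.approx(d0, abs=1e-12)

    def test_zero_statistic_gives_p_one(self):
        assert ks2d_pvalue(0.0, 50, 50, mode="analytic") == pytest.approx(1.0)

    def test_permutation_mode_identical_samples_p_near_one(self, rng):
        s = rng.normal(size=(15, 2))
        p = ks2d_pvalue(
            0.0, 15, 15, mode="permutation", n_permutations=100, seed=0,
            sample1=s, sample2=s.copy(),
        )
        assert p > 0.5

    def test_analytic_close_to_permutation_for_shifted_gaussians(self, rng):
        s1 = rng.normal(size=(100, 2))
        s2 = rng.normal(loc=1.0, size=(100, 2))
        d = ks2d_statistic(s1, s2)
        p_perm = ks2d_pvalue(
            d, 100, 100, mode="permutation", n_permutations=400, seed=1,
            sample1=s1, sample2=s2,
        )
        p_ana = ks2d_pvalue(d, 100, 100, mode="analytic", sample1=s1, sample2=s2)
        assert abs(p_ana - p_perm) <= 0.05

    def test_small_sample_analytic_warns(self, rng):
        with pytest.warns(UserWarning, match="unreliable"):
            ks2d_pvalue(0.5, 5, 5, mode="analytic")

    def test_result_record_carries_sizes(self, rng):
        res = ks2d_test(rng.normal(size=(8, 2)), rng.normal(size=(40, 2)))
        assert (res.n1, res.n2) == (8, 40)
        assert res.statistic_name == "D2"


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        res = spearman([1, 2, 3, 4], [5, 4, 3, 1])
        assert res.rho == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 3.0, 6.0, 5.0]
        res = spearman(x, y)
        assert res.rho == pytest.approx(spearman_oracle(x, y), rel=1e-12)

    def test_constant_input_flagged_missing(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.constant_input and math.isnan(res.rho)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spearman([1.0, 2.0], [2.0, 1.0])


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == [0.03]

    def test_two_values_closed_form(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_three_equal_values_closed_form(self):
        assert holm_adjust([0.05, 0.05, 0.05]) == pytest.approx([0.15, 0.15, 0.15])

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            holm_adjust([0.5, 1.2])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(size=int(rng.integers(1, 12)))
            mine = holm_adjust(p)
            ref = multipletests(p, method="holm")[1]
            assert mine == pytest.approx(ref.tolist(), rel=1e-12)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
def test_holm_matches_closed_form_and_is_monotone(p_values):
    """Adjusted p-values equal the textbook step-down, never decrease
    relative to raw, and respect the raw ordering."""
    adj = holm_adjust(p_values)
    assert adj == pytest.approx(holm_oracle(p_values), rel=1e-12)
    assert all(a >= p - 1e-15 for a, p in zip(adj, p_values))
    for i in range(len(p_values)):
        for j in range(len(p_values)):
            if p_values[i] < p_values[j]:
                assert adj[i] <= adj[j] + 1e-15
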