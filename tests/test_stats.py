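"""Statistical primitives against hand-derived and enumeration oracles."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb
from scipy.stats import hypergeom, rankdata

from microhost import (DegenerateInputError, bh_adjust, chi_square_test,
                       fisher_exact, spearman_rho, t_test, wilcoxon_rank_sum)


class TestSpearman:
    def test_identity_and_antitone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_textbook_value(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2)=4 at n=5
        assert spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=12,
                    unique=True))
    def test_invariant_under_monotone_transform(self, x):
        x = np.asarray(x, dtype=float)
        y = np.linspace(0, 1, len(x)) ** 2
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x / 500.0), y) == pytest.approx(base)
        assert spearman_rho(x, 3.0 * y + 2.0) == pytest.approx(base)


class TestTTest:
    def test_identical_groups_give_t0_p1(self):
        r = t_test([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_pooled_variance_hand_example(self):
        r = t_test([1, 2, 3], [4, 5, 6], variant="student")
        assert r.statistic == pytest.approx(-3.674, abs=1e-3)
        assert r.df == pytest.approx(4)
        assert r.p_value == pytest.approx(0.0213, abs=1e-3)

    def test_constant_groups_conventions(self):
        r = t_test([2.0, 2.0], [2.0, 2.0])
        assert (r.statistic, r.p_value) == (0.0, 1.0)
        with pytest.raises(DegenerateInputError):
            t_test([2.0, 2.0], [3.0, 3.0])

    def test_null_type_i_error_calibrated(self, rng):
        hits = sum(
            t_test(rng.normal(size=5), rng.normal(size=5)).p_value < 0.05
            for _ in range(200)
        )
        assert 0.01 <= hits / 200 <= 0.10


class TestWilcoxon:
    def test_exact_small_sample(self):
        # all C(4,2)=6 rank assignments; observed rank sum 3 is the minimum
        r = wilcoxon_rank_sum([1, 2], [3, 4])
        assert r.p_value == pytest.approx(1 / 3)

    def test_same_multiset_p1(self):
        r = wilcoxon_rank_sum([1, 2, 3], [3, 1, 2])
        assert r.p_value == pytest.approx(1.0)

    def test_all_tied_p1(self):
        assert wilcoxon_rank_sum([5, 5], [5, 5, 5]).p_value == 1.0

    def test_exact_agrees_with_independent_enumeration(self, rng):
        for _ in range(10):
            a = rng.integers(0, 6, size=4).astype(float)
            b = rng.integers(0, 6, size=5).astype(float)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            got = wilcoxon_rank_sum(a, b).p_value
            pooled = np.concatenate([a, b])
            ranks = rankdata(pooled)
            w_obs = ranks[:4].sum()
            sums = [sum(ranks[list(c)]) for c in combinations(range(9), 4)]
            lo = sum(s <= w_obs + 1e-9 for s in sums) / len(sums)
            hi = sum(s >= w_obs - 1e-9 for s in sums) / len(sums)
            assert got == pytest.approx(min(1.0, 2 * min(lo, hi)))

    def test_exact_close_to_normal_approximation(self, rng):
        # n=6/6 sits at the exact/approximate boundary; the two should agree
        from scipy.stats import mannwhitneyu
        for _ in range(10):
            a = rng.normal(size=6)
            b = rng.normal(size=6) + 0.5
            exact = wilcoxon_rank_sum(a, b).p_value
            asym = mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic").pvalue
            assert abs(exact - asym) <= 0.02


class TestBH:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
           st.sampled_from([0.01, 0.05, 0.1, 0.2]))
    def test_rejection_set_matches_classical_step_up(self, pvals, alpha):
        """Rejecting q <= alpha must equal the BH step-up rejection rule."""
        q = bh_adjust(pvals)
        m = len(pvals)
        order = np.argsort(pvals, kind="mergesort")
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= alpha * rank / m:
                k_max = rank
        expected = np.zeros(m, bool)
        expected[order[:k_max]] = True
        np.testing.assert_array_equal(q <= alpha + 1e-12, expected)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_q_at_least_p_and_monotone_in_rank(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestChiSquare:
    def test_no_correction_df2_stage_table(self):
        r = chi_square_test([[10, 7, 0], [18, 0, 1]], yates=False)
        assert r.statistic == pytest.approx(10.21, abs=0.01)
        assert r.df == 2
        assert r.p_value == pytest.approx(0.006, abs=5e-4)

    def test_yates_clamps_to_zero(self):
        r = chi_square_test([[6, 9], [6, 10]], yates=True)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_proportional_rows_independent(self):
        r = chi_square_test([[10, 20, 30], [1, 2, 3]], yates=False)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_yates_restricted_to_2x2(self):
        with pytest.raises(ValueError):
            chi_square_test([[1, 2, 3], [4, 5, 6]], yates=True)

    @settings(max_examples=50, derandomize=True)
    @given(st.tuples(*[st.integers(1, 20)] * 4))
    def test_uncorrected_2x2_closed_form(self, cells):
        a, b, c, d = cells
        r = chi_square_test([[a, b], [c, d]], yates=False)
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert r.statistic == pytest.approx(closed)


def _fisher_enumeration_p(table):
    """Two-sided Fisher by full enumeration over margin-consistent tables."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = hypergeom.pmf(x, n, r1, c1)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


class TestFisher:
    def test_symmetric_table_p1(self):
        assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_tiny_enumeration_value(self):
        assert fisher_exact([[2, 0], [0, 2]]).p_value == pytest.approx(1 / 3)

    def test_zero_margin_convention(self):
        assert fisher_exact([[0, 0], [3, 4]]).p_value == 1.0

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 31))
            cells = rng.multinomial(n, [0.25] * 4)
            table = [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
            if min(sum(table[0]), sum(table[1]),
                   table[0][0] + table[1][0], table[0][1] + table[1][1]) == 0:
                continue
            assert fisher_exact(table).p_value == pytest.approx(
                _fisher_enumeration_p(table), abs=1e-10)
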