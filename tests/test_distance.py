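"""Unit and property tests for the copula Cramér–von Mises distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copclust import (InvalidInputError, InvalidLagError, Panel, TimeSeries,
                      WeightScheme, cvm_grid_oracle, distance_matrix,
                      empirical_copula, l_statistic, lag_distance,
                      pseudo_pairs, weighted_distance)


class TestPseudoPairs:
    @pytest.mark.parametrize(
        "values, U, V",
        [([1.0, 2.0, 3.0], [0.25, 0.50], [0.50, 0.75]),
         ([3.0, 1.0, 2.0], [0.75, 0.25], [0.25, 0.50])],
    )
    def test_rank_construction(self, values, U, V):
        p = pseudo_pairs(TimeSeries("x", values), h=1)
        np.testing.assert_allclose(p.U, U)
        np.testing.assert_allclose(p.V, V)

    def test_full_sample_cdf_and_grid(self):
        """U,V use the whole-series CDF, so all values are multiples of 1/(T+1)."""
        rng = np.random.default_rng(0)
        s = TimeSeries("x", rng.standard_normal(37))
        p = pseudo_pairs(s, h=3)
        assert len(p.U) == len(p.V) == 34
        for arr in (p.U, p.V):
            assert np.all((arr > 0) & (arr < 1))
            np.testing.assert_allclose(arr * 38, np.round(arr * 38), atol=1e-9)

    def test_monotone_transform_gives_identical_pairs(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(40)
        p1 = pseudo_pairs(TimeSeries("x", x), h=2)
        p2 = pseudo_pairs(TimeSeries("x", np.exp(x)), h=2)
        assert np.array_equal(p1.U, p2.U) and np.array_equal(p1.V, p2.V)

    def test_invalid_lag(self):
        with pytest.raises(InvalidLagError):
            pseudo_pairs(TimeSeries("x", [1.0, 2.0, 3.0]), h=3)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            TimeSeries("x", [1.0, np.nan, 3.0])

    def test_average_ties_option(self):
        p_max = pseudo_pairs(TimeSeries("x", [1.0, 1.0, 2.0]), h=1, ties="max")
        p_avg = pseudo_pairs(TimeSeries("x", [1.0, 1.0, 2.0]), h=1, ties="average")
        np.testing.assert_allclose(p_max.U, [0.5, 0.5])
        np.testing.assert_allclose(p_avg.U, [0.375, 0.375])


class TestEmpiricalCopula:
    @pytest.mark.parametrize("uv, expected", [((1.0, 1.0), 1.0),
                                              ((0.3, 0.6), 0.5),
                                              ((0.1, 0.6), 0.0)])
    def test_point_evaluations(self, uv, expected, micro_pair):
        p = pseudo_pairs(micro_pair[0], h=1)
        assert empirical_copula(p, *uv) == expected

    def test_monotone_in_each_argument(self):
        rng = np.random.default_rng(2)
        p = pseudo_pairs(TimeSeries("x", rng.standard_normal(30)), h=1)
        grid = np.linspace(0, 1, 21)
        C = empirical_copula(p, grid[:, None], grid[None, :])
        assert np.all(np.diff(C, axis=0) >= 0) and np.all(np.diff(C, axis=1) >= 0)


class TestClosedForm:
    def test_micro_example_l_statistics(self, micro_pair):
        X, Y = micro_pair
        pX, pY = pseudo_pairs(X, 1), pseudo_pairs(Y, 1)
        assert l_statistic(pX, pX) == 0.1875
        assert l_statistic(pX, pY) == 0.171875
        assert l_statistic(pY, pX) == 0.171875
        assert l_statistic(pY, pY) == 0.203125

    def test_micro_example_distance(self, micro_pair):
        assert lag_distance(*micro_pair, h=1) == 0.046875

    def test_lag_mismatch_rejected(self, micro_pair):
        X, _ = micro_pair
        s = TimeSeries("z", np.arange(10.0))
        with pytest.raises(InvalidInputError):
            l_statistic(pseudo_pairs(X, 1), pseudo_pairs(s, 2))

    def test_identical_and_rank_equivalent_series(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        a = TimeSeries("a", x)
        assert lag_distance(a, TimeSeries("b", x.copy()), 1) == 0.0
        assert lag_distance(a, TimeSeries("c", np.log(x - x.min() + 1.0)), 1) == 0.0

    def test_matches_grid_oracle_on_random_pairs(self):
        """Closed form equals the quadrature of the squared copula difference."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = TimeSeries("a", rng.standard_normal(50))
            b = TimeSeries("b", np.cumsum(rng.standard_normal(50)) * 0.1
                           + rng.standard_normal(50))
            closed = lag_distance(a, b, 1)
            grid = cvm_grid_oracle(pseudo_pairs(a, 1), pseudo_pairs(b, 1), m=2000)
            assert abs(closed - grid) < 1e-3

    def test_grid_oracle_converges(self):
        rng = np.random.default_rng(5)
        a, b = (TimeSeries(s, rng.standard_normal(50)) for s in "ab")
        closed = lag_distance(a, b, 1)
        pa, pb = pseudo_pairs(a, 1), pseudo_pairs(b, 1)
        errs = [abs(cvm_grid_oracle(pa, pb, m) - closed) for m in (250, 500, 1000)]
        assert errs[0] >= errs[1] >= errs[2]

    def test_unequal_lengths_supported(self):
        rng = np.random.default_rng(6)
        a = TimeSeries("a", rng.standard_normal(40))
        b = TimeSeries("b", rng.standard_normal(70))
        d = lag_distance(a, b, 1)
        assert 0.0 <= d <= 1.0
        assert d == lag_distance(b, a, 1)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=40, unique=True),
           st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=40, unique=True))
    def test_bounds_and_symmetry(self, xs, ys):
        a, b = TimeSeries("a", xs), TimeSeries("b", ys)
        pa, pb = pseudo_pairs(a, 1), pseudo_pairs(b, 1)
        lab = l_statistic(pa, pb)
        assert 0.0 <= lab <= 1.0
        assert lab == l_statistic(pb, pa)
        d = lag_distance(a, b, 1)
        assert 0.0 <= d <= 1.0


class TestWeightedDistance:
    def test_single_lag_reduces_to_lag_distance(self, micro_pair):
        X, Y = micro_pair
        a = TimeSeries("a", np.arange(20.0) % 7)
        b = TimeSeries("b", (np.arange(20.0) * 3) % 11)
        assert weighted_distance(a, b, WeightScheme.uniform(1)) == lag_distance(a, b, 1)

    def test_zero_weights_select_single_lag(self):
        rng = np.random.default_rng(7)
        a, b = (TimeSeries(s, rng.standard_normal(30)) for s in "ab")
        scheme = WeightScheme(K=2, weights=(0.0, 1.0))
        assert weighted_distance(a, b, scheme) == lag_distance(a, b, 2)

    def test_uniform_weights_are_additive(self):
        rng = np.random.default_rng(8)
        a, b = (TimeSeries(s, rng.standard_normal(50)) for s in "ab")
        total = weighted_distance(a, b, WeightScheme.uniform(2))
        assert total == pytest.approx(lag_distance(a, b, 1) + lag_distance(a, b, 2),
                                      abs=1e-15)

    def test_oversized_K_rejected(self):
        a = TimeSeries("a", np.arange(5.0))
        b = TimeSeries("b", np.arange(5.0)[::-1])
        with pytest.raises(InvalidLagError):
            weighted_distance(a, b, WeightScheme.uniform(5))


class TestDistanceMatrix:
    def test_duplicated_series_give_zero_matrix(self):
        x = np.arange(12.0) % 5
        panel = Panel(tuple(TimeSeries(f"s{i}", x) for i in range(3)))
        D = distance_matrix(panel)
        np.testing.assert_array_equal(D.values, np.zeros((3, 3)))

    def test_micro_pair_entry(self, micro_pair):
        D = distance_matrix(Panel(micro_pair))
        assert D.values[0, 1] == 0.046875

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(9)
        panel = Panel(tuple(TimeSeries(f"s{i}", rng.standard_normal(30))
                            for i in range(6)))
        D = distance_matrix(panel, WeightScheme.uniform(2))
        assert np.array_equal(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0)

    def test_rank_invariance_of_whole_matrix(self):
        rng = np.random.default_rng(10)
        xs = [rng.standard_normal(40) for _ in range(5)]
        p1 = Panel(tuple(TimeSeries(f"s{i}", x) for i, x in enumerate(xs)))
        p2 = Panel(tuple(TimeSeries(f"s{i}", np.arctan(x) * 3 + 7)
                         for i, x in enumerate(xs)))
        np.testing.assert_array_equal(distance_matrix(p1).values,
                                      distance_matrix(p2).values)

    def test_sqrt_distance_triangle_inequality(self):
        """sqrt(D) is a proper metric (L2 norm of the copula difference)."""
        rng = np.random.default_rng(11)
        panel = Panel(tuple(TimeSeries(f"s{i}", rng.standard_normal(40))
                            for i in range(8)))
        R = np.sqrt(distance_matrix(panel).values)
        n = R.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert R[i, j] <= R[i, k] + R[k, j] + 1e-12

    def test_too_few_series_rejected(self):
        with pytest.raises(InvalidInputError):
            distance_matrix(Panel((TimeSeries("a", np.arange(10.0)),)))
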