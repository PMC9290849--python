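"""Pushing hyperrectangles through black-box models."""

import numpy as np
import pytest
from scipy import stats

import pba
from pba import (BlackBoxModel, MinimalData, OutcomePBox, Parameter,
                 empirical_outcome_pbox, make_pbox, optimize_on_box,
                 propagate_mixed, propagate_pba, slice_pbox)
from pba.errors import EvaluationError, InvalidInputError
from pba.slicing import Hyperrectangle


def box(*intervals, mass=1.0):
    return Hyperrectangle(index=(0,) * len(intervals),
                          intervals=tuple(intervals), mass=mass)


def model_of(func, n_params, monotone=None, vectorized=False, support=(0, 1)):
    mono = monotone or [None] * n_params
    params = tuple(
        Parameter(f"x{i}", "pbox", data=MinimalData(*support), monotone=mono[i])
        for i in range(n_params))
    return BlackBoxModel(evaluator=func, parameters=params,
                         vectorized=vectorized, name="test")


class TestOptimizeOnBox:
    def test_linear_sum_all_methods_agree(self):
        m = model_of(lambda v: v[0] + v[1], 2,
                     monotone=["increasing", "increasing"], support=(0, 3))
        b = box((0, 1), (2, 3))
        for method in ("vertex", "grid", "direct"):
            assert optimize_on_box(m, b, method=method) == \
                pytest.approx((2.0, 4.0), abs=1e-9)

    def test_interior_minimum_needs_more_than_vertices(self):
        m = model_of(lambda v: (v[0] - 0.5) ** 2, 1)
        b = box((0, 1))
        ymin, ymax = optimize_on_box(m, b, method="grid", g=101)
        assert ymax == pytest.approx(0.25, abs=1e-12)
        assert ymin == pytest.approx(0.0, abs=1e-4)
        ymin_d, ymax_d = optimize_on_box(m, b, method="direct")
        assert ymax_d == pytest.approx(0.25, abs=1e-9)
        assert ymin_d == pytest.approx(0.0, abs=1e-6)

    def test_bilinear_extremes_at_corners(self):
        m = model_of(lambda v: v[0] * v[1], 2, support=(-1, 1))
        b = box((-1, 1), (-1, 1))
        assert optimize_on_box(m, b, method="grid", g=5) == (-1.0, 1.0)
        assert optimize_on_box(m, b, method="direct") == (-1.0, 1.0)

    def test_vertex_requires_monotonicity(self):
        m = model_of(lambda v: v[0], 1)
        with pytest.raises(InvalidInputError):
            optimize_on_box(m, box((0, 1)), method="vertex")

    def test_nan_output_raises_with_vector(self):
        m = model_of(lambda v: float("nan"), 1)
        with pytest.raises(EvaluationError) as exc:
            optimize_on_box(m, box((0.25, 1)), method="grid", g=3)
        assert exc.value.vector is not None

    def test_direct_is_not_tighter_than_dense_grid(self, toys):
        """DIRECT incumbents stay within grid-oracle bounds, up to the
        grid's own resolution error (both are inner approximations of the
        true extremes)."""
        m = toys["bowl"]
        for lo, hi in ((0.1, 0.9), (0.3, 0.4), (0.45, 0.99)):
            g_min, g_max = optimize_on_box(m, box((lo, hi)), method="grid",
                                           g=201)
            d_min, d_max = optimize_on_box(m, box((lo, hi)), method="direct")
            grid_err = ((hi - lo) / 200) ** 2  # bowl curvature x spacing^2
            assert d_min >= g_min - grid_err
            assert d_max <= g_max + grid_err


class TestOutcomeAssembly:
    def test_two_record_staircase_values(self):
        records = [(1.0, 2.0, 0.5), (3.0, 4.0, 0.5)]
        out = OutcomePBox.from_records(records)
        assert out.cdf_bounds(1.5) == (0.0, 0.5)
        assert out.cdf_bounds(2.5) == (0.5, 0.5)
        assert out.cdf_bounds(4.0) == (1.0, 1.0)

    def test_single_record_is_a_unit_step(self):
        ys, lower, upper = empirical_outcome_pbox([(2.0, 2.0, 1.0)],
                                                  grid=np.array([1.9, 2.0, 2.1]))
        np.testing.assert_array_equal(lower, [0, 1, 1])
        np.testing.assert_array_equal(upper, [0, 1, 1])

    def test_unequal_masses_give_unequal_jumps(self):
        ys, lower, upper = empirical_outcome_pbox(
            [(0.0, 1.0, 0.3), (2.0, 3.0, 0.7)],
            grid=np.array([0.5, 1.5, 2.5, 3.0]))
        np.testing.assert_allclose(upper, [0.3, 0.3, 1.0, 1.0])
        np.testing.assert_allclose(lower, [0.0, 0.3, 0.3, 1.0])

    def test_mass_must_sum_to_one(self):
        with pytest.raises(pba.PBAError):
            empirical_outcome_pbox([(0, 1, 0.5), (1, 2, 0.4)])

    def test_expectation_interval_from_records(self):
        out = OutcomePBox.from_records([(1.0, 2.0, 0.5), (3.0, 4.0, 0.5)])
        assert out.expectation_interval() == (2.0, 3.0)


class TestPropagatePBA:
    def test_identity_reproduces_input_within_one_slice_mass(self, toys):
        n = 20
        d = MinimalData(0.0, 1.0, mean=0.4, sd=0.15)
        m = BlackBoxModel(evaluator=lambda v: np.atleast_2d(v)[:, 0],
                          parameters=(Parameter("theta", "pbox", data=d),),
                          vectorized=True, name="identity")
        out = propagate_pba(m, n, method="grid", g=2)
        p = make_pbox(d)
        grid = np.linspace(0, 1, 401)
        lo_s, up_s = out.cdf_bounds(grid)
        lo_c, up_c = pba.eval_bounds(p, grid)
        assert np.all(np.abs(up_s - up_c) <= 1.0 / n + 1e-9)
        assert np.all(np.abs(lo_s - lo_c) <= 1.0 / n + 1e-9)

    def test_two_vacuous_parameters_sum_to_vacuous_interval(self):
        m = model_of(lambda v: v[0] + v[1], 2,
                     monotone=["increasing", "increasing"], support=(0, 1))
        out = propagate_pba(m, 4, method="vertex")
        # interval arithmetic oracle: [0,1] + [0,1] = [0,2]
        assert out.support == (0.0, 2.0)
        assert np.allclose(out.y_min, 0.0) and np.allclose(out.y_max, 2.0)

    def test_total_mass_conserved(self, toys):
        out = propagate_pba(toys["product"], (2, 3), method="grid", g=5)
        assert out.mass.sum() == pytest.approx(1.0, abs=1e-12)
        assert out.mass.size == 6

    def test_deterministic_methods_repeat_exactly(self, toys):
        a = propagate_pba(toys["bowl"], 8, method="direct")
        b = propagate_pba(toys["bowl"], 8, method="direct")
        np.testing.assert_array_equal(a.lower_cdf, b.lower_cdf)
        np.testing.assert_array_equal(a.upper_cdf, b.upper_cdf)

    def test_psa_cdf_lies_inside_outcome_pbox(self, rng):
        """Core guarantee: consistent inputs yield enclosed outputs."""
        from pba.fixtures import sample_consistent_distribution
        d1 = MinimalData(0.0, 1.0, mean=0.3, sd=0.1)
        d2 = MinimalData(0.0, 2.0, mean=1.2)
        m = BlackBoxModel(
            evaluator=lambda v: np.atleast_2d(v)[:, 0] * np.atleast_2d(v)[:, 1]
            + np.atleast_2d(v)[:, 0],
            parameters=(Parameter("x0", "pbox", data=d1),
                        Parameter("x1", "pbox", data=d2)),
            vectorized=True, name="mixed-product")
        n = 10
        out = propagate_pba(m, n, method="grid", g=31)
        g1 = sample_consistent_distribution(d1, seed=5)
        g2 = sample_consistent_distribution(d2, seed=6)
        draws = 100_000
        ys = m.evaluator(np.column_stack([g1.rvs(draws, rng),
                                          g2.rvs(draws, rng)]))
        assert pba.encloses(out.as_pbox(), ys, eps=1.0 / n)


class TestPropagateMixed:
    def test_pure_cdf_path_reduces_to_psa(self):
        m = BlackBoxModel(
            evaluator=lambda v: 2.0 * np.atleast_2d(v)[:, 0],
            parameters=(Parameter("x", "cdf", dist=stats.uniform(0, 1)),),
            vectorized=True, name="double")
        out = propagate_mixed(m, n_slices=4, N=500, seed=3)
        np.testing.assert_array_equal(out.lower_cdf, out.upper_cdf)
        lo, hi = out.expectation_interval()
        assert lo == hi == pytest.approx(1.0, abs=0.1)

    def test_no_cdf_parameters_matches_pure_pba(self, toys):
        out_a = propagate_mixed(toys["bowl"], 6, N=17, seed=9, method="grid")
        out_b = propagate_pba(toys["bowl"], 6, method="grid")
        np.testing.assert_array_equal(out_a.y_min, out_b.y_min)
        np.testing.assert_array_equal(out_a.y_max, out_b.y_max)

    def test_fix_at_mean_matches_sampling_for_linear_model(self):
        d = MinimalData(0.0, 1.0, mean=0.5)
        m = BlackBoxModel(
            evaluator=lambda v: np.atleast_2d(v)[:, 0] + np.atleast_2d(v)[:, 1],
            parameters=(Parameter("xb", "pbox", data=d),
                        Parameter("xc", "cdf", dist=stats.uniform(1, 2))),
            vectorized=True, name="linear-mixed")
        fixed = propagate_mixed(m, 10, mode="fix_at_mean", method="grid", g=2)
        sampled = propagate_mixed(m, 10, N=4000, seed=21, method="grid", g=2)
        for a, b in zip(fixed.expectation_interval(),
                        sampled.expectation_interval()):
            assert a == pytest.approx(b, abs=0.05)

    def test_seeded_runs_are_reproducible(self):
        m = BlackBoxModel(
            evaluator=lambda v: np.atleast_2d(v)[:, 0] ** 2,
            parameters=(Parameter("x", "cdf", dist=stats.norm(0, 1)),),
            vectorized=True, name="square")
        a = propagate_mixed(m, 1, N=64, seed=123)
        b = propagate_mixed(m, 1, N=64, seed=123)
        np.testing.assert_array_equal(a.y_min, b.y_min)
        assert a.provenance["seed"] == 123

    def test_invalid_sample_count(self, toys):
        m = BlackBoxModel(
            evaluator=lambda v: v[0],
            parameters=(Parameter("x", "cdf", dist=stats.norm()),),
            name="x")
        with pytest.raises(InvalidInputError):
            propagate_mixed(m, 1, N=0)
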