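"""Bounds on an unknown CDF built from summary statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pba
from pba import (MinimalData, encloses, eval_bounds, make_pbox,
                 make_pbox_mean, make_pbox_mean_sd, make_pbox_median,
                 make_pbox_minmax, quasi_inverse, verify_pbox)
from pba.bounding import PiecewiseBF
from pba.errors import InconsistentDataError, InvalidInputError
from pba.fixtures import random_minimal_data, sample_consistent_distribution
from pba.pbox import PBox


class TestMinimalData:
    def test_requires_ordered_support(self):
        with pytest.raises(InvalidInputError):
            MinimalData(1.0, 0.0)

    @pytest.mark.parametrize("kwargs", [
        dict(median=1.5), dict(mean=-0.2), dict(sd=0.1),        # sd w/o mean
        dict(mean=0.5, sd=0.6),                                  # sd too big
        dict(mean=0.5, sd=-0.1),
    ])
    def test_rejects_infeasible_statistics(self, kwargs):
        with pytest.raises(InvalidInputError):
            MinimalData(0.0, 1.0, **kwargs)

    def test_moment_feasibility_boundary_is_accepted(self):
        cap = np.sqrt(0.3 * 0.7)
        d = MinimalData(0.0, 1.0, mean=0.3, sd=cap)
        assert d.sd == cap

    def test_config_round_trip(self):
        d = MinimalData.from_dict({"a": 0, "b": 2, "mean": 1.2})
        assert d.to_dict() == {"a": 0.0, "b": 2.0, "mean": 1.2}
        with pytest.raises(InvalidInputError):
            MinimalData.from_dict({"a": 0, "b": 1, "average": 0.5})


class TestPrimitiveConstructors:
    @pytest.mark.parametrize("theta, expected", [
        (0.5, (0.0, 1.0)), (1.0, (1.0, 1.0)), (-0.1, (0.0, 0.0)),
    ])
    def test_minmax_box_is_vacuous_between_steps(self, theta, expected):
        p = make_pbox_minmax(MinimalData(0.0, 1.0))
        assert eval_bounds(p, theta) == expected

    @pytest.mark.parametrize("theta, expected", [
        (0.2, (0.0, 0.5)), (0.7, (0.5, 1.0)),
    ])
    def test_median_box_half_steps(self, theta, expected):
        p = make_pbox_median(MinimalData(0.0, 1.0, median=0.4))
        assert eval_bounds(p, theta) == expected

    def test_median_at_lower_endpoint(self):
        # median == a forces P(X <= a) >= 1/2, so the lower bound jumps to
        # 0.5 already at a (breakpoints belong to their upper branch) and
        # the upper bound is the unit step at a
        p = make_pbox_median(MinimalData(0.0, 1.0, median=0.0))
        assert eval_bounds(p, 0.0) == (0.5, 1.0)
        assert eval_bounds(p, -1e-9) == (0.0, 0.0)
        assert eval_bounds(p, 1e-9) == (0.5, 1.0)

    @pytest.mark.parametrize("theta, expected", [
        (0.75, (1.0 / 3.0, 1.0)),   # lower = (t - mu)/(t - a)
        (0.25, (0.0, 2.0 / 3.0)),   # upper = (b - mu)/(b - t)
        (0.5, (0.0, 1.0)),          # both ratio branches hit their edges
    ])
    def test_mean_box_markov_ratios(self, theta, expected):
        p = make_pbox_mean(MinimalData(0.0, 1.0, mean=0.5))
        lo, up = eval_bounds(p, theta)
        assert lo == pytest.approx(expected[0], abs=1e-12)
        assert up == pytest.approx(expected[1], abs=1e-12)

    def test_mean_sd_breakpoints(self):
        # case-study rate c6: support [0, 10], mean 1, sd 0.0167
        d = MinimalData(0.0, 10.0, mean=1.0, sd=0.0167)
        p = make_pbox_mean_sd(d)
        var = 0.0167**2
        xi1, xi2 = 1.0 - var / 9.0, 1.0 + var / 1.0
        assert xi1 == pytest.approx(0.9999690, abs=5e-7)
        assert xi2 == pytest.approx(1.0002789, abs=5e-7)
        assert xi1 in p.lower.breakpoints and xi2 in p.lower.breakpoints

    def test_mean_sd_value_at_xi2_matches_both_segments(self):
        a, b, mu, sd = 0.0, 1.0, 0.4, 0.2
        p = make_pbox_mean_sd(MinimalData(a, b, mean=mu, sd=sd))
        xi2 = mu + sd**2 / (mu - a)
        expected = sd**2 / ((mu - a) ** 2 + sd**2)
        assert p.lower(xi2) == pytest.approx(expected, abs=1e-12)
        assert p.lower(xi2 - 1e-11) == pytest.approx(expected, abs=1e-6)

    def test_sd_zero_degenerates_to_step_at_mean(self):
        p = make_pbox_mean_sd(MinimalData(0.0, 1.0, mean=0.3, sd=0.0))
        theta = np.array([0.29, 0.3, 0.31])
        assert np.array_equal(p.lower(theta), [0.0, 1.0, 1.0])
        assert np.array_equal(p.upper(theta), [0.0, 1.0, 1.0])

    def test_constructors_reject_wrong_statistics(self):
        with pytest.raises(InvalidInputError):
            make_pbox_minmax(MinimalData(0, 1, mean=0.5))
        with pytest.raises(InvalidInputError):
            make_pbox_mean(MinimalData(0, 1))


class TestIntersection:
    def test_median_mean_upper_is_pointwise_min(self):
        p = make_pbox(MinimalData(0.0, 1.0, median=0.5, mean=0.5))
        assert eval_bounds(p, 0.25)[1] == pytest.approx(0.5)  # min(0.5, 2/3)
        pm = make_pbox_median(MinimalData(0, 1, median=0.5))
        pmu = make_pbox_mean(MinimalData(0, 1, mean=0.5))
        grid = np.linspace(0, 1, 301)
        np.testing.assert_allclose(
            p.upper(grid), np.minimum(pm.upper(grid), pmu.upper(grid)))
        np.testing.assert_allclose(
            p.lower(grid), np.maximum(pm.lower(grid), pmu.lower(grid)))

    def test_minmax_dispatch_equals_primitive(self):
        d = MinimalData(0.0, 2.0)
        p, q = make_pbox(d), make_pbox_minmax(d)
        grid = np.linspace(-0.5, 2.5, 101)
        np.testing.assert_array_equal(p.lower(grid), q.lower(grid))
        np.testing.assert_array_equal(p.upper(grid), q.upper(grid))

    def test_conflicting_median_and_mean_raise(self):
        with pytest.raises(InconsistentDataError):
            make_pbox(MinimalData(0.0, 1.0, median=0.9, mean=0.1))


class TestQuasiInverse:
    def test_mean_box_analytic_inversion(self):
        p = make_pbox(MinimalData(0.0, 1.0, mean=0.5))
        qi = quasi_inverse(p, 0.8)
        assert qi.left == pytest.approx(0.375, abs=1e-8)
        assert qi.right == pytest.approx(1.0, abs=1e-8)

    def test_level_zero_and_one(self):
        p = make_pbox(MinimalData(0.0, 1.0, mean=0.5))
        assert quasi_inverse(p, 0.0) == pytest.approx((0.0, 0.5), abs=1e-8)
        assert quasi_inverse(p, 1.0).right == 1.0

    def test_rejects_levels_outside_unit_interval(self):
        p = make_pbox(MinimalData(0.0, 1.0))
        for bad in (-0.1, 1.1, np.nan):
            with pytest.raises(InvalidInputError):
                quasi_inverse(p, bad)

    @pytest.mark.parametrize("kind", ["median", "mean", "mean_sd"])
    def test_galois_property(self, rng, kind):
        """upper(left) >= q, and lower stays <= q strictly below right."""
        for _ in range(10):
            d = random_minimal_data(rng, kind)
            p = make_pbox(d)
            for q in rng.uniform(0, 1, 8):
                qi = quasi_inverse(p, float(q))
                assert qi.left <= qi.right
                assert p.upper(qi.left) >= q - 1e-7
                before = qi.right - 1e-6 * d.width
                if before > p.a:
                    assert p.lower(before) <= q + 1e-7


class TestDiagnostics:
    @pytest.mark.parametrize("kind", ["minmax", "median", "mean", "mean_sd",
                                      "median_mean", "median_mean_sd"])
    def test_constructed_boxes_verify(self, rng, kind):
        for _ in range(5):
            p = make_pbox(random_minimal_data(rng, kind))
            report = verify_pbox(p, 1001)
            assert report.passed, report.failures

    def test_crossed_bounds_are_flagged(self):
        crossed = PBox(lower=PiecewiseBF([0.2], [0.0, 1.0]),
                       upper=PiecewiseBF([0.8], [0.0, 1.0]), a=0.0, b=1.0)
        report = verify_pbox(crossed, 101)
        assert not report.passed
        name, theta = report.first_violation
        assert name == "lower <= upper"
        assert 0.2 <= theta < 0.8

    def test_mean_sd_breakpoint_continuity_on_fine_grid(self):
        p = make_pbox_mean_sd(MinimalData(0.0, 10.0, mean=1.0, sd=0.0167))
        assert verify_pbox(p, 10_000).passed

    def test_encloses_consistent_and_rejects_inconsistent_cdf(self):
        from scipy import stats
        p = make_pbox(MinimalData(0.0, 1.0, mean=0.5))
        assert encloses(p, stats.beta(2, 2).cdf)          # mean 1/2
        assert not encloses(p, stats.beta(5, 1).cdf)      # mean 5/6
        beta_bf = PiecewiseBF([0, 1], [0.0, stats.beta(2, 2).cdf, 1.0])
        degenerate = PBox(lower=beta_bf, upper=beta_bf, a=0.0, b=1.0)
        assert encloses(degenerate, stats.beta(2, 2).cdf)


class TestOrderingProperties:
    def test_information_nests_the_boxes(self, rng):
        """Adding statistics can only tighten the bounds, pointwise."""
        for _ in range(20):
            d = random_minimal_data(rng, "mean_sd")
            grid = np.linspace(d.a, d.b, 500)
            box0 = make_pbox(MinimalData(d.a, d.b))
            box_mu = make_pbox(MinimalData(d.a, d.b, mean=d.mean))
            box_musd = make_pbox(d)
            for wide, narrow in ((box0, box_mu), (box_mu, box_musd)):
                assert np.all(narrow.upper(grid) <= wide.upper(grid) + 1e-9)
                assert np.all(narrow.lower(grid) >= wide.lower(grid) - 1e-9)
            dm = random_minimal_data(rng, "median")
            gm = np.linspace(dm.a, dm.b, 500)
            bm = make_pbox(dm)
            b0 = make_pbox(MinimalData(dm.a, dm.b))
            assert np.all(bm.upper(gm) <= b0.upper(gm) + 1e-9)
            assert np.all(bm.lower(gm) >= b0.lower(gm) - 1e-9)

    def test_sd_to_zero_collapses_the_box(self):
        # away from the limiting jump at the mean, the gap between the
        # bounds vanishes as sd -> 0
        grid = np.linspace(0, 1, 2001)
        away = np.abs(grid - 0.4) > 0.01
        gaps = []
        for sd in (0.2, 0.02, 0.002, 2e-4):
            p = make_pbox_mean_sd(MinimalData(0.0, 1.0, mean=0.4, sd=sd))
            gap = p.upper(grid) - p.lower(grid)
            gaps.append(float(gap[away].max()))
        assert all(x > y for x, y in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-3

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_random_consistent_distributions_are_enclosed(self, seed):
        """Any distribution matching the record lies inside its p-box."""
        rng = np.random.default_rng(seed)
        kind = ["median", "mean", "mean_sd", "median_mean"][seed % 4]
        d = random_minimal_data(rng, kind)
        dist = sample_consistent_distribution(d, seed=seed)
        assert encloses(make_pbox(d), dist.cdf, eps=1e-6)
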