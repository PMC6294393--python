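import numpy as np
import pytest

from antforage import DomainError
from antforage.analytics import (
    CHAT_CONVENTIONS,
    critical_volatility,
    critical_volatility_report,
    default_rin_grid,
    fixed_points,
    nest_io_curve_analytic,
    nest_io_curve_simulated,
    oscillation_bound,
    qss_vs_c,
    two_population_io,
    two_spike_threshold,
)
from antforage.excitable import FNParams, bifurcation_points, fn_period

GRID6 = np.array([0.1, 0.5, 1.0, 2.0, 3.5, 5.0])


@pytest.fixture(scope="module")
def curve_c2():
    return nest_io_curve_analytic(2.0, r_in_grid=default_rin_grid())


class TestAnalyticCurve:
    def test_vanishes_at_low_incoming_rate(self):
        low = nest_io_curve_analytic(2.0, r_in_grid=np.array([0.01, 0.05]))
        assert low.r_out_values[0] < 0.05
        assert low.r_out_values[0] < low.r_out_values[1]

    def test_unimodal_rises_then_falls(self, curve_c2):
        v = curve_c2.r_out_values
        peak = int(np.argmax(v))
        assert 0 < peak < len(v) - 1
        assert np.all(np.diff(v[: peak + 1]) > 0)
        assert np.all(np.diff(v[peak:]) < 0)

    def test_bounded_by_natural_frequency(self, curve_c2):
        p = FNParams(c=2.0)
        b1, b2 = bifurcation_points(p)
        ss = np.linspace(b1 * 1.02, b2 * 0.98, 15)
        min_period = min(fn_period(float(s), 2.0) for s in ss)
        assert curve_c2.r_out_values.max() <= 1.0 / min_period + 1e-9

    def test_grid_refinement_leaves_values_unchanged(self):
        coarse = nest_io_curve_analytic(2.0, r_in_grid=np.array([0.5, 2.0]))
        fine = nest_io_curve_analytic(2.0, r_in_grid=np.array([0.5, 1.0, 2.0, 3.0]))
        assert coarse.r_out_values[0] == pytest.approx(fine.r_out_values[0], rel=1e-6)
        assert coarse.r_out_values[1] == pytest.approx(fine.r_out_values[2], rel=1e-6)

    def test_asymptotic_period_curve_sits_above_numeric(self):
        # 1/T_lc overestimates the spike frequency, so the asymptotic-period
        # curve must dominate the numeric-period curve
        grid = np.array([0.5, 1.0, 2.0])
        num = nest_io_curve_analytic(2.0, r_in_grid=grid, period="numeric")
        asym = nest_io_curve_analytic(2.0, r_in_grid=grid, period="asymptotic")
        assert np.all(asym.r_out_values > num.r_out_values)


class TestSimulatedCurve:
    def test_reproducible_under_fixed_seed(self):
        a = nest_io_curve_simulated(2.0, r_in_grid=GRID6[:3], trials=3, seed=7)
        b = nest_io_curve_simulated(2.0, r_in_grid=GRID6[:3], trials=3, seed=7)
        np.testing.assert_array_equal(a.r_out_values, b.r_out_values)

    def test_tracks_analytic_curve_at_interior_points(self):
        """Simulated rates sit at or above the quasi-static prediction and
        within ~25% at interior points (band-entry spikes are extra)."""
        grid = np.array([0.5, 1.0, 2.0, 3.0])
        sim = nest_io_curve_simulated(2.0, r_in_grid=grid, trials=8, seed=3)
        ana = nest_io_curve_analytic(2.0, r_in_grid=grid)
        assert np.all(sim.r_out_values + 2 * sim.stderr >= ana.r_out_values)
        rel = np.abs(sim.r_out_values - ana.r_out_values) / sim.r_out_values
        assert np.all(rel < 0.25)


class TestTwoPopulation:
    def test_endpoint_weights_recover_single_curves(self):
        grid = np.array([0.5, 2.0])
        lone = nest_io_curve_analytic(0.9, r_in_grid=grid)
        mixed = two_population_io(3.0, 0.9, x_i=1.0, r_in_grid=grid)
        np.testing.assert_allclose(mixed.r_out_values, lone.r_out_values, rtol=1e-9)
        lone_u = nest_io_curve_analytic(3.0, r_in_grid=grid)
        mixed0 = two_population_io(3.0, 0.9, x_i=0.0, r_in_grid=grid)
        np.testing.assert_allclose(mixed0.r_out_values, lone_u.r_out_values, rtol=1e-9)

    def test_half_mixture_is_pointwise_mean(self):
        grid = np.array([0.5, 2.0])
        a = nest_io_curve_analytic(3.0, r_in_grid=grid).r_out_values
        b = nest_io_curve_analytic(0.9, r_in_grid=grid).r_out_values
        mid = two_population_io(3.0, 0.9, x_i=0.5, r_in_grid=grid).r_out_values
        np.testing.assert_allclose(mid, 0.5 * (a + b), rtol=1e-9)

    def test_identical_volatilities_collapse_to_single_curve(self):
        grid = np.array([1.0, 3.0])
        single = nest_io_curve_analytic(2.0, r_in_grid=grid).r_out_values
        for x in (0.0, 0.3, 1.0):
            mixed = two_population_io(2.0, 2.0, x_i=x, r_in_grid=grid).r_out_values
            np.testing.assert_allclose(mixed, single, rtol=1e-9)

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(DomainError):
            two_population_io(3.0, 0.9, x_i=1.5)


class TestFixedPoints:
    def test_low_volatility_confined_to_origin(self):
        curve = nest_io_curve_analytic(0.1, r_in_grid=GRID6)
        res = fixed_points(curve)
        assert res.r_star < 0.1

    def test_moderate_and_high_volatility_attract(self, curve_c2):
        res = fixed_points(curve_c2)
        assert res.origin_unstable
        nontrivial = [f for f in res.fixed_points if f.r > 0.2 and f.stable]
        assert len(nontrivial) == 1
        assert res.r_star == pytest.approx(nontrivial[0].r)
        res5 = fixed_points(nest_io_curve_analytic(5.0, r_in_grid=GRID6))
        assert res5.origin_unstable and res5.r_star > res.r_star

    def test_cobweb_iteration_agrees(self, curve_c2):
        g = curve_c2.interpolator()
        res = fixed_points(curve_c2)
        for r0 in (0.05, 1.0, 3.0):
            r = r0
            for _ in range(300):
                r = float(g(r))
            assert r == pytest.approx(res.r_star, rel=1e-3)


class TestCriticalVolatility:
    def test_bound_crosses_count_exactly_once(self):
        cs = np.linspace(0.05, 15.0, 200)
        vals = np.array([oscillation_bound(c, convention="min-band") for c in cs])
        crossings = np.sum((vals[:-1] < 2.0) & (vals[1:] >= 2.0))
        assert crossings == 1

    def test_all_conventions_yield_a_root(self):
        report = critical_volatility_report()
        assert set(report) == set(CHAT_CONVENTIONS)
        for v in report.values():
            assert 0.05 < v < 5.0
        # half-period conventions sit below full-period ones
        assert report["half-at-b1"] < report["min-band"]

    def test_root_consistency(self):
        c_hat = critical_volatility(convention="min-band")
        assert oscillation_bound(c_hat, convention="min-band") == pytest.approx(2.0, abs=1e-4)

    def test_two_spike_threshold_brackets_simulated_behavior(self):
        """Direct simulation: one isolated arrival elicits a second departure
        above the threshold, a single departure below it."""
        from antforage import EventSequence, open_loop_response

        thr = two_spike_threshold()
        one = EventSequence(np.array([0.0]), "in")
        below = open_loop_response(FNParams(c=thr * 0.9), one, duration=8.0)
        above = open_loop_response(FNParams(c=thr * 1.1), one, duration=8.0)
        assert len(below) == 1
        assert len(above) >= 2


class TestCriticalBracket:
    def test_bracket_separates_cessation_from_sustained_foraging(self):
        from antforage.analytics import critical_volatility_bracket, nest_io_curve_analytic

        lo, hi = critical_volatility_bracket(tol=0.2)
        assert 0.2 <= lo < hi <= 3.0
        assert fixed_points(nest_io_curve_analytic(hi + 0.5, r_in_grid=GRID6)).r_star > 0.1
        assert fixed_points(nest_io_curve_analytic(max(lo - 0.3, 0.05), r_in_grid=GRID6)).r_star < 0.1


class TestQssVsC:
    def test_transition_from_cessation_to_sustained_foraging(self):
        cs, rates = qss_vs_c(c_grid=np.array([0.25, 0.5, 1.5, 3.0]), r_in_grid=GRID6)
        assert rates[0] < 0.05 and rates[1] < 0.05
        assert rates[2] > 0.5 and rates[3] > rates[2]
        assert np.all(np.diff(rates) >= -1e-9)
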