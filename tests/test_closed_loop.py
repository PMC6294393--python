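import numpy as np
import pytest

from antforage import (
    ColonyConfig,
    EventSequence,
    InvalidParameterError,
    SimulationRecord,
    qss_estimate,
    run_closed_loop,
)
from antforage.analytics import nest_io_curve_simulated


class TestBookkeeping:
    def test_exact_forager_conservation(self, short_colony_record):
        rec = short_colony_record
        N = rec.config.N
        n_i = N - rec.n_uninformed_trace - rec.q_trace
        assert np.all(n_i >= 0)
        assert np.all(rec.q_trace >= 0) and np.all(rec.q_trace <= N)
        # x_i equals the informed fraction of the available pool wherever the
        # pool is nonempty
        avail = rec.n_uninformed_trace + n_i
        m = avail > 0
        np.testing.assert_allclose(rec.x_i_trace[m], n_i[m] / avail[m], atol=1e-12)

    def test_informed_status_never_lost(self, short_colony_record):
        # the uninformed pool can only shrink
        nu = short_colony_record.n_uninformed_trace
        assert np.all(np.diff(nu) <= 0)
        assert 0.0 <= short_colony_record.x_i_trace[-1] <= 1.0

    def test_every_departure_matched_or_outside_at_end(self, short_colony_record):
        rec = short_colony_record
        n_out = len(rec.lambda_out)
        n_back = len(rec.returns)
        assert n_out - n_back == rec.q_trace[-1]

    def test_exogenous_events_stimulate_but_do_not_join_pools(self):
        cfg = ColonyConfig(c_u=3.0, c_i=2.0, N=100, D=3.0, duration=1200.0, seed=3)
        rec = run_closed_loop(cfg)
        # the incoming record is exactly seed arrivals plus simulated returns
        merged = np.sort(np.concatenate([rec.exogenous.times, rec.returns.times]))
        np.testing.assert_array_equal(rec.lambda_in.times, merged)
        # nobody is informed before the first simulated return
        if len(rec.returns):
            first_back = rec.returns.times[0]
            before = rec.trace_t < first_back
            assert np.all(rec.x_i_trace[before] == 0.0)

    def test_determinism_bit_identical(self):
        cfg = ColonyConfig(c_u=3.0, c_i=2.0, N=100, D=2.0, duration=900.0, seed=17)
        a, b = run_closed_loop(cfg), run_closed_loop(cfg)
        np.testing.assert_array_equal(a.lambda_out.times, b.lambda_out.times)
        np.testing.assert_array_equal(a.lambda_in.times, b.lambda_in.times)
        np.testing.assert_array_equal(a.q_trace, b.q_trace)

    def test_tiny_colony_pool_exhaustion_is_safe(self):
        cfg = ColonyConfig(c_u=5.0, c_i=5.0, N=2, D=1.0, duration=600.0, seed=1)
        rec = run_closed_loop(cfg)
        assert np.all(rec.q_trace <= 2)
        assert rec.n_dropped >= 0  # drops counted, never crash

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidParameterError):
            ColonyConfig(c_u=0.0, c_i=1.0, N=10, D=5.0)
        with pytest.raises(InvalidParameterError):
            ColonyConfig(c_u=1.0, c_i=1.0, N=0, D=5.0)


class TestQssEstimate:
    def test_exact_recovery_on_constant_rate_record(self, short_colony_record):
        # synthetic record: perfectly regular in/out streams at 0.5 ants/s
        times = np.arange(0.0, 3600.0, 2.0)
        cfg = short_colony_record.config
        rec = SimulationRecord(
            config=ColonyConfig(c_u=1, c_i=1, N=10, D=5.0, duration=3600.0, seed=0),
            lambda_in=EventSequence(times, "in"),
            lambda_out=EventSequence(times + 0.5, "out"),
            exogenous=EventSequence(np.empty(0)),
            returns=EventSequence(times, "in"),
            spikes_u=short_colony_record.spikes_u,
            spikes_i=short_colony_record.spikes_i,
            trace_t=np.arange(0.0, 3600.0),
            s_trace=np.zeros(3600),
            x_i_trace=np.zeros(3600),
            q_trace=np.full(3600, 7),
            n_uninformed_trace=np.zeros(3600, int),
            n_dropped=0,
        )
        est = qss_estimate(rec, tail_fraction=0.5)
        # closed-window boxcar double counts lattice-aligned events at the
        # window edges; exact regular spacing is the worst case
        assert est.r_qss == pytest.approx(0.5, rel=5e-3)
        assert est.q_qss == 7.0
        assert est.rate_gap < 5e-3

    def test_too_short_record_rejected(self, short_colony_record):
        with pytest.raises(InvalidParameterError):
            qss_estimate(short_colony_record, tail_fraction=0.01)


class TestSteadyState:
    def test_qss_consistent_with_queueing_law(self):
        """At QSS the number outside matches rate x trip time (ants/min x D)."""
        cfg = ColonyConfig(c_u=3.0, c_i=2.0, N=1000, D=5.0, duration=7200.0, seed=5)
        est = qss_estimate(run_closed_loop(cfg))
        assert est.q_qss == pytest.approx(est.r_qss * 60.0 * cfg.D, rel=0.06)

    def test_qss_independent_of_initialization(self):
        """Sparse seed sequences at different rates lead to the same QSS."""
        base = dict(c_u=3.0, c_i=2.0, N=1000, D=5.0, duration=9000.0)
        rates = []
        for init_rate in (0.005, 0.02):
            per_seed = [
                qss_estimate(
                    run_closed_loop(
                        ColonyConfig(**base, seed=s, initial_rate=init_rate)
                    )
                ).r_qss
                for s in (1, 2, 3)
            ]
            rates.append(np.mean(per_seed))
        assert abs(rates[0] - rates[1]) < 0.15 * np.mean(rates)

    def test_identical_volatilities_match_single_population_map(self):
        """With c_u = c_i = c the two-unit loop must equilibrate at the
        diagonal crossing of the single-population simulated I/O curve
        (independent open-loop protocol)."""
        c = 2.0
        qss = [
            qss_estimate(
                run_closed_loop(
                    ColonyConfig(c_u=c, c_i=c, N=1200, D=5.0, duration=10800.0, seed=s)
                )
            ).r_qss
            for s in (1, 2, 3)
        ]
        curve = nest_io_curve_simulated(
            c, r_in_grid=np.linspace(1.5, 4.0, 8), trials=8, seed=11
        )
        g = curve.interpolator()
        rr = np.linspace(1.5, 4.0, 400)
        crossing = rr[np.argmin(np.abs(g(rr) - rr))]
        assert np.mean(qss) == pytest.approx(crossing, rel=0.10)
        # and the loop is equilibrated: in and out rates agree
        assert all(
            qss_estimate(
                run_closed_loop(
                    ColonyConfig(c_u=c, c_i=c, N=1200, D=5.0, duration=10800.0, seed=1)
                )
            ).rate_gap
            < 0.1 * np.mean(qss)
            for _ in (0,)
        )
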