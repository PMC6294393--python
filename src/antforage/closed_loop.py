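"""Closed-loop colony simulator with informed/uninformed volatility switching.

The loop: incoming foragers bump the stimulus; the stimulus drives two FN
units (uninformed volatility ``c_u``, informed ``c_i``); unit spikes are
probabilistically thinned by the informed fraction ``x_i`` of the available
pool (uninformed spikes kept with probability 1-x_i, informed with x_i);
each kept spike sends one available forager of the matching class on a
chi-square trip of mean ``D`` minutes; every returning forager rejoins the
available pool as *informed* (exposure to outside conditions is permanent
within a foraging day), appends an incoming event and bumps the stimulus.

Conservation holds exactly: available uninformed + available informed +
active outside = N at all times.  Exogenous seed arrivals (the sparse
morning trickle that starts the day) stimulate ``s`` but are not colony
members: they never touch the pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrationFailureError, InvalidParameterError
from .events import EventSequence, estimate_rate, generate_poisson_events
from .excitable import FNParams, SpikeTrain
from .stimulus import StimulusParams
from ._kernels import closed_loop_integrate

__all__ = ["ColonyConfig", "SimulationRecord", "run_closed_loop", "qss_estimate"]

#: Default run length: three hours of simulated foraging.
DEFAULT_DURATION = 3 * 3600.0
#: Default mean rate of the exogenous seed sequence, ants/sec.
DEFAULT_INITIAL_RATE = 0.01


@dataclass(frozen=True)
class ColonyConfig:
    """Parameters of one closed-loop run.

    ``initial_incoming`` defaults to a Poisson trickle at 0.01 ants/sec
    covering the first ``60*(D+1)`` seconds — sparse enough that the colony's
    behaviour is set by (c_u, c_i, N, D), long enough that the seed stream
    does not end before the first returns arrive.
    """

    c_u: float
    c_i: float
    N: int
    D: float  # mean trip time, minutes
    stim: StimulusParams = field(default_factory=StimulusParams)
    fn: FNParams = field(default_factory=FNParams)
    duration: float = DEFAULT_DURATION
    seed: int = 0
    dt: float = 1e-3
    sample_dt: float = 1.0
    initial_incoming: EventSequence | None = None
    initial_rate: float = DEFAULT_INITIAL_RATE

    def __post_init__(self) -> None:
        if self.N < 1:
            raise InvalidParameterError("N must be >= 1")
        if not (self.c_u > 0 and self.c_i > 0):
            raise InvalidParameterError("volatilities must be > 0")
        if not self.D > 0:
            raise InvalidParameterError("D must be > 0")
        if not self.duration > 0:
            raise InvalidParameterError("duration must be > 0")

    def resolve_initial_incoming(self) -> EventSequence:
        if self.initial_incoming is not None:
            return self.initial_incoming
        child = np.random.SeedSequence(self.seed).spawn(1)[0]
        return generate_poisson_events(
            self.initial_rate, 60.0 * (self.D + 1.0), np.random.default_rng(child)
        )


@dataclass(frozen=True)
class SimulationRecord:
    """Everything a closed-loop run produced.

    ``lambda_in`` merges exogenous seed arrivals and simulated returns;
    ``returns`` holds the simulated returns alone (so that out-minus-return
    counting reproduces ``q_trace`` exactly).  ``q_trace`` is the number of
    active foragers outside sampled on ``trace_t``; ``x_i_trace`` the
    informed fraction of the available pool; ``s_trace`` the stimulus.
    """

    config: ColonyConfig
    lambda_in: EventSequence
    lambda_out: EventSequence
    exogenous: EventSequence
    returns: EventSequence
    spikes_u: SpikeTrain
    spikes_i: SpikeTrain
    trace_t: np.ndarray
    s_trace: np.ndarray
    x_i_trace: np.ndarray
    q_trace: np.ndarray
    n_uninformed_trace: np.ndarray
    n_dropped: int


def run_closed_loop(config: ColonyConfig) -> SimulationRecord:
    """Run the closed loop and return the full record.

    Both FN units start at their rest state for s = 0 and are integrated
    with fixed-step RK4 (dt = 1 ms by default) against the shared stimulus;
    thinning and trip draws come from a single RNG stream seeded by
    ``config.seed`` (the exogenous fixture uses a spawned child seed), so a
    rerun with the same config is bit-identical.
    """
    exo = config.resolve_initial_incoming()
    fn, st = config.fn, config.stim
    (
        sp_u,
        sp_i,
        out_t,
        in_t,
        n_drop,
        samp_t,
        samp_s,
        samp_xi,
        samp_q,
        samp_nu,
        ok,
    ) = closed_loop_integrate(
        exo.times,
        float(config.duration),
        float(config.dt),
        st.k,
        st.tau,
        fn.a,
        fn.eps1,
        fn.eps2,
        fn.spike_threshold,
        float(config.c_u),
        float(config.c_i),
        int(config.N),
        float(config.D),
        int(config.seed) % (2**31),
        float(config.sample_dt),
    )
    if not ok:
        raise IntegrationFailureError("closed-loop integration diverged")
    lam_in = EventSequence(np.sort(np.concatenate([exo.times, in_t])), "in")
    # spikes of the two units are processed uninformed-first within a step,
    # so interpolated departure times can interleave: sort for the record
    out_t = np.sort(out_t)
    return SimulationRecord(
        config=config,
        lambda_in=lam_in,
        lambda_out=EventSequence(out_t, "out"),
        exogenous=exo,
        returns=EventSequence(in_t, "in"),
        spikes_u=SpikeTrain(sp_u),
        spikes_i=SpikeTrain(sp_i),
        trace_t=samp_t,
        s_trace=samp_s,
        x_i_trace=samp_xi,
        q_trace=samp_q,
        n_uninformed_trace=samp_nu,
        n_dropped=int(n_drop),
    )


@dataclass(frozen=True)
class QssEstimate:
    r_qss: float  # mean of incoming and outgoing rate, ants/sec
    r_in: float
    r_out: float
    q_qss: float  # mean number outside
    rate_gap: float  # |r_in - r_out|

    def __iter__(self):
        yield self.r_qss
        yield self.q_qss


def qss_estimate(
    record: SimulationRecord,
    tail_fraction: float = 1.0 / 3.0,
    window: float = 300.0,
) -> QssEstimate:
    """Quasi-steady-state readout over the final ``tail_fraction`` of a run.

    Rates are boxcar estimates (default 300 s window) averaged over a
    1-second grid on the tail; ``rate_gap`` reports |r_in - r_out| as the
    equilibration diagnostic.
    """
    if not 0 < tail_fraction <= 1:
        raise InvalidParameterError("tail_fraction must be in (0, 1]")
    dur = record.config.duration
    t0 = dur * (1.0 - tail_fraction)
    if dur - t0 < window - 1e-6:
        raise InvalidParameterError("record tail shorter than the rate window")
    grid = np.arange(t0, dur, 1.0)
    r_in = estimate_rate(record.lambda_in, window, grid, t_start=0.0, t_end=dur).rates
    r_out = estimate_rate(record.lambda_out, window, grid, t_start=0.0, t_end=dur).rates
    q = record.q_trace[record.trace_t >= t0]
    ri, ro = float(r_in.mean()), float(r_out.mean())
    return QssEstimate(
        r_qss=0.5 * (ri + ro),
        r_in=ri,
        r_out=ro,
        q_qss=float(q.mean()),
        rate_gap=abs(ri - ro),
    )
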