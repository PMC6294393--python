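"""FitzHugh-Nagumo activation of available foragers.

The response of the pool of available foragers to the stimulus ``s`` is
modelled phenomenologically by FitzHugh-Nagumo (FN) excitability dynamics

    eps1*eps2 * dv/dt = v - v^3/3 - c*u - a + s
    eps1      * du/dt = v - c*u

with fast activation ``v`` and slow recovery ``u``.  Each upward crossing of
``v`` through the spike threshold (0.75) is one forager leaving the nest.
The volatility ``c`` scales the recovery feedback: it sets both the
oscillation frequency and the width of the stimulus band that oscillates.

Three regimes, delimited by the Hopf points b1 < b2:
rest for s < b1, periodic spiking for b1 < s < b2, and saturation (no
spikes) for s > b2, with

    b1,2 = a -/+ (1/3) * (1 - c*eps2)^(3/2).

``lc_period`` gives the leading-order singular-perturbation (slow-branch
transit-time) approximation of the limit-cycle period; it is exactly
proportional to 1/c and systematically underestimates the measured period at
finite eps2 (the fold corrections are O(eps2^(2/3)) and are not small at the
default eps2 = 0.05 for moderate c — see docs/methods.md).  ``fn_period``
measures the true period by direct integration and is used by the analytic
input/output machinery by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .errors import (
    DegenerateRegimeError,
    DomainError,
    IntegrationFailureError,
    InvalidParameterError,
)
from .events import EventSequence
from .stimulus import StimulusParams, StimulusTrajectory, propagate_stimulus
from ._kernels import fn_integrate, fn_period_const

__all__ = [
    "FNParams",
    "FNState",
    "SpikeTrain",
    "FNTrace",
    "bifurcation_points",
    "rest_state",
    "simulate_fn",
    "lc_period",
    "fn_period",
    "open_loop_response",
]


@dataclass(frozen=True)
class FNParams:
    """FN parameters: offset ``a``, timescale separations ``eps1`` (dynamics
    vs stimulus) and ``eps2`` (fast vs slow state), volatility ``c`` > 0, and
    the activation level counted as a departure."""

    a: float = 0.35
    eps1: float = 0.2
    eps2: float = 0.05
    c: float = 1.0
    spike_threshold: float = 0.75

    def __post_init__(self) -> None:
        if not (self.eps1 > 0 and self.eps2 > 0):
            raise InvalidParameterError("eps1 and eps2 must be > 0")
        if not self.c > 0:
            raise InvalidParameterError("volatility c must be > 0")

    def with_c(self, c: float) -> "FNParams":
        return FNParams(self.a, self.eps1, self.eps2, c, self.spike_threshold)


@dataclass(frozen=True)
class FNState:
    v: float
    u: float


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted departure (spike) times in seconds."""

    spike_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, float)
        object.__setattr__(self, "spike_times", t)

    def __len__(self) -> int:
        return int(self.spike_times.size)

    def rate(self, duration: float) -> float:
        return len(self) / duration

    def to_events(self, label: str = "out") -> EventSequence:
        return EventSequence(self.spike_times, label)


@dataclass(frozen=True)
class FNTrace:
    """Decimated state trace of a simulation: t, v, u, s arrays."""

    t: np.ndarray
    v: np.ndarray
    u: np.ndarray
    s: np.ndarray


def bifurcation_points(params: FNParams) -> tuple[float, float]:
    """Hopf points (b1, b2) of the FN unit for its volatility ``c``."""
    ce = params.c * params.eps2
    if ce >= 1.0:
        raise DegenerateRegimeError("c*eps2 >= 1: the oscillating band is empty")
    half = (1.0 - ce) ** 1.5 / 3.0
    return params.a - half, params.a + half


def rest_state(params: FNParams, s: float) -> FNState:
    """Equilibrium of the FN unit at constant stimulus ``s``.

    At equilibrium u = v/c, which collapses the cubic nullcline condition to
    v^3 = 3*(s - a); the real cube root is the unique equilibrium.
    """
    if params.c == 0:
        raise DegenerateRegimeError(
            "c = 0: the recovery equilibrium is unconstrained (u arbitrary)"
        )
    v = float(np.cbrt(3.0 * (s - params.a)))
    return FNState(v, v / params.c)


def _default_dt(params: FNParams) -> float:
    # resolve the fast timescale eps1*eps2 with at least 10 substeps
    return min(1e-3, params.eps1 * params.eps2 / 10.0)


def simulate_fn(
    params: FNParams,
    stimulus: StimulusTrajectory | float,
    duration: float,
    dt: float | None = None,
    init: FNState | None = None,
    record_stride: int = 0,
) -> tuple[FNTrace, SpikeTrain]:
    """Integrate the FN unit against a stimulus trajectory or constant.

    Fixed-step RK4 with the stimulus evaluated analytically at substeps and
    event times forced onto the step mesh.  A spike is recorded at each
    upward crossing of the threshold (crossing time by linear interpolation
    within the step); the trajectory must fall back below threshold before
    the next spike can be recorded.  The default initial condition is the
    rest state at the initial stimulus value.
    """
    if not duration > 0:
        raise InvalidParameterError("duration must be > 0")
    if isinstance(stimulus, (int, float)):
        stimulus = StimulusTrajectory.from_constant(float(stimulus))
    if dt is None:
        dt = _default_dt(params)
    if init is None:
        # rest state at the initial stimulus, with an infinitesimal kick so a
        # start exactly on an unstable equilibrium (constant in-band s) still
        # finds the limit cycle
        r = rest_state(params, stimulus.s0)
        init = FNState(r.v + 1e-6, r.u)
    jumps = (
        np.full(stimulus.jump_times.size, stimulus.params.k)
        if not stimulus.constant
        else np.empty(0)
    )
    max_spikes = int(duration * (params.c * 3.0 + 2.0)) + 64
    sp, tt, tv, tu, ts, ok = fn_integrate(
        stimulus.jump_times,
        jumps,
        stimulus.s0,
        stimulus.constant,
        float(duration),
        float(dt),
        0.0,
        stimulus.params.tau,
        params.a,
        params.eps1,
        params.eps2,
        params.c,
        params.spike_threshold,
        init.v,
        init.u,
        int(record_stride),
        max_spikes,
    )
    if not ok:
        raise IntegrationFailureError("FN integration produced non-finite state")
    return FNTrace(tt, tv, tu, ts), SpikeTrain(sp)


def lc_period(s: float, c: float, params: FNParams | None = None) -> float:
    """Leading-order transit-time approximation of the limit-cycle period.

    In the singular limit the cycle spends its time creeping along the two
    outer branches of the cubic nullcline between the folds |v| = 1 and the
    jump landing points |v| = 2; the fast jumps are instantaneous.  The
    transit times give

        T(s, c) = (eps1/c) * [ I(s - a) + I(-(s - a)) ],
        I(d) = ∫_1^2 (v^2 - 1) / (v^3/3 - d) dv,

    strictly positive on the oscillating band and exactly proportional to
    1/c.  Valid for b1 < s < b2.
    """
    p = params if params is not None else FNParams()
    p = p.with_c(c)
    b1, b2 = bifurcation_points(p)
    if not (b1 < s < b2):
        raise DomainError(f"s={s} outside the oscillating band ({b1:.4f}, {b2:.4f})")
    d = s - p.a
    i1 = quad(lambda v: (v * v - 1.0) / (v**3 / 3.0 - d), 1.0, 2.0)[0]
    i2 = quad(lambda v: (v * v - 1.0) / (v**3 / 3.0 + d), 1.0, 2.0)[0]
    return p.eps1 / c * (i1 + i2)


def fn_period(
    s: float,
    c: float,
    params: FNParams | None = None,
    dt: float = 2e-4,
    duration: float | None = None,
) -> float:
    """Numerically measured spike-to-spike period at constant stimulus.

    Integrates from just off the rest state and averages the second half of
    the inter-spike intervals.  Returns NaN when no sustained spiking occurs
    (outside the band, or in the narrow near-Hopf sliver where the cycle
    amplitude stays below the spike threshold).
    """
    p = (params if params is not None else FNParams()).with_c(c)
    if duration is None:
        # long enough for ~15 cycles even at low volatility
        duration = max(25.0, 18.0 * p.eps1 * 2.5 / c * 10.0)
    return float(
        fn_period_const(
            c, float(s), p.a, p.eps1, p.eps2, p.spike_threshold, dt, duration
        )
    )


def open_loop_response(
    params: FNParams,
    incoming: EventSequence,
    stim_params: StimulusParams = StimulusParams(),
    duration: float | None = None,
    dt: float | None = None,
) -> SpikeTrain:
    """Departures elicited by an incoming event sequence (open loop).

    Composition of the leaky integrator and the FN unit: the stimulus starts
    at 0, the unit at its rest state.
    """
    if duration is None:
        duration = (incoming.times[-1] if len(incoming) else 0.0) + 20.0 * stim_params.tau
    traj = propagate_stimulus(0.0, incoming, stim_params)
    _, spikes = simulate_fn(params, traj, duration, dt=dt)
    return spikes
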