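"""Foraging outside the nest as an infinite-server queue.

A departing forager searches until it finds a seed, so trips need no
waiting: the foraging population is an M/G/infinity queue whose "service
time" is the trip duration, modelled as a chi-square random variable with
mean ``D`` minutes.  Queue formulas run in minutes (t' = t/60); the
simulator schedules returns in seconds.

For the chi-square family the trip-time CDF is
``F(x, D) = 1 - Q(D/2, x/2)`` with ``Q`` the regularized upper incomplete
gamma ratio, which reduces to ``1 - exp(-x/2)`` at D = 2.  Fractional ``D``
is handled through the gamma(shape D/2, scale 2) representation.

Standard M/G/infinity results used here, for a nonhomogeneous Poisson
departure stream ``r_out``:

* the number outside is Poisson with mean
  ``E[Q(t')] = ∫_0^∞ r_out(t'-x) (1-F(x,D)) dx`` (→ r*·D at steady state);
* the return stream is again Poisson with rate
  ``r_in(t') = ∫_0^∞ r_out(t'-x) dF(x, D)``, i.e. the trip-time-density
  convolution of the departure rate, so a constant rate is a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats
from scipy.integrate import quad

from .errors import DomainError, InvalidParameterError

__all__ = [
    "DelayModel",
    "trip_cdf",
    "trip_pdf",
    "sample_trip_times",
    "expected_outside",
    "incoming_rate_from_outgoing",
    "step_relaxation_gap",
]


@dataclass(frozen=True)
class DelayModel:
    """Mean foraging-trip time ``D`` in minutes."""

    D: float

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise InvalidParameterError("mean trip time D must be > 0")

    @property
    def dist(self):
        return stats.chi2(self.D)


def trip_cdf(x, D: float):
    """P(trip time <= x minutes) for mean trip time D minutes."""
    if not D > 0:
        raise InvalidParameterError("D must be > 0")
    x = np.asarray(x, float)
    if np.any(x < 0):
        raise DomainError("trip time must be >= 0")
    out = stats.chi2.cdf(x, D)
    return float(out) if out.ndim == 0 else out


def trip_pdf(x, D: float):
    """Trip-time density (chi-square with D degrees of freedom), minutes^-1."""
    if not D > 0:
        raise InvalidParameterError("D must be > 0")
    x = np.asarray(x, float)
    out = stats.chi2.pdf(x, D)
    return float(out) if out.ndim == 0 else out


def sample_trip_times(
    n: int, D: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """n i.i.d. trip durations (minutes); gamma(D/2, scale 2) draw so that
    fractional D is well defined."""
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    if not D > 0:
        raise InvalidParameterError("D must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return 2.0 * rng.standard_gamma(D / 2.0, n)


def _x_breakpoints(t_prime: float, x_hi: float, breakpoints) -> list:
    if breakpoints is None:
        return []
    pts = [t_prime - float(b) for b in breakpoints]
    return sorted(p for p in pts if 0.0 < p < x_hi)


def expected_outside(
    r_out: Callable[[float], float] | float,
    D: float,
    t_prime: float,
    rel_tol: float = 1e-10,
    breakpoints=None,
) -> float:
    """Expected number of foragers outside at time t' (minutes).

    ``r_out`` is the departure rate in ants/minute defined on (-inf, t'];
    a scalar is treated as a constant rate (giving exactly r*·D).
    ``breakpoints`` lists times (in the t' axis) where the rate is
    discontinuous or sharply peaked, so the quadrature subdivides there.
    """
    if not D > 0:
        raise InvalidParameterError("D must be > 0")
    if np.isscalar(r_out):
        if r_out < 0:
            raise InvalidParameterError("rate must be >= 0")
        return float(r_out) * D
    # integrate r_out(t'-x) * survival(x); the survival factor decays like a
    # chi-square tail, so truncate where it is < 1e-14
    x_hi = stats.chi2.isf(1e-14, D)
    val, _ = quad(
        lambda x: r_out(t_prime - x) * stats.chi2.sf(x, D),
        0.0,
        x_hi,
        limit=400,
        epsrel=rel_tol,
        epsabs=1e-12,
        points=_x_breakpoints(t_prime, x_hi, breakpoints) or None,
    )
    if not np.isfinite(val):
        raise DomainError("expected-outside integral did not converge")
    return float(val)


def incoming_rate_from_outgoing(
    r_out: Callable[[float], float] | float,
    D: float,
    t_prime,
    breakpoints=None,
) -> np.ndarray | float:
    """Return (incoming) rate implied by a departure-rate history.

    Convolution of ``r_out`` with the trip-time density; a constant rate maps
    to itself.  ``t_prime`` may be scalar or an array of times in minutes.
    ``breakpoints`` as in :func:`expected_outside`.
    """
    if not D > 0:
        raise InvalidParameterError("D must be > 0")
    if np.isscalar(r_out):
        r = float(r_out)
        t = np.asarray(t_prime, float)
        return r if t.ndim == 0 else np.full(t.shape, r)
    x_hi = stats.chi2.isf(1e-14, D)

    def one(tp: float) -> float:
        val, _ = quad(
            lambda x: r_out(tp - x) * stats.chi2.pdf(x, D),
            0.0,
            x_hi,
            limit=400,
            epsabs=1e-12,
            epsrel=1e-10,
            points=_x_breakpoints(tp, x_hi, breakpoints) or None,
        )
        return val

    t = np.asarray(t_prime, float)
    if t.ndim == 0:
        return float(one(float(t)))
    return np.array([one(tp) for tp in t])


def step_relaxation_gap(r_star: float, D: float, t_prime):
    """|r_out - r_in| after a step from 0 to r* at t' = 0.

    Equals ``r* · Q(D/2, t'/2)`` (the chi-square survival function), which
    for D = 2 is ``r* · exp(-t'/2)``: the queue output relaxes to the input
    exponentially fast.
    """
    t = np.asarray(t_prime, float)
    out = r_star * stats.chi2.sf(t, D)
    return float(out) if out.ndim == 0 else out
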