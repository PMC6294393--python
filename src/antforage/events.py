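"""Forager crossing events and instantaneous-rate estimation.

A colony's foraging traffic is observed as two point processes: the times at
which foragers cross a reference line going out of the nest, and the times at
which they cross it coming back in.  This module provides the event-sequence
container, the boxcar (sliding-window) rate estimator used to turn spike
trains into rates in ants/sec, the cumulative out-minus-in count (the number
of foragers currently outside the nest when applied to a closed system), and
a Poisson fixture generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "EventSequence",
    "RateSeries",
    "estimate_rate",
    "cumulative_outside",
    "generate_poisson_events",
    "DEFAULT_WINDOW",
]

#: Width of the boxcar rate-estimation window, seconds.
DEFAULT_WINDOW = 300.0


@dataclass(frozen=True)
class EventSequence:
    """An ordered sequence of forager crossing times, in seconds.

    Simultaneous events are allowed (multiplicity counts): merging or
    probabilistic thinning of spike trains can produce coincident times.

    Parameters
    ----------
    times:
        Nondecreasing, finite, nonnegative timestamps in seconds.
    label:
        Either ``"in"`` (foragers entering the nest) or ``"out"``.
    """

    times: np.ndarray
    label: str = "in"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1:
            raise InvalidParameterError("event times must be a 1-D sequence")
        if t.size and (not np.all(np.isfinite(t)) or t[0] < 0):
            raise InvalidParameterError("event times must be finite and >= 0")
        if t.size and np.any(np.diff(t) < 0):
            raise InvalidParameterError("event times must be nondecreasing")
        if self.label not in ("in", "out"):
            raise InvalidParameterError(f"label must be 'in' or 'out', got {self.label!r}")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return int(self.times.size)

    def shifted(self, delta: float) -> "EventSequence":
        """Return a copy with all times translated by ``delta`` seconds."""
        return EventSequence(self.times + delta, self.label)


@dataclass(frozen=True)
class RateSeries:
    """A rate estimate (ants/sec) on a time grid, with the window used."""

    grid_times: np.ndarray
    rates: np.ndarray
    window: float = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        g = np.asarray(self.grid_times, float)
        r = np.asarray(self.rates, float)
        if g.shape != r.shape:
            raise InvalidParameterError("grid and rates must have equal length")
        if r.size and r.min() < 0:
            raise InvalidParameterError("rates must be nonnegative")
        object.__setattr__(self, "grid_times", g)
        object.__setattr__(self, "rates", r)


def estimate_rate(
    events: EventSequence,
    window: float = DEFAULT_WINDOW,
    grid: np.ndarray | None = None,
    t_start: float | None = None,
    t_end: float | None = None,
) -> RateSeries:
    """Boxcar estimate of the instantaneous event rate.

    The rate at grid time ``t`` is the number of events in
    ``[t - window/2, t + window/2]`` divided by the length of that interval
    actually covered by the record.  Near the record edges the window is
    truncated and the covered length is used as the denominator, which avoids
    the artificial ramp a fixed denominator would produce at the start and
    end of a recording.

    Parameters
    ----------
    events:
        The event sequence.
    window:
        Boxcar width in seconds (default 300).
    grid:
        Times at which to evaluate the rate; defaults to a 1-second grid
        spanning the record.
    t_start, t_end:
        Extent of the recording, used for edge truncation.  Default to the
        grid extent.
    """
    if not window > 0:
        raise InvalidParameterError("window must be positive")
    t = events.times
    if grid is None:
        hi = float(t[-1]) if t.size else window
        grid = np.arange(0.0, hi + 1.0, 1.0)
    grid = np.asarray(grid, float)
    if grid.size and np.any(np.diff(grid) < 0):
        raise InvalidParameterError("grid must be sorted")
    ts = grid[0] if t_start is None else float(t_start)
    te = grid[-1] if t_end is None else float(t_end)
    lo = np.maximum(grid - window / 2.0, ts)
    hi = np.minimum(grid + window / 2.0, te)
    covered = np.maximum(hi - lo, 1e-12)
    counts = np.searchsorted(t, hi, side="right") - np.searchsorted(t, lo, side="left")
    return RateSeries(grid, counts / covered, window)


def cumulative_outside(
    in_events: EventSequence,
    out_events: EventSequence,
    grid: np.ndarray,
) -> np.ndarray:
    """Number of foragers outside the nest versus time.

    Returns, at each grid time ``t``, the count of out-events up to ``t``
    minus the count of in-events up to ``t``.  For a closed colony whose
    every departure is matched by a later return this equals the number of
    active foragers currently outside, and is nonnegative.
    """
    grid = np.asarray(grid, float)
    n_out = np.searchsorted(out_events.times, grid, side="right")
    n_in = np.searchsorted(in_events.times, grid, side="right")
    return n_out - n_in


def generate_poisson_events(
    rate: float,
    duration: float,
    rng: np.random.Generator | int | None = None,
    label: str = "in",
) -> EventSequence:
    """Homogeneous Poisson event sequence on ``[0, duration)``.

    Inter-event intervals are exponential with mean ``1/rate``; a fixed seed
    yields an identical sequence.
    """
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    if duration < 0:
        raise InvalidParameterError("duration must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if rate == 0 or duration == 0:
        return EventSequence(np.empty(0), label)
    n = rng.poisson(rate * duration)
    return EventSequence(np.sort(rng.uniform(0.0, duration, n)), label)
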