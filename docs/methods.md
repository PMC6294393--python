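# Methods

## The model

Desert harvester ant colonies regulate foraging without central control.
Available foragers wait in the nest entrance chamber and are stimulated to
leave by brief antennal contacts with returning food-bearing foragers; each
departing forager searches until it finds a seed and then returns, closing a
feedback loop between activity inside and outside the nest.  The package
models this loop with three coupled components.

**Stimulus (interactions).**  The contact stimulus experienced by the
available-forager pool is a leaky integrator driven by the incoming event
stream:

    ds/dt = -s/tau + k * lambda_in(t),

with jump size `k = 0.3` per incoming forager (dimensionless) and decay time
constant `tau = 0.41` s.  Between events the solution is exactly
exponential, so the implementation stores jump times and evaluates `s`
analytically — there is no interpolation error in the stimulus path.  Under
homogeneous Poisson input `s` is a shot-noise process; Campbell's theorem
gives the stationary mean `r k tau` and variance `r k^2 tau / 2`, used
throughout as closed-form oracles.

**Activation (response of available foragers).**  The pool's activation is a
single phenomenological FitzHugh–Nagumo (FN) unit

    eps1*eps2 * dv/dt = v - v^3/3 - c*u - a + s
    eps1      * du/dt = v - c*u

with `a = 0.35`, `eps1 = 0.2`, `eps2 = 0.05`.  An upward crossing of
`v` through 0.75 is one departure.  The volatility `c` scales the recovery
feedback: higher `c` means fewer contacts are needed to trigger departures
and faster oscillations.  The unit rests for `s < b1`, oscillates for
`b1 < s < b2`, and saturates (crowding, entrance-tunnel capacity) for
`s > b2`, where `b1,2 = a -/+ (1/3)(1 - c*eps2)^(3/2)` are the two Hopf
points.  With the default `a`, `k > b1` for all `c <= 5`, so every isolated
incoming forager elicits at least one departure.

**Foraging (random delay).**  Trips are independent chi-square random
variables with mean `D` minutes (fractional `D` via the gamma(D/2, scale 2)
representation).  Because searching needs no queueing, the population
outside the nest is an M/G/∞ system: for a Poisson departure stream the
number outside is Poisson with mean `∫ r_out(t'-x)(1-F(x,D)) dx` (→ `r* D`
at steady state), and the return stream is again Poisson with rate equal to
the trip-density convolution of the departure rate.

**Closing the loop; informed and uninformed foragers.**  Foragers that have
not yet been outside ("uninformed", volatility `c_u`) and foragers that have
been exposed to outside temperature and humidity at least once ("informed",
`c_i`) are modelled as two FN units sharing the stimulus.  Spikes are
combined by probabilistic thinning with the informed fraction `x_i` of the
available pool: uninformed spikes are kept with probability `1 - x_i`,
informed spikes with `x_i`.  A kept spike removes one available forager of
the matching class (dropped, with a counter, if that pool is empty — pool
exhaustion behaviour is a modelling choice, not an observable of the
original system), schedules a chi-square trip, and every return joins the
informed pool permanently for the day.  Exogenous seed arrivals (the sparse
morning trickle that starts foraging, default Poisson 0.01 ants/s over the
first `60*(D+1)` s) bump the stimulus but are not colony members.
Conservation `n_u + n_i + outside = N` holds exactly and is asserted in
tests.

## Numerics

* **Integration.**  Fixed-step classical RK4 with `dt = 1 ms`
  (`<= eps1*eps2/10`, resolving the 10 ms fast timescale), with the stimulus
  advanced analytically inside each step and all event times (arrivals,
  returns, trace samples) forced onto the step mesh.  The kernel was
  cross-checked against scipy's LSODA at `rtol 1e-10`: spike times and the
  spiking-regime boundaries agree, and halving `dt` moves closed-loop
  steady-state rates by under 1%.  Inner loops are numba-compiled.
* **Spike detection.**  Upward threshold crossing with hysteresis (the state
  must fall below threshold before the next spike); crossing times by linear
  interpolation within the step.  Default initial condition is the rest
  state at the initial stimulus, with a 1e-6 kick so a start exactly on an
  unstable equilibrium still reaches the limit cycle.
* **Stationary stimulus density.**  The density under Poisson drive
  satisfies the level-crossing balance `(s/tau) p(s) = r [P(s) - P(s-k)]`,
  solved piece-by-piece on intervals of width `k`.  The first piece is the
  exact power law `p ∝ s^(r*tau - 1)` (integrably divergent at 0 for
  `r*tau < 1`) and is handled analytically together with its CDF; later
  pieces use an implicit trapezoid step of the cumulative form, which is
  robust to the integrable kinks at multiples of `k`.  Support is truncated
  at `max(2, mean + 12 sd)` (captured mass > 0.999) and normalized
  numerically.  Validation: Kolmogorov–Smirnov distance below 0.003 against
  10^6 exact stationary Monte-Carlo samples for rates 0.5–5 ants/s, and
  Campbell means to 0.1%.
* **Random numbers.**  Each closed-loop run seeds one in-kernel legacy numpy
  stream (thinning + trip draws) and one SeedSequence child for the
  exogenous fixture; reruns from the same config are bit-identical.

## Analytic machinery

**Limit-cycle period.**  `lc_period` is the leading-order
singular-perturbation (slow-branch transit-time) approximation

    T(s, c) = (eps1/c) [ ∫_1^2 (v^2-1)/(v^3/3 - (s-a)) dv
                       + ∫_1^2 (v^2-1)/(v^3/3 + (s-a)) dv ],

exactly proportional to `1/c` and symmetric about `s = a`.  At the default
`eps2 = 0.05` the neglected fold corrections (O(eps2^(2/3)) per fold) are
not small: the approximation underestimates the measured period by 29%
(c = 0.5) to 142% (c = 5), converging as `eps2 → 0` (verified over
eps2 ∈ {0.05, 0.02, 0.01}).  `fn_period` therefore measures the true period
by direct integration, and the input/output machinery uses it by default
(`period="numeric"`); the asymptotic form remains available
(`period="asymptotic"`).

**Nest I/O curves.**  Under Poisson input the stimulus is ergodic, so the
mean outgoing rate at fixed `c` is approximated quasi-statically:

    r_out(r_in, c) = ∫_{b1}^{b2} p(s, r_in) / T(s, c) ds .

With the measured period this prediction sits slightly *below* open-loop
simulation (Poisson input trials, spike counts): the quasi-static integral
misses the extra spikes fired at each entry of `s` into the oscillating
band.  Measured agreement at c ∈ {1, 2, 5}: within ~25% over the rising and
plateau region of the curve, degrading to ~30–40% in the saturating tail
where band re-entries from above dominate; the simulated curve is higher
everywhere.  Known limitation: with the asymptotic period instead, the
analytic curve overshoots the simulation by up to a factor ~1.7 at c = 2 —
the two period models bracket the truth.

**Iterated map and steady states.**  Feeding the curve through the queue
(which preserves a constant rate) makes the colony a discrete map
`r_{n+1} = G_c(r_n)`; fixed points are found by bracketing diagonal
crossings of a monotone (PCHIP) interpolant, classified by local slope,
cross-checked by cobweb iteration, with near-tangencies (|G'-1| < 0.05)
flagged marginal.  Closed-loop simulations with `c_u = c_i = c` equilibrate
on the diagonal crossing of the *simulated* curve to ~1%; the quasi-static
analytic fixed point sits ~19% below it at c = 2 (same undercount as above).
Because the map hugs the diagonal near the critical volatility, fixed-point
positions there are ill-conditioned: a few-percent vertical shift of the
curve moves the steady-state rate by tens of percent.  This conditioning is
the dominant source of disagreement between independent implementations of
the same equations.

**Critical volatility.**  Sustained foraging requires the map to rise above
the diagonal at low rate, i.e. more than one departure per isolated
arrival.  A single arrival lifts `s` to `k`, which stays above `b1` for
`-tau log(b1/k)` seconds; dividing by a per-oscillation time cost bounds the
number of departures.  The time cost is a convention (the `s`-argument and
fraction of the period approximation), and the package implements four,
calibrated once against the analytic anchor value 0.5287 for this bound:

| convention   | per-oscillation cost                  | root of bound = 2 |
|--------------|---------------------------------------|-------------------|
| `half-at-b1` | half the transit period at `s → b1`   | 0.468 (default)   |
| `midpoint`   | transit period at `(b1+b2)/2`         | 0.916             |
| `at-k`       | transit period at `s = k`             | 0.920             |
| `min-band`   | min transit period over `(b1, k]`     | 0.920             |

No convention built on the leading-order transit time reproduces the anchor
exactly (the anchor's implied per-oscillation cost lies between the half-
and full-period values); `half-at-b1` — motivated by the first excursion
starting mid-cycle from the resting branch — comes closest and is the
default.  The *operational* counterpart, the volatility above which direct
simulation of one isolated arrival yields a second departure, is
`two_spike_threshold()` ≈ 1.01; between the bound root and that threshold
the map's diagonal tangency makes the closed-loop outcome
initialization-sensitive.

## The synthetic-data generator

`generate_poisson_events` (homogeneous Poisson streams, 0.1–5 ants/s for
open-loop curves; 0.01 ants/s sparse seeds for closed-loop runs) emulates
the statistical character of line-crossing observations near a nest.  Real
colony records additionally show diurnal nonstationarity, observation gaps,
bursty departures at foraging onset and weather-driven trends; none of these
are generated, so passing tests demonstrate correctness of the model
dynamics and estimators under the model's own assumptions, not goodness of
fit to any field recording.

## Study-condition defaults

| parameter | value | meaning |
|-----------|-------|---------|
| k         | 0.3   | stimulus jump per incoming forager |
| tau       | 0.41 s | stimulus decay time constant |
| a         | 0.35  | stimulus offset (sets `b1` so that `k > b1` for c ≤ 5) |
| eps1      | 0.2   | FN-vs-stimulus timescale separation |
| eps2      | 0.05  | fast-vs-slow FN timescale separation |
| threshold | 0.75  | activation level counted as a departure |
| window    | 300 s | boxcar width for rate estimates |
| duration  | 3 h   | closed-loop run length |
| seed rate | 0.01 ants/s | exogenous arrivals over the first 60(D+1) s |

Boxcar rate estimates near record edges use the truncated window with the
actually covered length as denominator (no artificial ramp); the window is
closed on both ends, which double-counts events exactly on the edge lattice
— irrelevant for continuous-time data.  The outside-count sign convention is
departures minus returns, the nonnegative number of active foragers outside.

## Known limitations

* Two volatility classes only; information decay, repeated-exposure classes
  (M > 2) and mid-day reduction of N are out of scope.
* The quasi-static I/O curve under- (numeric period) or over-
  (asymptotic period) counts spikes near band boundaries; treat analytic
  steady-state magnitudes near the critical volatility as qualitative.
* Trip times are exchangeable chi-square draws; no food-availability
  dependence or spatial structure.
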