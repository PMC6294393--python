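"""numba-jitted inner loops.

The fast activation timescale of the oscillator is eps1*eps2 = 0.01 s, so a
three-hour colony simulation at the default 1 ms step is ~10^7 RK4 steps;
these loops are JIT-compiled.  The stimulus is advanced analytically inside
each step (its ODE has an exact exponential solution), event times are forced
to be step boundaries, and spike times are located by linear interpolation of
the upward threshold crossing with hysteresis (the activation state must fall
back below threshold before another spike can be recorded).
"""

import numpy as np
from numba import njit

__all__ = ["fn_integrate", "closed_loop_integrate"]


@njit(cache=True)
def _rk4_step(v, u, s, sm, se, h, c, a, e12, e1):
    """One RK4 step of the activation/recovery pair; s given at t, t+h/2, t+h."""
    k1v = (v - v**3 / 3.0 - c * u - a + s) / e12
    k1u = (v - c * u) / e1
    v2 = v + 0.5 * h * k1v
    u2 = u + 0.5 * h * k1u
    k2v = (v2 - v2**3 / 3.0 - c * u2 - a + sm) / e12
    k2u = (v2 - c * u2) / e1
    v3 = v + 0.5 * h * k2v
    u3 = u + 0.5 * h * k2u
    k3v = (v3 - v3**3 / 3.0 - c * u3 - a + sm) / e12
    k3u = (v3 - c * u3) / e1
    v4 = v + h * k3v
    u4 = u + h * k3u
    k4v = (v4 - v4**3 / 3.0 - c * u4 - a + se) / e12
    k4u = (v4 - c * u4) / e1
    vn = v + h / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
    un = u + h / 6.0 * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
    return vn, un


@njit(cache=True)
def fn_integrate(
    ev_times,
    ev_jumps,
    s0,
    s_constant,
    duration,
    dt,
    k_unused,
    tau,
    a,
    eps1,
    eps2,
    c,
    thr,
    v_init,
    u_init,
    record_stride,
    max_spikes,
):
    """Integrate one FN unit against a piecewise-exponential stimulus.

    ev_times/ev_jumps: stimulus jump times and magnitudes (already scaled by
    multiplicity).  If ``s_constant`` the stimulus stays at s0.  Returns
    (spike_times[:n], trace_t, trace_v, trace_u, trace_s, ok).  record_stride
    <= 0 disables the trace.
    """
    e12 = eps1 * eps2
    v = v_init
    u = u_init
    s = s0
    armed = v < thr
    spikes = np.empty(max_spikes)
    nsp = 0
    n_ev = len(ev_times)
    i_ev = 0
    nrec_cap = 0 if record_stride <= 0 else int(duration / (dt * record_stride)) + 2
    tr_t = np.empty(nrec_cap)
    tr_v = np.empty(nrec_cap)
    tr_u = np.empty(nrec_cap)
    tr_s = np.empty(nrec_cap)
    nrec = 0
    step_i = 0
    if nrec_cap > 0:
        tr_t[0] = 0.0
        tr_v[0] = v
        tr_u[0] = u
        tr_s[0] = s
        nrec = 1
    t = 0.0
    ok = True
    while t < duration - 1e-12:
        t_next = t + dt
        if i_ev < n_ev and ev_times[i_ev] < t_next:
            t_next = ev_times[i_ev]
        if t_next > duration:
            t_next = duration
        h = t_next - t
        if h > 1e-15:
            if s_constant:
                sm = s
                se = s
            else:
                eh = np.exp(-0.5 * h / tau)
                sm = s * eh
                se = sm * eh
            vn, un = _rk4_step(v, u, s, sm, se, h, c, a, e12, eps1)
            if not (np.isfinite(vn) and np.isfinite(un)):
                ok = False
                break
            if armed and v <= thr and vn > thr:
                if nsp < max_spikes:
                    spikes[nsp] = t + h * (thr - v) / (vn - v)
                    nsp += 1
                armed = False
            if (not armed) and vn < thr:
                armed = True
            v = vn
            u = un
            s = se
            step_i += 1
            if record_stride > 0 and step_i % record_stride == 0 and nrec < nrec_cap:
                tr_t[nrec] = t_next
                tr_v[nrec] = v
                tr_u[nrec] = u
                tr_s[nrec] = s
                nrec += 1
        t = t_next
        while i_ev < n_ev and ev_times[i_ev] <= t + 1e-12:
            s += ev_jumps[i_ev]
            i_ev += 1
    return (
        spikes[:nsp],
        tr_t[:nrec],
        tr_v[:nrec],
        tr_u[:nrec],
        tr_s[:nrec],
        ok,
    )


@njit(cache=True)
def fn_period_const(c, s, a, eps1, eps2, thr, dt, duration):
    """Spike-to-spike period at constant stimulus; NaN if fewer than 4 spikes.

    Starts slightly off the rest equilibrium so the limit cycle (if any) is
    reached; the returned value is the mean of the second half of the
    inter-spike intervals.
    """
    e12 = eps1 * eps2
    d = 3.0 * (s - a)
    v = np.sign(d) * np.abs(d) ** (1.0 / 3.0) + 1e-3
    u = v / c
    armed = v < thr
    sp = np.empty(8192)
    nsp = 0
    n = int(duration / dt)
    t = 0.0
    for _ in range(n):
        vn, un = _rk4_step(v, u, s, s, s, dt, c, a, e12, eps1)
        if armed and v <= thr and vn > thr and nsp < 8192:
            sp[nsp] = t + dt * (thr - v) / (vn - v)
            nsp += 1
            armed = False
        if (not armed) and vn < thr:
            armed = True
        v = vn
        u = un
        t += dt
    if nsp < 4:
        return np.nan
    isis = np.diff(sp[:nsp])
    m = len(isis) // 2
    return isis[m:].mean()


@njit(cache=True)
def closed_loop_integrate(
    exo_times,
    duration,
    dt,
    k,
    tau,
    a,
    eps1,
    eps2,
    thr,
    c_u,
    c_i,
    n_foragers,
    d_minutes,
    seed,
    sample_dt,
):
    """Event-driven closed-loop colony simulation.

    Two FN units (uninformed volatility c_u, informed c_i) share the stimulus
    s.  A spike of the uninformed unit is kept with probability 1-x_i, of the
    informed unit with probability x_i, where x_i is the informed fraction of
    the available pool at the spike instant.  A kept spike removes one
    available forager of the matching class (dropped, and counted, if that
    pool is empty), and schedules its return after a chi-square trip of mean
    d_minutes (sampled in minutes, converted to seconds).  Every return joins
    the informed pool, bumps s by k and is recorded as an incoming event.
    Exogenous events bump s only.  Simultaneous unit spikes are processed
    uninformed-first.

    Returns (spikes_u, spikes_i, out_times, return_times, n_dropped,
    samp_t, samp_s, samp_xi, samp_q, samp_nu, ok).
    """
    np.random.seed(seed)
    e12 = eps1 * eps2
    v0 = -((3.0 * a) ** (1.0 / 3.0))
    vs = np.array([v0, v0])
    us = np.array([v0 / c_u, v0 / c_i])
    cs = np.array([c_u, c_i])
    armed = np.array([v0 < thr, v0 < thr])
    s = 0.0
    n_u = n_foragers
    n_i = 0
    x_i = 0.0
    ret = np.empty(n_foragers)
    n_act = 0
    # generous capacity: spike rate is bounded by the natural frequency
    cap = int(duration * (max(c_u, c_i) * 3.0 + 2.0)) + 1024
    sp_u = np.empty(cap)
    nsp_u = 0
    sp_i = np.empty(cap)
    nsp_i = 0
    out_t = np.empty(cap)
    n_out = 0
    in_t = np.empty(cap)
    n_in = 0
    n_drop = 0
    nsamp_cap = int(duration / sample_dt) + 4
    samp_t = np.empty(nsamp_cap)
    samp_s = np.empty(nsamp_cap)
    samp_xi = np.empty(nsamp_cap)
    samp_q = np.empty(nsamp_cap, np.int64)
    samp_nu = np.empty(nsamp_cap, np.int64)
    ns = 0
    t = 0.0
    i_exo = 0
    n_exo = len(exo_times)
    t_samp = 0.0
    ok = True
    while t < duration - 1e-9:
        t_next = t + dt
        if i_exo < n_exo and exo_times[i_exo] < t_next:
            t_next = exo_times[i_exo]
        if n_act > 0 and ret[0] < t_next:
            t_next = ret[0]
        if t_samp < t_next:
            t_next = t_samp
        if t_next > duration:
            t_next = duration
        h = t_next - t
        if h > 1e-15:
            eh = np.exp(-0.5 * h / tau)
            sm = s * eh
            se = sm * eh
            for j in range(2):
                vn, un = _rk4_step(vs[j], us[j], s, sm, se, h, cs[j], a, e12, eps1)
                if not (np.isfinite(vn) and np.isfinite(un)):
                    ok = False
                if armed[j] and vs[j] <= thr and vn > thr:
                    armed[j] = False
                    t_sp = t + h * (thr - vs[j]) / (vn - vs[j])
                    if j == 0:
                        if nsp_u < cap:
                            sp_u[nsp_u] = t_sp
                            nsp_u += 1
                        keep = np.random.random() < 1.0 - x_i
                        pool = n_u
                    else:
                        if nsp_i < cap:
                            sp_i[nsp_i] = t_sp
                            nsp_i += 1
                        keep = np.random.random() < x_i
                        pool = n_i
                    if keep:
                        if pool > 0:
                            if j == 0:
                                n_u -= 1
                            else:
                                n_i -= 1
                            if n_out < cap:
                                out_t[n_out] = t_sp
                                n_out += 1
                            trip_min = 2.0 * np.random.standard_gamma(0.5 * d_minutes)
                            t_ret = t_sp + 60.0 * trip_min
                            lo = 0
                            hi = n_act
                            while lo < hi:
                                mid = (lo + hi) // 2
                                if ret[mid] < t_ret:
                                    lo = mid + 1
                                else:
                                    hi = mid
                            for m in range(n_act, lo, -1):
                                ret[m] = ret[m - 1]
                            ret[lo] = t_ret
                            n_act += 1
                            if n_u + n_i > 0:
                                x_i = n_i / (n_u + n_i)
                        else:
                            n_drop += 1
                if (not armed[j]) and vn < thr:
                    armed[j] = True
                vs[j] = vn
                us[j] = un
            s = se
            if not ok:
                break
        t = t_next
        while i_exo < n_exo and exo_times[i_exo] <= t + 1e-12:
            s += k
            i_exo += 1
        while n_act > 0 and ret[0] <= t + 1e-12:
            if n_in < cap:
                in_t[n_in] = ret[0]
                n_in += 1
            for m in range(n_act - 1):
                ret[m] = ret[m + 1]
            n_act -= 1
            n_i += 1
            s += k
            x_i = n_i / (n_u + n_i)
        if t >= t_samp - 1e-12 and ns < nsamp_cap:
            samp_t[ns] = t
            samp_s[ns] = s
            samp_xi[ns] = x_i
            samp_q[ns] = n_act
            samp_nu[ns] = n_u
            ns += 1
            t_samp += sample_dt
    return (
        sp_u[:nsp_u],
        sp_i[:nsp_i],
        out_t[:n_out],
        in_t[:n_in],
        n_drop,
        samp_t[:ns],
        samp_s[:ns],
        samp_xi[:ns],
        samp_q[:ns],
        samp_nu[:ns],
        ok,
    )
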