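"""Compiled numerical kernels.

Everything in this module is deliberately free of Python objects so that
numba can compile it: the delay-differential integrator, the delayed-SSA
single-cell segment simulator, and the Euler-Maruyama integrator of the
amplitude/phase toy oscillator.  Orchestration (lineage trees, parameter
resampling, binomial partitioning at division) lives in plain Python.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Species indices used throughout: 0=r (LacI), 1=a (AraC), 2=g (immature GFP),
# 3=G (mature GFP).


@njit(cache=True)
def _hill(r, a, f, c_a, c_r):
    u = a / c_a
    return (1.0 / f + u) / ((1.0 + u) * (1.0 + r / c_r) ** 2)


@njit(cache=True)
def dde_integrate(
    y0,  # float64[4] constant initial history
    t_end,
    dt,
    alpha_r,
    alpha_a,
    alpha_g,
    gamma_r,
    gamma_a,
    gamma_g,
    gamma_G,
    r0_mm,
    c_a,
    c_r,
    f,
    tau_r,
    tau_a,
    tau_g,
    lam,
    beta,
):
    """Fixed-step RK4 for the four delayed rate equations.

    Delayed arguments are linearly interpolated from the stored solution;
    for t < tau the constant initial history is used.  Returns the (n+1, 4)
    solution array on the grid i*dt.
    """
    n = int(np.ceil(t_end / dt))
    Y = np.empty((n + 1, 4))
    Y[0, :] = y0

    def interp(i, tau):
        # delayed state at time i*dt - tau
        j = i - tau / dt
        if j <= 0.0:
            return Y[0, 0], Y[0, 1]
        j0 = int(np.floor(j))
        w = j - j0
        if j0 >= i:
            return Y[i, 0], Y[i, 1]
        r = (1.0 - w) * Y[j0, 0] + w * Y[j0 + 1, 0]
        a = (1.0 - w) * Y[j0, 1] + w * Y[j0 + 1, 1]
        return r, a

    for i in range(n):
        # delayed promoter states for the three production terms, evaluated
        # at the RK stage offsets (0, dt/2, dt/2, dt)
        hr0_r, hr0_a = interp(i, tau_r)
        ha0_r, ha0_a = interp(i, tau_a)
        hg0_r, hg0_a = interp(i, tau_g)
        hr1_r, hr1_a = interp(i, tau_r - 0.5 * dt)
        ha1_r, ha1_a = interp(i, tau_a - 0.5 * dt)
        hg1_r, hg1_a = interp(i, tau_g - 0.5 * dt)
        hr2_r, hr2_a = interp(i, tau_r - dt)
        ha2_r, ha2_a = interp(i, tau_a - dt)
        hg2_r, hg2_a = interp(i, tau_g - dt)

        prod_r0 = alpha_r * _hill(hr0_r, hr0_a, f, c_a, c_r)
        prod_a0 = alpha_a * _hill(ha0_r, ha0_a, f, c_a, c_r)
        prod_g0 = alpha_g * _hill(hg0_r, hg0_a, f, c_a, c_r)
        prod_r1 = alpha_r * _hill(hr1_r, hr1_a, f, c_a, c_r)
        prod_a1 = alpha_a * _hill(ha1_r, ha1_a, f, c_a, c_r)
        prod_g1 = alpha_g * _hill(hg1_r, hg1_a, f, c_a, c_r)
        prod_r2 = alpha_r * _hill(hr2_r, hr2_a, f, c_a, c_r)
        prod_a2 = alpha_a * _hill(ha2_r, ha2_a, f, c_a, c_r)
        prod_g2 = alpha_g * _hill(hg2_r, hg2_a, f, c_a, c_r)

        y = Y[i]
        k1 = _dde_rhs(y, prod_r0, prod_a0, prod_g0, gamma_r, gamma_a, gamma_g,
                      gamma_G, r0_mm, lam, beta)
        k2 = _dde_rhs(y + 0.5 * dt * k1, prod_r1, prod_a1, prod_g1, gamma_r,
                      gamma_a, gamma_g, gamma_G, r0_mm, lam, beta)
        k3 = _dde_rhs(y + 0.5 * dt * k2, prod_r1, prod_a1, prod_g1, gamma_r,
                      gamma_a, gamma_g, gamma_G, r0_mm, lam, beta)
        k4 = _dde_rhs(y + dt * k3, prod_r2, prod_a2, prod_g2, gamma_r,
                      gamma_a, gamma_g, gamma_G, r0_mm, lam, beta)
        ynew = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for s in range(4):
            if ynew[s] < 0.0:
                ynew[s] = 0.0
        Y[i + 1] = ynew
    return Y


@njit(cache=True)
def _dde_rhs(y, prod_r, prod_a, prod_g, gamma_r, gamma_a, gamma_g, gamma_G,
             r0_mm, lam, beta):
    tot = r0_mm + y[0] + y[1] + y[2] + y[3]
    out = np.empty(4)
    out[0] = prod_r - gamma_r * y[0] / tot - beta * y[0]
    out[1] = prod_a - gamma_a * y[1] / tot - beta * y[1]
    out[2] = prod_g - gamma_g * y[2] / tot - lam * y[2] - beta * y[2]
    out[3] = lam * y[2] - gamma_G * y[3] / tot - beta * y[3]
    return out


@njit(cache=True)
def _push(queue, tail, value):
    # append with amortised doubling; returns (queue, tail)
    if tail >= queue.shape[0]:
        new = np.empty(max(2 * queue.shape[0], 64))
        new[: queue.shape[0]] = queue
        queue = new
    queue[tail] = value
    return queue, tail + 1


@njit(cache=True)
def ssa_cell(
    seed,
    t0,
    t_end,
    counts,  # int64[4], modified in place
    v0,
    beta_growth,  # 0.0 for fixed-volume mode
    beta_dil,  # explicit dilution propensity term (fixed-volume mode only)
    alpha_r,
    alpha_a,
    alpha_g,
    gamma_r,
    gamma_a,
    gamma_g,
    gamma_G,
    r0_mm,
    c_a,
    c_r,
    f,
    tau_r,
    tau_a,
    tau_g,
    lam,
    q_r,  # float64[:] pending completion times per species, ascending
    q_a,
    q_g,
    frame_times,  # float64[:] global frame times inside [t0, t_end)
    fluor_out,  # float64[:] same length as frame_times, filled with G/V
):
    """Delayed SSA for one cell over [t0, t_end).

    Production reactions push a completion time t + tau onto the species
    queue instead of incrementing the count; whenever the earliest queued
    completion precedes the next reaction time it fires first.  Volume grows
    as v0 * exp(beta_growth (t - t0)); propensities are evaluated on
    concentrations (counts / V) with the production terms multiplied by V.

    Returns (q_r_left, q_a_left, q_g_left, status) where the leftover queues
    contain completion times >= t_end (pending events inherited by the
    daughters) and status is 0 on success, 1 if the event budget was hit.
    """
    np.random.seed(seed)
    t = t0
    # queue heads / tails
    hr, ha, hg = 0, 0, 0
    tr, ta, tg = q_r.shape[0], q_a.shape[0], q_g.shape[0]
    fi = 0
    nframe = frame_times.shape[0]
    max_events = 200_000_000
    n_events = 0
    status = 0
    big = 1.0e300

    while t < t_end:
        v = v0 * np.exp(beta_growth * (t - t0))
        inv_v = 1.0 / v
        conc_tot = (counts[0] + counts[1] + counts[2] + counts[3]) * inv_v
        h = _hill(counts[0] * inv_v, counts[1] * inv_v, f, c_a, c_r)
        d = 1.0 / (r0_mm + conc_tot)
        p = np.empty(8)
        p[0] = v * alpha_r * h
        p[1] = v * alpha_a * h
        p[2] = v * alpha_g * h
        p[3] = counts[0] * (beta_dil + gamma_r * d)
        p[4] = counts[1] * (beta_dil + gamma_a * d)
        p[5] = counts[2] * (beta_dil + gamma_g * d)
        p[6] = counts[3] * (beta_dil + gamma_G * d)
        p[7] = lam * counts[2]
        ptot = p[0] + p[1] + p[2] + p[3] + p[4] + p[5] + p[6] + p[7]

        # earliest queued completion
        tq = big
        which = -1
        if hr < tr and q_r[hr] < tq:
            tq = q_r[hr]
            which = 0
        if ha < ta and q_a[ha] < tq:
            tq = q_a[ha]
            which = 1
        if hg < tg and q_g[hg] < tq:
            tq = q_g[hg]
            which = 2

        if ptot <= 0.0:
            t_next = big
        else:
            t_next = t + np.random.exponential() / ptot

        if tq < t_next:
            t_new = tq
        else:
            t_new = t_next
        if t_new >= t_end:
            t_new = t_end

        # emit frames passed over during [t, t_new); counts constant here
        while fi < nframe and frame_times[fi] < t_new:
            vf = v0 * np.exp(beta_growth * (frame_times[fi] - t0))
            fluor_out[fi] = counts[3] / vf
            fi += 1

        if t_new >= t_end:
            t = t_end
            break
        t = t_new

        if tq < t_next:
            # queued completion fires: species count +1
            counts[which] += 1
            if which == 0:
                hr += 1
            elif which == 1:
                ha += 1
            else:
                hg += 1
        else:
            u = np.random.random() * ptot
            acc = 0.0
            rxn = 7
            for k in range(8):
                acc += p[k]
                if u < acc:
                    rxn = k
                    break
            if rxn == 0:
                q_r, tr = _push(q_r, tr, t + tau_r)
            elif rxn == 1:
                q_a, ta = _push(q_a, ta, t + tau_a)
            elif rxn == 2:
                q_g, tg = _push(q_g, tg, t + tau_g)
            elif rxn == 3:
                counts[0] -= 1
            elif rxn == 4:
                counts[1] -= 1
            elif rxn == 5:
                counts[2] -= 1
            elif rxn == 6:
                counts[3] -= 1
            else:
                counts[2] -= 1
                counts[3] += 1

        n_events += 1
        if n_events >= max_events:
            status = 1
            break

    # any frames not yet emitted (e.g. ptot became 0 with empty queues)
    while fi < nframe:
        vf = v0 * np.exp(beta_growth * (frame_times[fi] - t0))
        fluor_out[fi] = counts[3] / vf
        fi += 1

    return q_r[hr:tr].copy(), q_a[ha:ta].copy(), q_g[hg:tg].copy(), status


@njit(cache=True)
def toy_em(
    seed,
    t0,
    t_end,
    r_init,
    theta_init,
    r0,
    rho,
    period,
    omega,
    dt,
    r_floor,
    frame_times,
    x_out,
    r_out,
):
    """Euler-Maruyama for the amplitude/phase oscillator.

    dr     = rho (r0 - r) dt + Omega^{-1/2} dW1
    dtheta = (2 pi / T) (r0 / r) dt + (r sqrt(Omega))^{-1} dW2

    The amplitude is reflected at r_floor to keep the 1/r drift finite.
    Emits x = r cos(theta) at the requested frame times; returns
    (r_final, theta_final, n_floor_hits).
    """
    np.random.seed(seed)
    r = r_init
    theta = theta_init
    t = t0
    fi = 0
    nframe = frame_times.shape[0]
    sq_dt = np.sqrt(dt)
    sig_r = 1.0 / np.sqrt(omega)
    two_pi_T = 2.0 * np.pi / period
    n_floor = 0
    while t < t_end - 1.0e-12:
        while fi < nframe and frame_times[fi] <= t + 1.0e-9:
            x_out[fi] = r * np.cos(theta)
            r_out[fi] = r
            fi += 1
        step = dt
        if t + step > t_end:
            step = t_end - t
            sq = np.sqrt(step)
        else:
            sq = sq_dt
        dw1 = np.random.normal() * sq
        dw2 = np.random.normal() * sq
        r_new = r + rho * (r0 - r) * step + sig_r * dw1
        theta = theta + two_pi_T * (r0 / r) * step + sig_r / r * dw2
        if r_new < r_floor:
            r_new = 2.0 * r_floor - r_new
            if r_new < r_floor:
                r_new = r_floor
            n_floor += 1
        r = r_new
        t += step
    while fi < nframe:
        x_out[fi] = r * np.cos(theta)
        r_out[fi] = r
        fi += 1
    return r, theta, n_floor
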