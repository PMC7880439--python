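"""Numba inner loop of the Brownian dynamics propagator.

The kernel advances one filament through a pre-generated chunk of N(0,1)
noise (one row per step; row layout: triplets ``(x, y, theta)`` per *free*
monomer, monomers in ascending index order — this draw order is part of the
reproducibility contract).  All quantities are in internal units (nm, µs,
kT(295.15 K)); see :mod:`cryofil.constants`.

The temperature/viscosity schedule and the adaptive time step are refreshed
every ``HOIST`` steps: the step size is a small fraction of the stability
bound, so the schedule changes negligibly within a block, except near the
stop temperature where the step is additionally capped so a block never
overshoots the viscosity singularity.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import DRAG_R, DRAG_T, KB

#: schedule/timestep refresh interval, steps
HOIST = 16

#: termination codes
RUNNING, REACHED_T_STOP, REACHED_T_MAX = 0, 1, 2


@njit(cache=True, fastmath=True)
def run_chunk(x, y, th, n_fixed, R, b, th0, k,
              T0, v, Tstop, eta0, Ts, gam,
              safety, dt_fixed, noise_scale, scheme_lm,
              t0, t_max, noise, prev, steps_before,
              rec_t, rec_xy, rec_interval, rec_start,
              rec_every, state_buf, state_t, state_start):
    """Advance the chain through one noise chunk; return bookkeeping.

    Returns ``(steps_used, t_end, code, rec_count, state_count)`` where
    ``code`` is RUNNING / REACHED_T_STOP / REACHED_T_MAX.  ``rec_*`` is the
    fixed-real-time tip recording used by the immobilisation detector;
    ``state_buf`` receives full decimated states every ``rec_every`` steps.
    """
    n = x.shape[0]
    nf3 = 3 * (n - n_fixed)
    fx = np.empty(n)
    fy = np.empty(n)
    ft = np.empty(n)
    sn = np.empty(n)
    cs = np.empty(n)
    C = noise.shape[0]
    t = t0
    ct = DRAG_T * R
    cr = DRAG_R * R * R * R
    beff = b + 2.0 * k * R * R
    dt = 0.0
    igt = 0.0
    igr = 0.0
    st = 0.0
    sr = 0.0
    nrec = rec_start
    nstate = state_start
    for s in range(C):
        if s % HOIST == 0:
            T = T0 - v * t
            if T <= Tstop:
                return s, t, REACHED_T_STOP, nrec, nstate
            if t >= t_max:
                return s, t, REACHED_T_MAX, nrec, nstate
            eta = eta0 * (T / Ts - 1.0) ** (-gam)
            gt = ct * eta
            gr = cr * eta
            if dt_fixed > 0.0:
                dt = dt_fixed
            else:
                dt = safety * min(gt / k, gr / beff)
                if v > 0.0:
                    # never let one block cool past the stop temperature
                    cap = (0.1 * (T - Tstop) + 1e-2) / (v * HOIST)
                    if dt > cap:
                        dt = cap
            igt = dt / gt
            igr = dt / gr
            kT = KB * T
            st = noise_scale * np.sqrt(2.0 * kT * igt)
            sr = noise_scale * np.sqrt(2.0 * kT * igr)
        for i in range(n):
            fx[i] = 0.0
            fy[i] = 0.0
            ft[i] = 0.0
            sn[i] = np.sin(th[i])
            cs[i] = np.cos(th[i])
        for j in range(n - 1):
            rx = x[j] - x[j + 1] - R * (sn[j] + sn[j + 1])
            ry = y[j] - y[j + 1] + R * (cs[j] + cs[j + 1])
            dth = th[j + 1] - th[j]
            if dth > np.pi or dth <= -np.pi:
                # branch-free wrap; also terminates on inf/NaN blow-ups,
                # which the driver then reports as a too-large time step
                dth -= 2.0 * np.pi * np.round(dth / (2.0 * np.pi))
            m = b * (dth - th0)
            krx = k * rx
            kry = k * ry
            fx[j] += krx
            fy[j] += kry
            fx[j + 1] -= krx
            fy[j + 1] -= kry
            ft[j] += R * (-cs[j] * krx - sn[j] * kry) - m
            ft[j + 1] += R * (-cs[j + 1] * krx - sn[j + 1] * kry) + m
        for i in range(n_fixed, n):
            c = 3 * (i - n_fixed)
            n0 = noise[s, c]
            n1 = noise[s, c + 1]
            n2 = noise[s, c + 2]
            if scheme_lm:
                wx = 0.5 * (n0 + prev[c])
                wy = 0.5 * (n1 + prev[c + 1])
                wt = 0.5 * (n2 + prev[c + 2])
            else:
                wx = n0
                wy = n1
                wt = n2
            x[i] += -igt * fx[i] + st * wx
            y[i] += -igt * fy[i] + st * wy
            th[i] += -igr * ft[i] + sr * wt
            prev[c] = n0
            prev[c + 1] = n1
            prev[c + 2] = n2
        t += dt
        if rec_interval > 0.0 and t >= rec_interval * nrec:
            if nrec < rec_t.shape[0]:
                rec_t[nrec] = t
                rec_xy[nrec, 0] = x[n - 1]
                rec_xy[nrec, 1] = y[n - 1]
                nrec += 1
        if rec_every > 0 and (steps_before + s + 1) % rec_every == 0:
            if nstate < state_buf.shape[0]:
                for i in range(n):
                    state_buf[nstate, i] = x[i]
                    state_buf[nstate, n + i] = y[i]
                    state_buf[nstate, 2 * n + i] = th[i]
                state_t[nstate] = t
                nstate += 1
    return C, t, RUNNING, nrec, nstate
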