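"""Numba hot loops for the Gillespie simulations.

Kernels take a ``numpy.random.Generator`` (numba supports it in nopython
mode), consume it sequentially, and return extinction times; one kernel also
accumulates the time-weighted occupancy of the final pre-extinction window
into a 2-D histogram.  Both treatment schedules are handled: Poisson pulses
are an ordinary constant-propensity channel; periodic pulses fire exactly at
times k/nu, with the memoryless exponential clock simply re-drawn after each
pulse (statistically exact for time-homogeneous demographic rates).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EPS = 1e-9  # guards binary representation error in kappa*I


@njit(cache=True)
def _pulse_size(kappa, I, ceil_round):
    if I <= 0 or kappa <= 0.0:
        return 0
    x = kappa * I
    if ceil_round:
        r = int(math.ceil(x - _EPS))
    else:
        r = int(math.floor(x + _EPS))
    if r > I:
        r = I
    return r


@njit(cache=True)
def m1_extinction_time(beta, rem, kappa, nu, periodic, ceil_round, N, I0, t_max, rng):
    """One constrained-model realization; returns (time, extinct_flag)."""
    t = 0.0
    I = I0
    have_pulses = nu > 0.0 and kappa > 0.0
    next_pulse = 1.0 / nu if (periodic and have_pulses) else 1e308
    poisson_tr = nu if (have_pulses and not periodic) else 0.0
    while True:
        if I == 0:
            return t, True
        a_up = beta * I * (N - I) / N
        a_dn = rem * I
        a0 = a_up + a_dn + poisson_tr
        dt = rng.exponential(1.0 / a0)
        if periodic and t + dt >= next_pulse:
            if next_pulse > t_max:
                return t_max, False
            t = next_pulse
            I -= _pulse_size(kappa, I, ceil_round)
            next_pulse += 1.0 / nu
            continue
        t += dt
        if t > t_max:
            return t_max, False
        u = rng.random() * a0
        if u < a_up:
            I += 1
        elif u < a_up + a_dn:
            I -= 1
        else:
            I -= _pulse_size(kappa, I, ceil_round)


@njit(cache=True)
def m2_extinction_time(beta, gamma, mu, kappa, nu, periodic, ceil_round,
                       N, S0, I0, t_max, rng):
    """One full-model realization; returns (time, extinct_flag)."""
    t = 0.0
    S, I = S0, I0
    have_pulses = nu > 0.0 and kappa > 0.0
    next_pulse = 1.0 / nu if (periodic and have_pulses) else 1e308
    poisson_tr = nu if (have_pulses and not periodic) else 0.0
    a_birth = mu * N
    while True:
        if I == 0:
            return t, True
        a_ds = mu * S
        a_di = mu * I
        a_inf = beta * S * I / (S + I)
        a_rec = gamma * I
        a0 = a_birth + a_ds + a_di + a_inf + a_rec + poisson_tr
        dt = rng.exponential(1.0 / a0)
        if periodic and t + dt >= next_pulse:
            if next_pulse > t_max:
                return t_max, False
            t = next_pulse
            r = _pulse_size(kappa, I, ceil_round)
            S += r
            I -= r
            next_pulse += 1.0 / nu
            continue
        t += dt
        if t > t_max:
            return t_max, False
        u = rng.random() * a0
        if u < a_birth:
            S += 1
        elif u < a_birth + a_ds:
            S -= 1
        elif u < a_birth + a_ds + a_di:
            I -= 1
        elif u < a_birth + a_ds + a_di + a_inf:
            S -= 1
            I += 1
        elif u < a_birth + a_ds + a_di + a_inf + a_rec:
            S += 1
            I -= 1
        else:
            r = _pulse_size(kappa, I, ceil_round)
            S += r
            I -= r


@njit(cache=True)
def m2_prehistory(beta, gamma, mu, kappa, nu, periodic, ceil_round,
                  N, S0, I0, t_max, window, rng,
                  hist, y_lo, y_hi, x_lo, x_hi,
                  tbuf, sbuf, ibuf):
    """One full-model realization accumulating last-``window`` occupancy.

    The (time, S, I) history is kept in a circular buffer; at extinction the
    time-weighted occupancy of the final window is added to ``hist`` (rows:
    susceptible-fraction bins, cols: infected-fraction bins).  Returns
    (time, extinct_flag, truncated_flag); truncated means the buffer was too
    small to hold the whole window.
    """
    cap = tbuf.shape[0]
    head = 0
    count = 0
    t = 0.0
    S, I = S0, I0
    have_pulses = nu > 0.0 and kappa > 0.0
    next_pulse = 1.0 / nu if (periodic and have_pulses) else 1e308
    poisson_tr = nu if (have_pulses and not periodic) else 0.0
    a_birth = mu * N

    tbuf[0] = 0.0
    sbuf[0] = S
    ibuf[0] = I
    head = 1
    count = 1

    while I > 0:
        a_ds = mu * S
        a_di = mu * I
        a_inf = beta * S * I / (S + I)
        a_rec = gamma * I
        a0 = a_birth + a_ds + a_di + a_inf + a_rec + poisson_tr
        dt = rng.exponential(1.0 / a0)
        if periodic and t + dt >= next_pulse:
            if next_pulse > t_max:
                return t_max, False, False
            t = next_pulse
            r = _pulse_size(kappa, I, ceil_round)
            S += r
            I -= r
            next_pulse += 1.0 / nu
        else:
            t += dt
            if t > t_max:
                return t_max, False, False
            u = rng.random() * a0
            if u < a_birth:
                S += 1
            elif u < a_birth + a_ds:
                S -= 1
            elif u < a_birth + a_ds + a_di:
                I -= 1
            elif u < a_birth + a_ds + a_di + a_inf:
                S -= 1
                I += 1
            elif u < a_birth + a_ds + a_di + a_inf + a_rec:
                S += 1
                I -= 1
            else:
                r = _pulse_size(kappa, I, ceil_round)
                S += r
                I -= r
        tbuf[head] = t
        sbuf[head] = S
        ibuf[head] = I
        head = (head + 1) % cap
        if count < cap:
            count += 1

    # accumulate occupancy of [t - window, t)
    t_end = t
    t_start = t_end - window
    if t_start < 0.0:
        t_start = 0.0
    ny = hist.shape[0]
    nx = hist.shape[1]
    dy = (y_hi - y_lo) / ny
    dx = (x_hi - x_lo) / nx
    oldest = (head - count) % cap
    truncated = count == cap and tbuf[oldest] > t_start
    for k in range(count):
        idx = (oldest + k) % cap
        t0 = tbuf[idx]
        t1 = tbuf[(idx + 1) % cap] if k < count - 1 else t_end
        lo = t0 if t0 > t_start else t_start
        hi = t1 if t1 < t_end else t_end
        w = hi - lo
        if w <= 0.0:
            continue
        yv = sbuf[idx] / N
        xv = ibuf[idx] / N
        iy = int((yv - y_lo) / dy)
        ix = int((xv - x_lo) / dx)
        if 0 <= iy < ny and 0 <= ix < nx:
            hist[iy, ix] += w
    return t_end, True, truncated
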