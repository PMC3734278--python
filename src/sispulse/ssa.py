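"""Exact stochastic simulation (Gillespie) of both SIS models.

Treatment pulses are either an ordinary constant-propensity channel (Poisson
schedule) or fire deterministically at times k/nu, k = 1, 2, ... (periodic
schedule; the first pulse comes one full period in, so both schedules have a
comparable mean first-pulse time).  Between pulses the demographic channels
evolve by the standard direct method; for the periodic schedule the
next-event clock is capped at the pulse time, which is statistically exact
because the exponential clock is memoryless.

RNG contract: an ensemble with master seed ``m`` gives realization ``i`` the
generator ``PCG64(SeedSequence(entropy=m, spawn_key=(i,)))``, so ensembles
are reproducible and independent of evaluation order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .models import ModelSpec, mean_field_endemic
from .params import round_pulse

__all__ = [
    "Trajectory",
    "ExtinctionEnsemble",
    "simulate_to_extinction",
    "extinction_ensemble",
    "prehistory_density",
    "prehistory_histogram",
    "default_initial_state",
    "realization_rng",
]


def realization_rng(master_seed: int, index: int = 0) -> np.random.Generator:
    """Child generator for realization ``index`` of ensemble ``master_seed``."""
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))))


@dataclass
class Trajectory:
    """One realization: event times, integer states, and pulse times."""

    times: np.ndarray
    states: np.ndarray          # (n,) infected counts or (n, 2) = (S, I)
    pulse_times: np.ndarray
    extinct: bool
    t_max: float
    model_kind: str

    @property
    def extinction_time(self) -> float:
        return float(self.times[-1]) if self.extinct else math.nan

    def infected(self) -> np.ndarray:
        return self.states if self.states.ndim == 1 else self.states[:, 1]


@dataclass
class ExtinctionEnsemble:
    """Extinction times of an ensemble; statistics over uncensored runs."""

    times: np.ndarray           # extinction time per realization (nan if censored)
    censored: np.ndarray        # bool per realization
    master_seed: int
    t_max: float

    @property
    def n_realizations(self) -> int:
        return self.times.size

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def uncensored_times(self) -> np.ndarray:
        return self.times[~self.censored]

    @property
    def mean(self) -> float:
        return float(self.uncensored_times.mean())

    @property
    def sd(self) -> float:
        return float(self.uncensored_times.std(ddof=1))

    @property
    def se(self) -> float:
        u = self.uncensored_times
        return float(u.std(ddof=1) / math.sqrt(u.size))


def default_initial_state(model: ModelSpec):
    """Integer-rounded endemic state (the standard simulation start)."""
    N = model.params.N_bar
    xe = mean_field_endemic(model.params, model.policy, model.kind)
    if model.kind == "constrained_1d":
        return max(1, int(round(N * xe[0])))
    S0 = int(round(N * xe[0]))
    I0 = max(1, int(round(N * xe[1])))
    return (S0, I0)


def _kernel_args(model: ModelSpec):
    p, pol = model.params, model.policy
    periodic = pol.is_active and pol.schedule == "periodic"
    ceil_round = pol.rounding == "ceil"
    return p, pol, periodic, ceil_round


def simulate_to_extinction(model: ModelSpec, initial_state, seed: int,
                           t_max: float = 1e4) -> Trajectory:
    """Full event-level Gillespie trajectory until extinction (or t_max).

    Records every state change and every realized pulse time.  Meant for
    inspection and testing; ensemble statistics use the fast kernels in
    :func:`extinction_ensemble`.
    """
    if not (t_max > 0 and math.isfinite(t_max)):
        raise ValueError(f"t_max must be positive and finite, got {t_max}")
    p, pol, periodic, ceil_round = _kernel_args(model)
    rng = realization_rng(seed, 0)
    N = p.N_bar
    have_pulses = pol.is_active
    poisson_tr = pol.nu if (have_pulses and not periodic) else 0.0
    next_pulse = 1.0 / pol.nu if (periodic and have_pulses) else math.inf

    one_d = model.kind == "constrained_1d"
    if one_d:
        I = int(initial_state)
        S = N - I
        if I < 0 or I > N:
            raise ValueError(f"initial infected count must lie in [0, {N}]")
    else:
        S, I = int(initial_state[0]), int(initial_state[1])
        if S < 0 or I < 0:
            raise ValueError("initial counts must be nonnegative")

    times, states, pulses = [0.0], [(S, I)], []
    t = 0.0
    extinct = I == 0
    while not extinct:
        if one_d:
            a = [p.beta * I * (N - I) / N, p.removal * I, poisson_tr]
        else:
            a = [p.mu * N, p.mu * S, p.mu * I, p.beta * S * I / (S + I),
                 p.gamma * I, poisson_tr]
        a0 = sum(a)
        dt = rng.exponential(1.0 / a0)
        if periodic and t + dt >= next_pulse:
            if next_pulse > t_max:
                t = t_max
                break
            t = next_pulse
            r = round_pulse(pol.kappa, I, pol.rounding)
            S += r
            I -= r
            pulses.append(t)
            next_pulse += 1.0 / pol.nu
        else:
            t += dt
            if t > t_max:
                t = t_max
                break
            u = rng.random() * a0
            c = 0
            acc = a[0]
            while u >= acc:
                c += 1
                acc += a[c]
            if one_d:
                if c == 0:
                    I += 1
                    S -= 1
                elif c == 1:
                    I -= 1
                    S += 1
                else:
                    r = round_pulse(pol.kappa, I, pol.rounding)
                    I -= r
                    S += r
                    pulses.append(t)
            else:
                if c == 0:
                    S += 1
                elif c == 1:
                    S -= 1
                elif c == 2:
                    I -= 1
                elif c == 3:
                    S -= 1
                    I += 1
                elif c == 4:
                    S += 1
                    I -= 1
                else:
                    r = round_pulse(pol.kappa, I, pol.rounding)
                    S += r
                    I -= r
                    pulses.append(t)
        times.append(t)
        states.append((S, I))
        extinct = I == 0

    times = np.array(times)
    st = np.array(states)
    if one_d:
        st = st[:, 1]
    return Trajectory(times=times, states=st, pulse_times=np.array(pulses),
                      extinct=extinct, t_max=t_max, model_kind=model.kind)


def extinction_ensemble(model: ModelSpec, initial_state=None, n_realizations: int = 2000,
                        seed: int = 0, t_max: float = 1e4) -> ExtinctionEnsemble:
    """Ensemble of extinction times from independent child streams.

    The default initial state is the integer-rounded endemic state.  Runs
    still alive at ``t_max`` are censored and excluded from the statistics;
    a warning is emitted when more than 1% of runs are censored.
    """
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    if initial_state is None:
        initial_state = default_initial_state(model)
    p, pol, periodic, ceil_round = _kernel_args(model)
    N = p.N_bar
    times = np.empty(n_realizations)
    cens = np.zeros(n_realizations, dtype=bool)
    if model.kind == "constrained_1d":
        I0 = int(initial_state)
        for i in range(n_realizations):
            rng = realization_rng(seed, i)
            t, ok = _kernels.m1_extinction_time(
                p.beta, p.removal, pol.kappa, pol.nu, periodic, ceil_round,
                N, I0, t_max, rng)
            times[i], cens[i] = t, not ok
    else:
        S0, I0 = int(initial_state[0]), int(initial_state[1])
        for i in range(n_realizations):
            rng = realization_rng(seed, i)
            t, ok = _kernels.m2_extinction_time(
                p.beta, p.gamma, p.mu, pol.kappa, pol.nu, periodic, ceil_round,
                N, S0, I0, t_max, rng)
            times[i], cens[i] = t, not ok
    times[cens] = np.nan
    ens = ExtinctionEnsemble(times=times, censored=cens, master_seed=seed, t_max=t_max)
    if ens.n_censored > 0.01 * n_realizations:
        warnings.warn(
            f"{ens.n_censored}/{n_realizations} realizations censored at "
            f"t_max = {t_max:g} years; the ensemble mean is biased low")
    return ens


def _hist_ranges(model: ModelSpec, y_range, x_range):
    xe = mean_field_endemic(model.params, model.policy, "full_2d")
    if x_range is None:
        x_range = (0.0, min(1.0, 2.0 * xe[1]))
    if y_range is None:
        y_range = (max(0.0, xe[0] - 0.5 * xe[1]), 1.0 + 2.0 / model.params.N_bar)
    return y_range, x_range


def prehistory_density(trajectories: Sequence[Trajectory], window: float = 5.0,
                       bins: int = 40, y_range=None, x_range=None, model: ModelSpec = None):
    """Extinction-prehistory density from recorded trajectories.

    Pools the time-weighted occupancy of the normalized (susceptible,
    infected) state over the final ``window`` years before each extinction
    and normalizes the 2-D histogram to total mass 1.  The default window of
    five years matches the usual presentation of extinction prehistories.

    Returns (hist, y_edges, x_edges): rows are susceptible-fraction bins,
    columns infected-fraction bins.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    if window <= 0:
        raise ValueError("window must be positive")
    for tr in trajectories:
        if not tr.extinct:
            raise ValueError("prehistory density needs extinct trajectories")
        if tr.model_kind != "full_2d":
            raise ValueError("prehistory density is defined for the full 2-D model")
    if model is None:
        raise ValueError("pass the model for normalization and default ranges")
    N = model.params.N_bar
    y_range, x_range = _hist_ranges(model, y_range, x_range)
    y_edges = np.linspace(*y_range, bins + 1)
    x_edges = np.linspace(*x_range, bins + 1)
    hist = np.zeros((bins, bins))
    for tr in trajectories:
        t_end = tr.times[-1]
        t_start = max(0.0, t_end - window)
        t0 = tr.times
        t1 = np.append(tr.times[1:], t_end)
        w = np.clip(np.minimum(t1, t_end), t_start, None) - np.clip(t0, t_start, None)
        keep = w > 0
        yv = tr.states[keep, 0] / N
        xv = tr.states[keep, 1] / N
        h, _, _ = np.histogram2d(yv, xv, bins=[y_edges, x_edges], weights=w[keep])
        hist += h
    hist /= hist.sum()
    return hist, y_edges, x_edges


def prehistory_histogram(model: ModelSpec, n_realizations: int, seed: int = 0,
                         window: float = 5.0, bins: int = 40, t_max: float = 1e6,
                         y_range=None, x_range=None, buffer_size: int = 1 << 16):
    """Monte-Carlo extinction-prehistory density without storing trajectories.

    Runs ``n_realizations`` full-model realizations from the endemic state,
    accumulating each one's final-window occupancy directly into the shared
    histogram (circular buffer per realization).  Returns
    (hist, y_edges, x_edges, ensemble) with the histogram normalized to 1.
    """
    if model.kind != "full_2d":
        raise ValueError("prehistory histogram is defined for the full 2-D model")
    p, pol, periodic, ceil_round = _kernel_args(model)
    N = p.N_bar
    S0, I0 = default_initial_state(model)
    y_range, x_range = _hist_ranges(model, y_range, x_range)
    hist = np.zeros((bins, bins))
    tbuf = np.empty(buffer_size)
    sbuf = np.empty(buffer_size, dtype=np.int64)
    ibuf = np.empty(buffer_size, dtype=np.int64)
    times = np.empty(n_realizations)
    cens = np.zeros(n_realizations, dtype=bool)
    n_trunc = 0
    for i in range(n_realizations):
        rng = realization_rng(seed, i)
        t, ok, trunc = _kernels.m2_prehistory(
            p.beta, p.gamma, p.mu, pol.kappa, pol.nu, periodic, ceil_round,
            N, S0, I0, t_max, window, rng,
            hist, y_range[0], y_range[1], x_range[0], x_range[1],
            tbuf, sbuf, ibuf)
        times[i], cens[i] = t, not ok
        n_trunc += int(trunc)
    if n_trunc:
        warnings.warn(f"{n_trunc} realizations overflowed the event buffer; "
                      "their windows were truncated (increase buffer_size)")
    times[cens] = np.nan
    total = hist.sum()
    if total <= 0:
        raise RuntimeError("no extinct realizations within t_max; histogram empty")
    hist /= total
    y_edges = np.linspace(*y_range, bins + 1)
    x_edges = np.linspace(*x_range, bins + 1)
    ens = ExtinctionEnsemble(times=times, censored=cens, master_seed=seed, t_max=t_max)
    return hist, y_edges, x_edges, ens
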