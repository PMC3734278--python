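"""Transition-channel definitions of the two stochastic SIS models.

Model 1 (``constrained_1d``) fixes S + I = N_bar and tracks only the infected
count I, with three channels: infection (+1), combined recovery/death (-1),
and the bulk treatment pulse.  Model 2 (``full_2d``) tracks (S, I) with six
channels: constant birth of susceptibles at rate mu*N_bar, per-capita deaths
of S and of I, frequency-dependent infection beta*S*I/(S+I), recovery, and
the bulk treatment pulse.

Raw rates act on integer counts; scaled rates are the intensive forms
w(x) = W(N*x)/N used by the WKB machinery, except the treatment propensity,
which is already intensive (a pulse arrives at rate nu regardless of N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .params import EpidemicParams, TreatmentPolicy, ReproductionNumbers, reproduction_numbers, round_pulse

__all__ = [
    "TransitionChannel",
    "ModelSpec",
    "make_constrained_model",
    "make_full_model",
    "mean_field_endemic",
    "NoEndemicStateError",
]


class NoEndemicStateError(ValueError):
    """Raised when an endemic state is requested but RT <= 1."""


@dataclass(frozen=True)
class TransitionChannel:
    """One reaction channel of a jump process over integer counts.

    ``increment`` is the state change per event; for the bulk treatment
    channel the realized increment depends on the current state (a pulse
    removes round(kappa*I) infecteds) and ``increment`` holds the direction
    only, with ``is_bulk`` set.
    """

    name: str
    increment: tuple
    rate_fn: Callable[..., float]
    scaled_rate_fn: Callable[..., float]
    is_bulk: bool = False


@dataclass(frozen=True)
class ModelSpec:
    """A stochastic SIS model: its channels, parameters, and policy."""

    kind: str  # "constrained_1d" | "full_2d"
    channels: tuple
    params: EpidemicParams
    policy: TreatmentPolicy

    @property
    def reproduction(self) -> ReproductionNumbers:
        return reproduction_numbers(self.params, self.policy)

    def propensities(self, state) -> np.ndarray:
        """Raw channel propensities at an integer state (I, or (S, I))."""
        if self.kind == "constrained_1d":
            return np.array([c.rate_fn(int(state)) for c in self.channels])
        s, i = int(state[0]), int(state[1])
        return np.array([c.rate_fn(s, i) for c in self.channels])


def _constrained_channels(params: EpidemicParams, policy: TreatmentPolicy):
    beta, rem, N = params.beta, params.removal, params.N_bar

    def infect(I: int) -> float:
        return beta * I * (N - I) / N if 0 < I < N else 0.0

    def down(I: int) -> float:
        return rem * I if I > 0 else 0.0

    chans = [
        TransitionChannel(
            "infection", (1,), infect,
            lambda x, beta=beta: beta * x * (1.0 - x),
        ),
        TransitionChannel(
            "recovery_death", (-1,), down,
            lambda x, rem=rem: rem * x,
        ),
    ]
    if policy.is_active:
        nu = policy.nu
        chans.append(TransitionChannel(
            "treatment", (-1,),
            lambda I, nu=nu: nu if I > 0 else 0.0,
            lambda x, nu=nu: nu,
            is_bulk=True,
        ))
    return tuple(chans)


def make_constrained_model(params: EpidemicParams, policy: TreatmentPolicy) -> ModelSpec:
    """Constrained (one-dimensional) SIS model with pulsed treatment.

    Channels: infection I -> I+1 at beta*I*(N-I)/N; combined recovery and
    death-with-compensating-birth I -> I-1 at (gamma+mu)*I; treatment
    I -> I - round(kappa*I) at constant propensity nu.  The treatment channel
    is dropped when kappa*nu = 0.
    """
    return ModelSpec("constrained_1d", _constrained_channels(params, policy), params, policy)


def _full_channels(params: EpidemicParams, policy: TreatmentPolicy):
    beta, gamma, mu, N = params.beta, params.gamma, params.mu, params.N_bar

    chans = [
        TransitionChannel(
            "birth", (1, 0),
            lambda S, I, mu=mu, N=N: mu * N,
            lambda y, x, mu=mu: mu,
        ),
        TransitionChannel(
            "death_S", (-1, 0),
            lambda S, I, mu=mu: mu * S if S > 0 else 0.0,
            lambda y, x, mu=mu: mu * y,
        ),
        TransitionChannel(
            "death_I", (0, -1),
            lambda S, I, mu=mu: mu * I if I > 0 else 0.0,
            lambda y, x, mu=mu: mu * x,
        ),
        TransitionChannel(
            "infection", (-1, 1),
            lambda S, I, beta=beta: beta * S * I / (S + I) if S > 0 and I > 0 else 0.0,
            lambda y, x, beta=beta: beta * y * x / (y + x) if y + x > 0 else 0.0,
        ),
        TransitionChannel(
            "recovery", (1, -1),
            lambda S, I, gamma=gamma: gamma * I if I > 0 else 0.0,
            lambda y, x, gamma=gamma: gamma * x,
        ),
    ]
    if policy.is_active:
        nu = policy.nu
        chans.append(TransitionChannel(
            "treatment", (1, -1),
            lambda S, I, nu=nu: nu if I > 0 else 0.0,
            lambda y, x, nu=nu: nu,
            is_bulk=True,
        ))
    return tuple(chans)


def make_full_model(params: EpidemicParams, policy: TreatmentPolicy) -> ModelSpec:
    """Full (two-dimensional) SIS model with pulsed treatment.

    Channels: birth S -> S+1 at constant mu*N_bar (keeps the mean population
    at N_bar with fluctuations); deaths S -> S-1 at mu*S and I -> I-1 at
    mu*I; frequency-dependent infection (S,I) -> (S-1,I+1) at
    beta*S*I/(S+I); recovery (S,I) -> (S+1,I-1) at gamma*I; treatment moves
    round(kappa*I) infecteds to S at constant propensity nu, conserving
    S + I.  Normalizing infection by the realized population (not N_bar)
    makes per-capita transmission insensitive to total-population dips, so
    the model reduces to the constrained one when fluctuations are small.
    """
    return ModelSpec("full_2d", _full_channels(params, policy), params, policy)


def pulse_size(model: ModelSpec, I: int) -> int:
    """Realized number of infecteds removed by a pulse at infected count I."""
    return round_pulse(model.policy.kappa, I, model.policy.rounding)


def mean_field_endemic(params: EpidemicParams, policy: TreatmentPolicy,
                       model_kind: str = "constrained_1d"):
    """Normalized mean-field endemic state (momenta are zero there).

    Constrained model: the positive root x* = 1 - 1/RT of
    beta*x*(1-x) - (gamma+mu)*x - kappa*nu*x = 0.  Full model: the point
    (s*, x*) = (1/RT, 1 - 1/RT).  Raises NoEndemicStateError when RT <= 1.
    """
    rt = reproduction_numbers(params, policy).RT
    if rt <= 1.0:
        raise NoEndemicStateError(
            f"no endemic state: RT = {rt:.6g} <= 1 (beta={params.beta}, "
            f"removal={params.removal}, dose rate={policy.dose_rate})")
    x_star = 1.0 - 1.0 / rt
    if model_kind == "constrained_1d":
        return np.array([x_star])
    if model_kind == "full_2d":
        return np.array([1.0 / rt, x_star])
    raise ValueError(f"unknown model kind {model_kind!r}")
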