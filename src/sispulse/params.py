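"""Epidemic parameters, treatment policies, and reproduction numbers.

Rates are per year throughout.  The SIS model has contact rate ``beta``,
recovery rate ``gamma`` and a common birth/death rate ``mu`` (births balance
deaths so the population is constant on average at ``N_bar``).  Treatment is
an instantaneous pulse that moves a fraction ``kappa`` of the infecteds back
to the susceptible class; pulses arrive either at Poisson-random times with
mean frequency ``nu`` per year, or strictly periodically at times k/nu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

__all__ = [
    "EpidemicParams",
    "TreatmentPolicy",
    "ReproductionNumbers",
    "reproduction_numbers",
    "round_pulse",
]

#: tolerance used when rounding kappa*I to an integer pulse size, so that
#: products that are exact in decimal (0.2 * 5 = 1) are not lost to binary
#: representation error
_ROUND_EPS = 1e-9


@dataclass(frozen=True)
class EpidemicParams:
    """Demographic and epidemic rates of the SIS model.

    Parameters
    ----------
    beta : float
        Contact (transmission) rate, 1/year.
    gamma : float
        Recovery rate, 1/year.
    mu : float
        Birth and death rate, 1/year.  Births balance deaths by construction.
    N_bar : int
        Mean population size (>= 2).
    """

    beta: float
    gamma: float
    mu: float
    N_bar: int

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")
        if not self.mu > 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if int(self.N_bar) != self.N_bar or self.N_bar < 2:
            raise ValueError(f"N_bar must be an integer >= 2, got {self.N_bar}")
        object.__setattr__(self, "N_bar", int(self.N_bar))

    @property
    def removal(self) -> float:
        """Total per-capita removal rate gamma + mu from the infected class."""
        return self.gamma + self.mu

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TreatmentPolicy:
    """Pulsed-treatment policy.

    Parameters
    ----------
    kappa : float
        Fraction of infecteds treated per pulse, in [0, 1].
    nu : float
        Pulse frequency, 1/year (>= 0).
    schedule : {"poisson", "periodic"}
        Poisson: exponential inter-pulse times with mean 1/nu.
        Periodic: pulses at fixed times k/nu, k = 1, 2, ...
    rounding : {"floor", "ceil"}
        How the non-integer pulse size kappa*I is mapped to a whole number of
        treated individuals.  "floor" keeps the integer part (so small pulses
        on few infecteds do nothing); "ceil" rounds up to the next integer.
    """

    kappa: float = 0.0
    nu: float = 0.0
    schedule: str = "poisson"
    rounding: str = "floor"

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")
        if self.nu < 0 or not math.isfinite(self.nu):
            raise ValueError(f"nu must be finite and >= 0, got {self.nu}")
        if self.schedule not in ("poisson", "periodic"):
            raise ValueError(f"schedule must be 'poisson' or 'periodic', got {self.schedule!r}")
        if self.rounding not in ("floor", "ceil"):
            raise ValueError(f"rounding must be 'floor' or 'ceil', got {self.rounding!r}")

    @property
    def is_active(self) -> bool:
        """Whether treatment has any effect at all (kappa*nu > 0)."""
        return self.kappa * self.nu > 0.0

    @property
    def dose_rate(self) -> float:
        """Mean per-capita treatment rate kappa*nu, 1/year."""
        return self.kappa * self.nu

    def to_dict(self) -> dict:
        return asdict(self)


def round_pulse(kappa: float, I: int, rounding: str = "floor") -> int:
    """Number of infecteds removed by one pulse at infected count ``I``.

    floor keeps the integer part of kappa*I; ceil rounds up.  A small epsilon
    guards against binary representation error in the product (0.2*5 must
    round to exactly 1 under floor, not 0).
    """
    if I <= 0:
        return 0
    x = kappa * I
    if rounding == "floor":
        r = int(math.floor(x + _ROUND_EPS))
    elif rounding == "ceil":
        r = int(math.ceil(x - _ROUND_EPS))
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return min(r, I)


@dataclass(frozen=True)
class ReproductionNumbers:
    """Basic (R0) and treated (RT) reproduction numbers."""

    R0: float
    RT: float


def reproduction_numbers(params: EpidemicParams, policy: TreatmentPolicy) -> ReproductionNumbers:
    """Reproduction numbers of the SIS model with pulsed treatment.

    R0 = beta/(gamma + mu).  With treatment, the mean per-capita removal rate
    gains the dose rate kappa*nu, giving RT = beta/(gamma + mu + kappa*nu);
    the mean-field endemic state exists iff RT > 1.
    """
    r0 = params.beta / params.removal
    rt = params.beta / (params.removal + policy.dose_rate)
    return ReproductionNumbers(R0=r0, RT=rt)
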