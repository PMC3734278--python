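"""Run configuration: parsing, validation, and serialization.

Configs are flat TOML (primary) or JSON files with the keys
{beta, gamma, mu, N, kappa, nu, schedule, rounding} plus run plumbing
(experiment, methods, out_dir, seed, scale, verbosity).  Unknown keys are
rejected; command-line flags override file values.  Rates are 1/year.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .models import make_constrained_model, make_full_model, ModelSpec
from .params import EpidemicParams, TreatmentPolicy

__all__ = ["RunConfig", "parse_config", "write_config"]

_SCALES = ("ci", "paper")


@dataclass
class RunConfig:
    """Validated parameters and plumbing for one run."""

    beta: float = 2.0
    gamma: float = 0.8
    mu: float = 0.2
    N: int = 500
    kappa: float = 0.0
    nu: float = 0.0
    schedule: str = "poisson"
    rounding: str = "floor"
    model: int = 1
    experiment: str = ""
    methods: list = field(default_factory=lambda: ["master_eq"])
    out_dir: str = "."
    seed: int = 0
    scale: str = "ci"
    verbosity: int = 1

    def __post_init__(self) -> None:
        # delegate range checks to the domain types
        self.params  # noqa: B018 - validation side effect
        self.policy
        if self.model not in (1, 2):
            raise ValueError(f"model must be 1 or 2, got {self.model}")
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")

    @property
    def params(self) -> EpidemicParams:
        return EpidemicParams(beta=self.beta, gamma=self.gamma, mu=self.mu,
                              N_bar=self.N)

    @property
    def policy(self) -> TreatmentPolicy:
        return TreatmentPolicy(kappa=self.kappa, nu=self.nu,
                               schedule=self.schedule, rounding=self.rounding)

    def make_model(self) -> ModelSpec:
        mk = make_constrained_model if self.model == 1 else make_full_model
        return mk(self.params, self.policy)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def parse_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional file plus flag overrides.

    Overrides (non-None keyword values) beat file values; field-level errors
    name the offending key.  Unknown keys in the file are rejected.
    """
    values: dict = {}
    if path is not None:
        p = Path(path)
        text = p.read_bytes()
        if p.suffix.lower() == ".json":
            loaded = json.loads(text)
        else:
            loaded = tomllib.loads(text.decode())
        unknown = set(loaded) - set(_FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    for k, v in overrides.items():
        if k not in _FIELDS:
            raise ValueError(f"unknown config field {k!r}")
        if v is not None:
            values[k] = v
    try:
        return RunConfig(**values)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def write_config(cfg: RunConfig, path) -> None:
    """Serialize a config (JSON; round-trips through parse_config)."""
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
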