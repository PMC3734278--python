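import numpy as np
import pytest

from sispulse import EpidemicParams, TreatmentPolicy, make_constrained_model, make_full_model


@pytest.fixture
def params_std():
    """The standard example rates: beta=2, gamma=0.8, mu=0.2 (R0 = 2)."""
    return EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=1000)


@pytest.fixture
def params_tiny():
    """Two-individual population, hand-solvable chain."""
    return EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=2)


@pytest.fixture
def policy_none():
    return TreatmentPolicy()


@pytest.fixture
def policy_mild():
    return TreatmentPolicy(kappa=0.05, nu=1.0)


def small_params(N=60, beta=2.0):
    return EpidemicParams(beta=beta, gamma=0.8, mu=0.2, N_bar=N)
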