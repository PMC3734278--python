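"""Statistical exactness and contracts of the Gillespie simulators."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from sispulse import (EpidemicParams, TreatmentPolicy, make_constrained_model,
                      make_full_model, simulate_to_extinction,
                      extinction_ensemble, prehistory_density,
                      prehistory_histogram, build_generator,
                      mean_extinction_time_direct)
from sispulse.ssa import default_initial_state, realization_rng


def test_fixed_seed_reproducibility(params_tiny):
    m = make_constrained_model(params_tiny, TreatmentPolicy())
    a = simulate_to_extinction(m, 2, seed=42)
    b = simulate_to_extinction(m, 2, seed=42)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.states, b.states)
    c = simulate_to_extinction(m, 2, seed=43)
    assert not np.array_equal(a.times, c.times)


def test_ensemble_reproducible_and_order_independent():
    p = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=20)
    m = make_constrained_model(p, TreatmentPolicy(kappa=0.1, nu=2.0))
    e1 = extinction_ensemble(m, n_realizations=50, seed=9)
    e2 = extinction_ensemble(m, n_realizations=50, seed=9)
    assert np.array_equal(e1.times, e2.times)
    # realization i depends only on (master seed, i), not on the batch
    e3 = extinction_ensemble(m, n_realizations=10, seed=9)
    assert np.array_equal(e1.times[:10], e3.times)


def test_single_death_process_mean():
    """With negligible infection and removal rate 1, extinction from I0=1 is
    ~Exponential(1): ensemble mean 1.0 within 3 SE."""
    p = EpidemicParams(beta=1e-9, gamma=0.8, mu=0.2, N_bar=100)
    m = make_constrained_model(p, TreatmentPolicy())
    ens = extinction_ensemble(m, initial_state=1, n_realizations=4000, seed=1)
    assert abs(ens.mean - 1.0) < 3 * ens.se
    assert abs(ens.sd - 1.0) < 0.1


def test_full_treatment_extinguishes_at_first_pulse():
    """kappa=1: the first pulse removes everyone still infected."""
    p = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=50)
    for sched in ("poisson", "periodic"):
        pol = TreatmentPolicy(kappa=1.0, nu=2.0, schedule=sched)
        m = make_constrained_model(p, pol)
        ens = extinction_ensemble(m, initial_state=25, n_realizations=400, seed=3)
        if sched == "periodic":
            assert np.nanmax(ens.times) <= 0.5 + 1e-12
        else:
            # E[min(Exp(nu), demographic)] <= 1/nu; allow sampling noise
            assert ens.mean <= 0.5 + 3 * ens.se
        # model 2 pulse conserves S + I
        m2 = make_full_model(p, pol)
        tr = simulate_to_extinction(m2, (25, 25), seed=4)
        assert (tr.states.sum(axis=1) >= 0).all()
        assert (tr.states >= 0).all()


def test_ensemble_mean_matches_exact_mfpt_tiny_chain(params_tiny):
    """Statistical exactness vs the 2-state linear solve."""
    m = make_constrained_model(params_tiny, TreatmentPolicy())
    ens = extinction_ensemble(m, initial_state=2, n_realizations=10_000, seed=5)
    assert abs(ens.mean - 2.0) < 3 * ens.se


def test_ensemble_mean_matches_exact_mfpt_treated():
    """Poisson-pulse ensemble vs the exact master-equation MFPT."""
    p = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=50)
    pol = TreatmentPolicy(kappa=0.15, nu=2.0)
    m = make_constrained_model(p, pol)
    tau = mean_extinction_time_direct(build_generator(m), default_initial_state(m))
    ens = extinction_ensemble(m, n_realizations=3000, seed=6, t_max=1e6)
    assert abs(ens.mean - tau) < 3 * ens.se


def test_full_model_pulses_conserve_population():
    p = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=40)
    pol = TreatmentPolicy(kappa=0.3, nu=6.0)
    m = make_full_model(p, pol)
    tr = simulate_to_extinction(m, (28, 12), seed=7, t_max=100.0)
    assert (tr.states >= 0).all()
    # at every recorded pulse, S+I just before equals S+I just after
    for tp in tr.pulse_times:
        k = np.searchsorted(tr.times, tp)
        assert tr.states[k - 1].sum() == tr.states[k].sum()


def test_periodic_pulse_times_exact():
    p = EpidemicParams(beta=20.0, gamma=0.8, mu=0.2, N_bar=10)
    pol = TreatmentPolicy(kappa=0.01, nu=3.0, schedule="periodic")
    m = make_constrained_model(p, pol)
    tr = simulate_to_extinction(m, 5, seed=8, t_max=50.0)
    k = np.arange(1, len(tr.pulse_times) + 1)
    assert np.allclose(tr.pulse_times, k / 3.0, rtol=0, atol=1e-9)


def test_poisson_interpulse_times_exponential():
    """KS test of inter-pulse gaps against Exponential(nu) at alpha = 0.01."""
    p = EpidemicParams(beta=20.0, gamma=0.8, mu=0.2, N_bar=10)
    pol = TreatmentPolicy(kappa=0.01, nu=10.0)  # pulses are no-ops at this size
    m = make_constrained_model(p, pol)
    tr = simulate_to_extinction(m, 8, seed=9, t_max=1001.0)
    assert not tr.extinct  # long quasi-stationary run
    gaps = np.diff(np.concatenate([[0.0], tr.pulse_times]))
    assert len(gaps) >= 9000
    ks = stats.kstest(gaps, "expon", args=(0, 1 / 10.0))
    assert ks.pvalue > 0.01


def test_censoring_reported_not_fatal():
    p = EpidemicParams(beta=4.0, gamma=0.8, mu=0.2, N_bar=200)
    m = make_constrained_model(p, TreatmentPolicy())
    with pytest.warns(UserWarning, match="censored"):
        ens = extinction_ensemble(m, n_realizations=50, seed=10, t_max=1.0)
    assert ens.n_censored > 0
    assert np.isnan(ens.times[ens.censored]).all()


def test_prehistory_density_contract():
    p = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=40)
    m = make_full_model(p, TreatmentPolicy())
    trajs = [simulate_to_extinction(m, (20, 20), seed=s, t_max=1e6)
             for s in range(30)]
    trajs = [t for t in trajs if t.extinct]
    hist, ye, xe = prehistory_density(trajs, window=5.0, bins=20, model=m)
    assert hist.sum() == pytest.approx(1.0, abs=1e-12)
    assert hist.min() >= 0
    # occupancy concentrates toward x -> 0 (the absorbing approach)
    col = hist.sum(axis=0)
    assert col[:5].sum() > col[-5:].sum()
    with pytest.raises(ValueError):
        prehistory_density([], model=m)


def test_prehistory_fast_histogram_matches_trajectory_route():
    """The streaming kernel and the trajectory-based histogram agree."""
    p = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=40)
    m = make_full_model(p, TreatmentPolicy())
    hist, ye, xe, ens = prehistory_histogram(m, n_realizations=40, seed=0,
                                             window=5.0, bins=15, t_max=1e6)
    assert hist.sum() == pytest.approx(1.0, abs=1e-12)
    trajs = [simulate_to_extinction(m, default_initial_state(m), seed=0, t_max=1e6)]
    # same seed & realization index -> identical extinction time
    assert trajs[0].extinction_time == pytest.approx(float(ens.times[0]), abs=1e-9)
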