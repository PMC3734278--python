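"""Hamiltonian machinery: fixed points, optimal paths, actions, prefactor."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from sispulse import (EpidemicParams, TreatmentPolicy, make_constrained_model,
                      make_full_model, mean_field_endemic,
                      hamiltonian, characteristic_field, fixed_points,
                      optimal_path, action_numeric, action_branch_quadrature,
                      action_asymptotic, prefactor, mte_wkb,
                      quasistationarity_map, build_generator,
                      mean_extinction_time_direct)
from sispulse.ssa import default_initial_state
from sispulse.wkb import die_out_momentum


def _models(params, policy):
    return make_constrained_model(params, policy), make_full_model(params, policy)


def test_hamiltonian_vanishes_on_deterministic_manifold(params_std):
    """H(x, 0) = 0 identically: momentum zero is the mean-field manifold."""
    rng = np.random.default_rng(0)
    pol = TreatmentPolicy(kappa=0.2, nu=3.0)
    m1, m2 = _models(params_std, pol)
    x = rng.uniform(0.01, 0.99, (50, 1))
    assert np.abs(hamiltonian(m1, x, np.zeros_like(x))).max() < 1e-14
    st2 = rng.uniform(0.05, 0.9, (50, 2))
    assert np.abs(hamiltonian(m2, st2, np.zeros_like(st2))).max() < 1e-14


def test_untreated_zero_energy_branch(params_std):
    """For kappa=0 the nontrivial branch is e^p = (gamma+mu)/(beta(1-x))."""
    m1 = make_constrained_model(params_std, TreatmentPolicy())
    x = np.linspace(0.05, 0.45, 9)[:, None]
    p = np.log(1.0 / (2.0 * (1.0 - x)))
    assert np.abs(hamiltonian(m1, x, p)).max() < 1e-12


def test_fixed_points_satisfy_definitions(params_std):
    pol = TreatmentPolicy(kappa=0.1, nu=4.0)
    for m in _models(params_std, pol):
        fps = fixed_points(m)
        for pp in (fps.disease_free, fps.endemic, fps.die_out):
            h = hamiltonian(m, pp.state, pp.momentum)
            assert abs(float(h)) < 1e-10
            sd, md = characteristic_field(m, pp.state, pp.momentum)
            assert np.abs(sd).max() < 1e-10
            assert np.abs(md).max() < 1e-10
        assert fps.die_out.state[-1] == 0.0
        assert fps.die_out.momentum[-1] != 0.0
        assert np.all(fps.endemic.momentum == 0.0)


def test_die_out_momentum_closed_form_and_oracle(params_std):
    """p_f = -ln R0 untreated; treated value vs an independent bisection."""
    m0 = make_constrained_model(params_std, TreatmentPolicy())
    assert die_out_momentum(m0) == pytest.approx(-math.log(2.0), abs=1e-12)

    pol = TreatmentPolicy(kappa=0.1, nu=4.0)
    m = make_constrained_model(params_std, pol)
    # independent oracle: bisection on the x->0 branch equation
    f = lambda p: 2.0 * math.expm1(p) + 1.0 * math.expm1(-p) - 4.0 * 0.1 * p
    oracle = brentq(f, -0.6931, -1e-6, xtol=1e-12)
    pf = die_out_momentum(m)
    assert pf == pytest.approx(oracle, abs=1e-10)
    assert pf == pytest.approx(-0.413222, abs=1e-5)


def test_treatment_shrinks_die_out_momentum(params_std):
    """|p_f| decreases with treatment intensity (grid check)."""
    prev = math.log(2.0)
    for dose in (0.1, 0.3, 0.6):
        m = make_constrained_model(params_std, TreatmentPolicy(kappa=0.1, nu=dose / 0.1))
        cur = abs(die_out_momentum(m))
        assert cur < prev
        prev = cur


def test_characteristic_field_matches_numeric_gradient(params_std):
    """Analytic Hamilton equations vs central finite differences of H."""
    rng = np.random.default_rng(1)
    pol = TreatmentPolicy(kappa=0.15, nu=2.0)
    eps = 1e-6
    for m, d in zip(_models(params_std, pol), (1, 2)):
        for _ in range(20):
            s = rng.uniform(0.1, 0.8, d)
            p = rng.uniform(-0.5, 0.3, d)
            sd, md = characteristic_field(m, s, p)
            for k in range(d):
                dp = np.zeros(d); dp[k] = eps
                num = (hamiltonian(m, s, p + dp) - hamiltonian(m, s, p - dp)) / (2 * eps)
                assert float(sd[k]) == pytest.approx(float(num), rel=1e-5, abs=1e-7)
                ds = np.zeros(d); ds[k] = eps
                num = -(hamiltonian(m, s + ds, p) - hamiltonian(m, s - ds, p)) / (2 * eps)
                assert float(md[k]) == pytest.approx(float(num), rel=1e-5, abs=1e-7)


def test_zero_momentum_flow_is_mean_field(params_std):
    """At p = 0 the state equation is the deterministic SIS ODE."""
    rng = np.random.default_rng(2)
    pol = TreatmentPolicy(kappa=0.2, nu=2.0)
    m1, m2 = _models(params_std, pol)
    for _ in range(100):
        x = rng.uniform(0.01, 0.99)
        sd, _ = characteristic_field(m1, [x], [0.0])
        expect = 2.0 * x * (1 - x) - 1.0 * x - 0.4 * x
        assert float(sd[0]) == pytest.approx(expect, abs=1e-12)
    for _ in range(20):
        y, x = rng.uniform(0.05, 0.7, 2)
        sd, _ = characteristic_field(m2, [y, x], [0.0, 0.0])
        dx = 2.0 * y * x / (y + x) - 1.0 * x - 0.4 * x
        assert float(sd[1]) == pytest.approx(dx, abs=1e-12)


def test_energy_conserved_along_characteristics(params_std):
    """H stays constant along numerically integrated characteristics."""
    pol = TreatmentPolicy(kappa=0.1, nu=4.0)
    m = make_constrained_model(params_std, pol)
    z0 = [0.2, -0.3]

    def rhs(t, z):
        sd, md = characteristic_field(m, z[:1], z[1:])
        return [float(sd[0]), float(md[0])]

    sol = solve_ivp(rhs, (0, 2.0), z0, rtol=1e-10, atol=1e-12, dense_output=True)
    h0 = float(hamiltonian(m, z0[:1], z0[1:]))
    hs = [float(hamiltonian(m, sol.y[:1, k], sol.y[1:, k])) for k in range(sol.y.shape[1])]
    assert max(abs(h - h0) for h in hs) < 1e-8


def test_path_momenta_match_closed_branch(params_std):
    """Untreated converged path lies on the known p(x) branch."""
    m = make_constrained_model(params_std, TreatmentPolicy())
    path = optimal_path(m, n_nodes=4001)
    x = path.states[400:-400, 0]
    p = path.momenta[400:-400, 0]
    expect = np.log(1.0 / (2.0 * (1.0 - x)))
    assert np.abs(p - expect).max() < 1e-6
    assert path.max_abs_H <= 1e-6
    assert path.residual <= 1e-8


@pytest.mark.parametrize("r0,expected", [(2.0, math.log(2) - 0.5), (4.0, math.log(4) - 0.75)])
def test_untreated_action_closed_form(r0, expected):
    p = EpidemicParams(beta=r0, gamma=0.8, mu=0.2, N_bar=1000)
    m = make_constrained_model(p, TreatmentPolicy())
    assert optimal_path(m).action == pytest.approx(expected, abs=1e-5)
    assert action_branch_quadrature(m) == pytest.approx(expected, abs=1e-9)


def test_action_mesh_convergence_is_second_order(params_std):
    """Halving the mesh step shrinks the action error by ~4 (order >= 1.9)."""
    m = make_constrained_model(params_std, TreatmentPolicy(kappa=0.1, nu=2.0))
    exact = action_branch_quadrature(m)
    errs = []
    for n in (201, 401, 801):
        errs.append(abs(optimal_path(m, n_nodes=n, t_half=25.0).action - exact))
    order1 = math.log2(errs[0] / errs[1])
    order2 = math.log2(errs[1] / errs[2])
    assert order1 >= 1.9
    assert order2 >= 1.9


def test_newton_path_agrees_with_branch_quadrature(params_std):
    """Two independent routes to the treated Model 1 action."""
    m = make_constrained_model(params_std, TreatmentPolicy(kappa=0.1, nu=4.0))
    assert optimal_path(m).action == pytest.approx(action_branch_quadrature(m), abs=1e-6)


def test_action_monotone_in_treatment(params_std):
    """Action decreases with kappa and with nu (stronger treatment, cheaper escape)."""
    vals_k = [action_branch_quadrature(
        make_constrained_model(params_std, TreatmentPolicy(kappa=k, nu=2.0)))
        for k in (0.02, 0.05, 0.1, 0.2)]
    assert all(a > b for a, b in zip(vals_k, vals_k[1:]))
    vals_n = [action_branch_quadrature(
        make_constrained_model(params_std, TreatmentPolicy(kappa=0.1, nu=n)))
        for n in (0.5, 1.0, 2.0, 4.0)]
    assert all(a > b for a, b in zip(vals_n, vals_n[1:]))


def test_asymptotic_action(params_std):
    """kappa=0 gives s0 exactly; the linear term matches a finite difference."""
    pol = TreatmentPolicy(kappa=0.0, nu=1.0)
    s, s0, s1, ok = action_asymptotic(params_std, pol)
    assert s == s0 == pytest.approx(math.log(2) - 0.5, abs=1e-12)
    assert ok

    pol = TreatmentPolicy(kappa=1e-4, nu=1.0)
    _, s0, s1, _ = action_asymptotic(params_std, pol)
    num = action_branch_quadrature(make_constrained_model(params_std, pol))
    fd_slope = (num - s0) / 1e-4
    assert fd_slope == pytest.approx(s1, rel=0.02)
    # truncation error grows with kappa
    errs = []
    for k in (0.05, 0.1, 0.2):
        pol = TreatmentPolicy(kappa=k, nu=1.0)
        sa, *_ = action_asymptotic(params_std, pol)
        sn = action_branch_quadrature(make_constrained_model(params_std, pol))
        errs.append(abs(sa - sn))
    assert errs[0] < errs[1] < errs[2]


def test_prefactor_modes(params_std):
    pol = TreatmentPolicy(kappa=0.05, nu=1.0)
    assert prefactor(params_std, pol, "unity") == 1.0
    # calibrated mode reproduces the reference at its own point
    s = 0.17
    B = prefactor(params_std, pol, "calibrated_constant", mte_ref=1e5, s=s)
    assert B * math.exp(params_std.N_bar * s) == pytest.approx(1e5)
    # analytic mode positive and finite over a parameter box
    for beta in (1.5, 2.0, 3.0):
        for k in (0.0, 0.05, 0.1):
            p = EpidemicParams(beta=beta, gamma=0.8, mu=0.2, N_bar=2000)
            b = prefactor(p, TreatmentPolicy(kappa=k, nu=2.0), "analytic")
            assert 0 < b < math.inf


def test_analytic_prefactor_against_exact_mfpt():
    """B*exp(N*s) tracks the exact untreated MFPT to O(1/N) accuracy."""
    for r0, N in ((2.0, 200), (4.0, 100), (1.5, 400)):
        p = EpidemicParams(beta=r0, gamma=0.8, mu=0.2, N_bar=N)
        pol = TreatmentPolicy()
        m = make_constrained_model(p, pol)
        tau = mean_extinction_time_direct(build_generator(m),
                                          int(round(N * (1 - 1 / r0))))
        s = math.log(r0) - 1 + 1 / r0
        pred = prefactor(p, pol, "analytic") * math.exp(N * s)
        assert tau / pred == pytest.approx(1.0, abs=0.08)


def test_calibrated_prefactor_cross_N():
    """B calibrated at N=150 predicts ln MTE at N=250 within 5% (untreated)."""
    r0 = 2.0
    s = math.log(r0) - 0.5
    taus = {}
    for N in (150, 250):
        p = EpidemicParams(beta=r0, gamma=0.8, mu=0.2, N_bar=N)
        m = make_constrained_model(p, TreatmentPolicy())
        taus[N] = mean_extinction_time_direct(build_generator(m),
                                              default_initial_state(m))
    B = taus[150] * math.exp(-150 * s)
    assert math.log(B * math.exp(250 * s)) == pytest.approx(math.log(taus[250]), rel=0.05)


def test_mte_wkb_contract():
    est = mte_wkb(0.0, 2.5, 1000)
    assert est.mte == pytest.approx(2.5)
    a = mte_wkb(0.1, 1.0, 500)
    b = mte_wkb(0.1, 1.0, 1000)
    assert b.log_mte == pytest.approx(2 * a.log_mte, rel=1e-12)
    big = mte_wkb(1.0, 1.0, 10_000)
    assert big.overflowed and big.mte == math.inf and big.log_mte == pytest.approx(10_000)
    with pytest.raises(ValueError):
        mte_wkb(-0.1, 1.0, 100)


def test_model2_action_close_to_model1_and_below(params_std):
    """The full model's action is slightly below the constrained model's,
    and both decrease with kappa, converging as treatment dominates."""
    gaps = []
    for k in (0.0, 0.1, 0.2):
        pol = TreatmentPolicy(kappa=k, nu=2.0) if k else TreatmentPolicy()
        s1 = action_branch_quadrature(make_constrained_model(params_std, pol))
        s2 = optimal_path(make_full_model(params_std, pol)).action
        assert 0 < s2 < s1
        gaps.append(s1 - s2)
    assert gaps[0] > gaps[1] > gaps[2]


def test_quasistationarity_map_geometry():
    """N*s -> 0 at the RT=1 boundary; threshold contour inside RT > 1 and
    moving toward the boundary as N doubles."""
    pol = TreatmentPolicy(kappa=0.0, nu=4.0)
    kg = np.linspace(0.0, 0.3, 7)
    bg = np.linspace(1.4, 2.6, 4)
    p1 = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=2000)
    res = quasistationarity_map(p1, pol, kg, bg, threshold=10.0, n_nodes=401)
    Ns, RT = res["Ns"], res["RT"]
    for i in range(bg.size):
        row, rt = Ns[i], RT[i]
        ok = np.isfinite(row)
        # N*s decreases toward the RT=1 contour (kappa increasing)
        assert all(a > b for a, b in zip(row[ok], row[ok][1:]))
        # cells just inside the boundary have small N*s
        if ok.any() and (~ok).any():
            assert row[ok][-1] < 0.25 * row[ok][0]
        # threshold contour lies strictly inside RT > 1
        if np.isfinite(res["qs_contour"][i]):
            assert res["qs_contour"][i] < res["rt1_curve"][i]
    p2 = EpidemicParams(beta=2.0, gamma=0.8, mu=0.2, N_bar=4000)
    res2 = quasistationarity_map(p2, pol, kg, bg, threshold=10.0, n_nodes=401)
    both = np.isfinite(res["qs_contour"]) & np.isfinite(res2["qs_contour"])
    # doubling N moves the N*s = threshold contour toward RT = 1 (larger kappa)
    assert (res2["qs_contour"][both] >= res["qs_contour"][both]).all()
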