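"""WKB (eikonal) machinery for the mean time to extinction.

Writing the quasi-stationary distribution as P(x) ~ exp(-N*s(x)) turns the
master equation into a stationary Hamilton-Jacobi problem H(x, ds/dx) = 0.
The Hamiltonian is assembled from the scaled channel rates w(x) as

    H(x, p) = sum_r w_r(x) * (exp(p . dx_r) - 1),

where dx_r is the normalized jump of channel r.  The treatment pulse is a
bulk jump of -kappa*x (Model 1) or kappa*x from I to S (Model 2) at constant
propensity nu, so it contributes nu*(exp(-kappa*x*p) - 1), resp.
nu*(exp(kappa*x*(p_s - p_x)) - 1); in this continuous description the pulse
acts at arbitrarily small x (no rounding).

The most probable route to extinction is the zero-energy heteroclinic
trajectory of the characteristic system (x' = dH/dp, p' = -dH/dx) from the
endemic fixed point (momentum zero) to the fluctuational die-out point
(x = 0, momentum p_f < 0).  Its action s = int p dx sets the exponential
scale of the mean extinction time, MTE ~ B * exp(N*s).

Sign convention: extinction paths carry negative momentum and positive
action.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import integrate, optimize, sparse
from scipy.sparse.linalg import spsolve

from .models import ModelSpec, mean_field_endemic, NoEndemicStateError
from .params import EpidemicParams, TreatmentPolicy, reproduction_numbers

__all__ = [
    "PhasePoint",
    "FixedPointSet",
    "OptimalPath",
    "MTEEstimate",
    "hamiltonian",
    "characteristic_field",
    "fixed_points",
    "optimal_path",
    "action_numeric",
    "action_branch_quadrature",
    "action_asymptotic",
    "prefactor",
    "mte_wkb",
    "quasistationarity_map",
    "PathConvergenceError",
]


class PathConvergenceError(RuntimeError):
    """Newton iteration for the optimal path failed to converge."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []


@dataclass(frozen=True)
class PhasePoint:
    """A point (state, momentum) of the Hamiltonian phase space."""

    state: np.ndarray
    momentum: np.ndarray


@dataclass(frozen=True)
class FixedPointSet:
    """Zero-energy fixed points: disease-free, endemic, fluctuational die-out."""

    disease_free: PhasePoint
    endemic: Optional[PhasePoint]
    die_out: PhasePoint


@dataclass
class OptimalPath:
    """Discretized heteroclinic extinction path with diagnostics."""

    t: np.ndarray           # mesh times, years
    states: np.ndarray      # (M, d) normalized states
    momenta: np.ndarray     # (M, d) conjugate momenta
    action: float           # per-capita action s = int p dx
    max_abs_H: float        # max |H| over nodes
    residual: float         # final Newton residual (inf norm)
    n_iter: int
    converged: bool
    model: ModelSpec = field(repr=False, default=None)


@dataclass(frozen=True)
class MTEEstimate:
    """Mean time to extinction as B * exp(N*s)."""

    s: float
    B: float
    N_bar: int
    log_mte: float
    mte: float              # inf when exp(N*s) overflows; use log_mte
    overflowed: bool
    method: str = "wkb_numeric"


def _policy_terms(model: ModelSpec):
    pol = model.policy
    if pol.is_active:
        return pol.kappa, pol.nu
    return 0.0, 0.0


# ----------------------------------------------------------------------
# Hamiltonians, characteristic fields, and their Jacobians
# ----------------------------------------------------------------------

def _h1(model, x, p):
    beta, rem = model.params.beta, model.params.removal
    ka, nu = _policy_terms(model)
    h = beta * x * (1.0 - x) * (np.exp(p) - 1.0) + rem * x * (np.exp(-p) - 1.0)
    if nu > 0.0:
        h = h + nu * (np.exp(-ka * x * p) - 1.0)
    return h


def _f1(model, x, p):
    """Characteristic field (dH/dp, -dH/dx) of Model 1."""
    beta, rem = model.params.beta, model.params.removal
    ka, nu = _policy_terms(model)
    A, B = np.exp(p), np.exp(-p)
    C = np.exp(-ka * x * p) if nu > 0.0 else 0.0
    h_p = beta * x * (1.0 - x) * A - rem * x * B - nu * ka * x * C
    h_x = beta * (1.0 - 2.0 * x) * (A - 1.0) + rem * (B - 1.0) - nu * ka * p * C
    return h_p, -h_x


def _j1(model, x, p):
    """Jacobian of the Model 1 characteristic field, as 2x2 blocks."""
    beta, rem = model.params.beta, model.params.removal
    ka, nu = _policy_terms(model)
    A, B = np.exp(p), np.exp(-p)
    C = np.exp(-ka * x * p) if nu > 0.0 else 0.0
    h_xx = -2.0 * beta * (A - 1.0) + nu * ka**2 * p**2 * C
    h_xp = beta * (1.0 - 2.0 * x) * A - rem * B - nu * ka * C + nu * ka**2 * x * p * C
    h_pp = beta * x * (1.0 - x) * A + rem * x * B + nu * ka**2 * x**2 * C
    # rows: d(xdot)/d(x,p); d(pdot)/d(x,p)
    return h_xp, h_pp, -h_xx, -h_xp


def _exp2(model, y, x, ps, px):
    ka, nu = _policy_terms(model)
    E1, E2 = np.exp(ps), np.exp(-ps)
    E3 = np.exp(-px)
    E4, E5 = np.exp(px - ps), np.exp(ps - px)
    E6 = np.exp(ka * x * (ps - px)) if nu > 0.0 else 0.0
    return E1, E2, E3, E4, E5, E6


def _h2(model, y, x, ps, px):
    beta, gamma, mu = model.params.beta, model.params.gamma, model.params.mu
    ka, nu = _policy_terms(model)
    E1, E2, E3, E4, E5, E6 = _exp2(model, y, x, ps, px)
    w = beta * y * x / (y + x)  # frequency-dependent infection
    h = (mu * (E1 - 1.0) + mu * y * (E2 - 1.0) + mu * x * (E3 - 1.0)
         + w * (E4 - 1.0) + gamma * x * (E5 - 1.0))
    if nu > 0.0:
        h = h + nu * (E6 - 1.0)
    return h


def _w2(model, y, x):
    """Scaled infection rate w = beta*y*x/(y+x) and its partials."""
    beta = model.params.beta
    n = y + x
    w = beta * y * x / n
    w_y = beta * x**2 / n**2
    w_x = beta * y**2 / n**2
    w_yy = -2.0 * beta * x**2 / n**3
    w_xy = 2.0 * beta * x * y / n**3
    w_xx = -2.0 * beta * y**2 / n**3
    return w, w_y, w_x, w_yy, w_xy, w_xx


def _f2(model, y, x, ps, px):
    """Characteristic field (ydot, xdot, psdot, pxdot) of Model 2."""
    gamma, mu = model.params.gamma, model.params.mu
    ka, nu = _policy_terms(model)
    E1, E2, E3, E4, E5, E6 = _exp2(model, y, x, ps, px)
    w, w_y, w_x, *_ = _w2(model, y, x)
    h_ps = mu * E1 - mu * y * E2 - w * E4 + gamma * x * E5 + nu * ka * x * E6
    h_px = -mu * x * E3 + w * E4 - gamma * x * E5 - nu * ka * x * E6
    h_y = mu * (E2 - 1.0) + w_y * (E4 - 1.0)
    h_x = (mu * (E3 - 1.0) + w_x * (E4 - 1.0) + gamma * (E5 - 1.0)
           + nu * ka * (ps - px) * E6)
    return h_ps, h_px, -h_y, -h_x


def _j2(model, y, x, ps, px):
    """Jacobian blocks of the Model 2 characteristic field.

    Returns a (4, 4) nested list: J[i][j] = dF_i/dz_j with
    z = (y, x, ps, px) and F = (H_ps, H_px, -H_y, -H_x).
    """
    gamma, mu = model.params.gamma, model.params.mu
    ka, nu = _policy_terms(model)
    E1, E2, E3, E4, E5, E6 = _exp2(model, y, x, ps, px)
    w, w_y, w_x, w_yy, w_xy, w_xx = _w2(model, y, x)
    d = ps - px

    h_ps_y = -mu * E2 - w_y * E4
    h_ps_x = -w_x * E4 + gamma * E5 + nu * ka * E6 + nu * ka**2 * x * d * E6
    h_ps_ps = mu * E1 + mu * y * E2 + w * E4 + gamma * x * E5 + nu * ka**2 * x**2 * E6
    h_ps_px = -w * E4 - gamma * x * E5 - nu * ka**2 * x**2 * E6

    h_px_y = w_y * E4
    h_px_x = -mu * E3 + w_x * E4 - gamma * E5 - nu * ka * E6 - nu * ka**2 * x * d * E6
    h_px_px = mu * x * E3 + w * E4 + gamma * x * E5 + nu * ka**2 * x**2 * E6

    h_y_y = w_yy * (E4 - 1.0)
    h_y_x = w_xy * (E4 - 1.0)
    h_x_x = w_xx * (E4 - 1.0) + nu * ka**2 * d**2 * E6

    return [
        [h_ps_y, h_ps_x, h_ps_ps, h_ps_px],
        [h_px_y, h_px_x, h_ps_px, h_px_px],
        [-h_y_y, -h_y_x, -h_ps_y, -h_px_y],
        [-h_y_x, -h_x_x, -h_ps_x, -h_px_x],
    ]


def _split(model, state, momentum):
    state = np.asarray(state, dtype=float)
    momentum = np.asarray(momentum, dtype=float)
    if model.kind == "constrained_1d":
        return (state[..., 0], momentum[..., 0])
    return (state[..., 0], state[..., 1], momentum[..., 0], momentum[..., 1])


def hamiltonian(model: ModelSpec, state, momentum):
    """Evaluate H(state, momentum); vanishes identically on momentum = 0.

    ``state`` and ``momentum`` have a trailing axis of length 1 (Model 1:
    x) or 2 (Model 2: susceptible fraction, infected fraction); leading axes
    broadcast.
    """
    if model.kind == "constrained_1d":
        x, p = _split(model, state, momentum)
        return _h1(model, x, p)
    y, x, ps, px = _split(model, state, momentum)
    return _h2(model, y, x, ps, px)


def characteristic_field(model: ModelSpec, state, momentum):
    """Hamilton's equations: returns (d state/dt, d momentum/dt).

    At momentum = 0 the state equation reduces to the mean-field ODE.
    Derivatives are analytic (no numerical differentiation).
    """
    if model.kind == "constrained_1d":
        x, p = _split(model, state, momentum)
        xd, pd = _f1(model, x, p)
        return np.stack([xd], axis=-1), np.stack([pd], axis=-1)
    y, x, ps, px = _split(model, state, momentum)
    yd, xd, psd, pxd = _f2(model, y, x, ps, px)
    return np.stack([yd, xd], axis=-1), np.stack([psd, pxd], axis=-1)


def _field_jacobian_matrix(model: ModelSpec, z):
    """Dense Jacobian of the phase-space field at a single point z=(state,mom)."""
    if model.kind == "constrained_1d":
        a, b, c, d = _j1(model, z[0], z[1])
        return np.array([[a, b], [c, d]], dtype=float)
    blocks = _j2(model, z[0], z[1], z[2], z[3])
    return np.array([[float(np.asarray(blocks[i][j])) for j in range(4)]
                     for i in range(4)], dtype=float)


# ----------------------------------------------------------------------
# Fixed points
# ----------------------------------------------------------------------

def die_out_momentum(model: ModelSpec) -> float:
    """Momentum p_f < 0 of the fluctuational die-out point.

    Root of the x -> 0 limit of the nontrivial zero-energy branch,

        beta*(e^p - 1) + (gamma+mu)*(e^-p - 1) - nu*kappa*p = 0,

    which closes to p_f = -ln R0 when kappa*nu = 0.  With treatment the
    equation is transcendental; the root is found by a bracketed scan of
    [p_f(kappa=0) - 1, 0) and the root closest to -ln R0 is kept
    (continuity in kappa).
    """
    beta, rem = model.params.beta, model.params.removal
    ka, nu = _policy_terms(model)
    r0 = beta / rem
    pf0 = -math.log(r0)
    if nu == 0.0 or ka == 0.0:
        return pf0

    def g(p):
        return beta * np.expm1(p) + rem * np.expm1(-p) - nu * ka * p

    lo, hi = pf0 - 1.0, -1e-12
    grid = np.linspace(lo, hi, 2001)
    vals = g(grid)
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0.0:
            roots.append(optimize.brentq(g, grid[i], grid[i + 1], xtol=1e-14, rtol=1e-15))
    if not roots:
        raise RuntimeError(
            f"die-out momentum root not bracketed in [{lo:.4f}, {hi:.4g}]; "
            f"scanned g range [{vals.min():.3g}, {vals.max():.3g}]")
    roots = np.array(roots)
    return float(roots[np.argmin(np.abs(roots - pf0))])


def fixed_points(model: ModelSpec) -> FixedPointSet:
    """Disease-free, endemic (if RT > 1), and die-out fixed points.

    All satisfy H = 0; the die-out point has state zero infecteds but
    nonzero momentum, distinguishing it from the disease-free equilibrium.
    """
    pf = die_out_momentum(model)
    if model.kind == "constrained_1d":
        dfe = PhasePoint(np.array([0.0]), np.array([0.0]))
        dio = PhasePoint(np.array([0.0]), np.array([pf]))
    else:
        dfe = PhasePoint(np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        dio = PhasePoint(np.array([1.0, 0.0]), np.array([0.0, pf]))
    try:
        xe = mean_field_endemic(model.params, model.policy, model.kind)
        endemic = PhasePoint(xe, np.zeros_like(xe))
    except NoEndemicStateError:
        endemic = None
    return FixedPointSet(disease_free=dfe, endemic=endemic, die_out=dio)


# ----------------------------------------------------------------------
# Optimal path: generalized Newton on the discretized characteristic system
# ----------------------------------------------------------------------

def _default_t_half(model: ModelSpec, fps: FixedPointSet) -> float:
    """Half-width of the time mesh from the slowest endpoint eigenvalue.

    The path approaches each endpoint exponentially at the local
    linearization rate; T is chosen so exp(-lambda*T) < 1e-8.
    """
    lam = np.inf
    for pp in (fps.endemic, fps.die_out):
        z = np.concatenate([pp.state, pp.momentum])
        J = _field_jacobian_matrix(model, z)
        ev = np.linalg.eigvals(J)
        pos = np.abs(ev.real)
        pos = pos[pos > 1e-9]
        if pos.size:
            lam = min(lam, pos.min())
    if not np.isfinite(lam) or lam <= 0:
        lam = 1.0
    return 20.0 / lam


def optimal_path(model: ModelSpec, n_nodes: int = 2001, t_half: Optional[float] = None,
                 tol: float = 1e-10, max_iter: int = 200,
                 initial: Optional[OptimalPath] = None) -> OptimalPath:
    """Heteroclinic extinction path by damped Newton iteration.

    The characteristic system is discretized on a uniform mesh over
    [-t_half, t_half] with central second-order differences; boundary nodes
    are pinned to the endemic and die-out fixed points, the interior is
    initialized with a sigmoidal interpolation between them (or a previous
    path), and the full stacked nonlinear system is solved simultaneously by
    Newton's method with residual backtracking.

    Raises PathConvergenceError (with the residual history) on failure.
    """
    fps = fixed_points(model)
    if fps.endemic is None:
        raise NoEndemicStateError("optimal path requires RT > 1")
    if t_half is None:
        t_half = _default_t_half(model, fps)

    d = fps.endemic.state.size
    M = int(n_nodes)
    t = np.linspace(-t_half, t_half, M)
    h = t[1] - t[0]

    za = np.concatenate([fps.endemic.state, fps.endemic.momentum])
    zb = np.concatenate([fps.die_out.state, fps.die_out.momentum])

    if initial is not None:
        Z = np.empty((M, 2 * d))
        for k in range(d):
            Z[:, k] = np.interp(t, initial.t, initial.states[:, k])
            Z[:, d + k] = np.interp(t, initial.t, initial.momenta[:, k])
    elif model.kind == "full_2d":
        # seed the 4-D solve from the constrained model's path: the full model
        # is a small perturbation of it (y ~ 1 - x, p_s ~ 0)
        from .models import make_constrained_model
        try:
            p1 = optimal_path(make_constrained_model(model.params, model.policy),
                              n_nodes=min(M, 801))
            x1 = np.interp(t, p1.t * (t_half / p1.t[-1]), p1.states[:, 0])
            px1 = np.interp(t, p1.t * (t_half / p1.t[-1]), p1.momenta[:, 0])
            Z = np.column_stack([1.0 - x1, x1, np.zeros(M), px1])
        except PathConvergenceError:
            sig = 0.5 * (1.0 + np.tanh(t / (t_half / 8.0)))
            Z = za[None, :] + sig[:, None] * (zb - za)[None, :]
    else:
        sig = 0.5 * (1.0 + np.tanh(t / (t_half / 8.0)))
        Z = za[None, :] + sig[:, None] * (zb - za)[None, :]
    Z[0], Z[-1] = za, zb

    def field(Zm):
        if model.kind == "constrained_1d":
            xd, pd = _f1(model, Zm[:, 0], Zm[:, 1])
            return np.stack([xd, pd], axis=1)
        f = _f2(model, Zm[:, 0], Zm[:, 1], Zm[:, 2], Zm[:, 3])
        return np.stack(f, axis=1)

    def residual(Zm):
        R = (Zm[2:] - Zm[:-2]) / (2.0 * h) - field(Zm[1:-1])
        return R.reshape(-1)

    nvar = 2 * d
    n_int = M - 2

    # sparsity pattern of the block-tridiagonal Jacobian (interior unknowns)
    def jacobian(Zm):
        rows, cols, vals = [], [], []
        # diagonal blocks: -J_F at each interior node
        if model.kind == "constrained_1d":
            a, b, c, dd = _j1(model, Zm[1:-1, 0], Zm[1:-1, 1])
            Jf = np.empty((n_int, 2, 2))
            Jf[:, 0, 0], Jf[:, 0, 1], Jf[:, 1, 0], Jf[:, 1, 1] = a, b, c, dd
        else:
            blocks = _j2(model, Zm[1:-1, 0], Zm[1:-1, 1], Zm[1:-1, 2], Zm[1:-1, 3])
            Jf = np.empty((n_int, 4, 4))
            for i in range(4):
                for j in range(4):
                    Jf[:, i, j] = blocks[i][j]
        idx = np.arange(n_int)
        for i in range(nvar):
            for j in range(nvar):
                rows.append(idx * nvar + i)
                cols.append(idx * nvar + j)
                vals.append(-Jf[:, i, j])
        # off-diagonal +/- I/(2h) from the central difference
        coef = 1.0 / (2.0 * h)
        for i in range(nvar):
            up = idx[:-1]
            rows.append(up * nvar + i)
            cols.append((up + 1) * nvar + i)
            vals.append(np.full(n_int - 1, coef))
            rows.append((up + 1) * nvar + i)
            cols.append(up * nvar + i)
            vals.append(np.full(n_int - 1, -coef))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return sparse.csc_matrix((vals, (rows, cols)), shape=(n_int * nvar, n_int * nvar))

    R = residual(Z)
    rnorm = np.abs(R).max()
    history = [rnorm]
    n_it = 0
    while rnorm > tol and n_it < max_iter:
        J = jacobian(Z)
        try:
            dz = spsolve(J, -R)
        except Exception as exc:  # pragma: no cover - singular Jacobian
            raise PathConvergenceError(f"linear solve failed: {exc}", history)
        step = dz.reshape(n_int, nvar)
        alpha = 1.0
        while alpha >= 1e-6:
            Znew = Z.copy()
            Znew[1:-1] += alpha * step
            Rnew = residual(Znew)
            rn = np.abs(Rnew).max()
            if rn < rnorm or rn < tol:
                break
            alpha *= 0.5
        else:
            raise PathConvergenceError(
                f"Newton stalled at residual {rnorm:.3g} after {n_it} iterations",
                history)
        Z, R, rnorm = Znew, Rnew, rn
        history.append(rnorm)
        n_it += 1

    converged = rnorm <= tol
    if not converged:
        raise PathConvergenceError(
            f"no convergence after {n_it} iterations (residual {rnorm:.3g})", history)

    states, momenta = Z[:, :d], Z[:, d:]
    Hvals = hamiltonian(model, states, momenta)
    path = OptimalPath(t=t, states=states, momenta=momenta, action=np.nan,
                       max_abs_H=float(np.abs(Hvals).max()), residual=float(rnorm),
                       n_iter=n_it, converged=True, model=model)
    path.action = action_numeric(path)
    return path


def action_numeric(path: OptimalPath) -> float:
    """Per-capita action s = int p . dx along a converged path.

    Evaluated as the time-parametrized integral int p . (dH/dp) dt with the
    analytic characteristic velocity, by composite Simpson on the mesh (so
    non-monotone Model 2 coordinates need no special handling).
    """
    sd, _ = characteristic_field(path.model, path.states, path.momenta)
    integrand = np.sum(path.momenta * sd, axis=1)
    return float(integrate.simpson(integrand, x=path.t))


# ----------------------------------------------------------------------
# Model 1 zero-energy branch: independent route to momentum and action
# ----------------------------------------------------------------------

def branch_momentum(model: ModelSpec, x: float) -> float:
    """Nontrivial root p(x) < 0 of H(x, p) = 0 for the constrained model.

    Without treatment this is the closed form p = ln[(gamma+mu)/(beta(1-x))];
    with treatment it is found by bracketed root-finding.
    """
    if model.kind != "constrained_1d":
        raise ValueError("branch_momentum applies to the constrained model only")
    beta, rem = model.params.beta, model.params.removal
    ka, nu = _policy_terms(model)
    if nu == 0.0 or ka == 0.0:
        return math.log(rem / (beta * (1.0 - x)))
    pf = die_out_momentum(model)
    if x < 1e-12:
        return pf

    # H is strictly convex in p with H(x, 0) = 0, so there is exactly one
    # nontrivial root, below zero for 0 < x < x*.  Near the endemic point the
    # branch is linear with slope p'(x*) = -2*H_xp/H_pp (l'Hopital on
    # dp/dx = -H_x/H_p), which both regularizes the merging roots and gives a
    # strict bracket endpoint between 0 and the root.
    xe = mean_field_endemic(model.params, model.policy, "constrained_1d")[0]
    h_xp = beta * (1.0 - 2.0 * xe) - rem - nu * ka
    h_pp = beta * xe * (1.0 - xe) + rem * xe + nu * ka**2 * xe**2
    slope = -2.0 * h_xp / h_pp
    p_lin = slope * (x - xe)
    if abs(p_lin) < 1e-8:
        return float(p_lin)

    def g(p):
        return _h1(model, x, p)

    hi = 0.05 * p_lin
    lo = pf - 1.0
    glo = g(lo)
    while glo < 0.0 and lo > pf - 30.0:
        lo -= 1.0
        glo = g(lo)
    return float(optimize.brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16))


def action_branch_quadrature(model: ModelSpec) -> float:
    """Model 1 action by quadrature of the zero-energy branch, s = -int p dx.

    Independent of the Newton path solver; used as a cross-check and as a
    robust fallback for parameter sweeps.
    """
    xe = mean_field_endemic(model.params, model.policy, "constrained_1d")[0]

    def integrand(x):
        return -branch_momentum(model, x)

    val, _ = integrate.quad(integrand, 0.0, xe, limit=200, epsabs=1e-12, epsrel=1e-11)
    return float(val)


def action_asymptotic(params: EpidemicParams, policy: TreatmentPolicy,
                      order: int = 1, kappa_validity: float = 0.2):
    """Small-kappa expansion of the Model 1 action, s(kappa) = s0 + kappa*s1.

    s0 = ln R0 - 1 + 1/R0 is the untreated closed form.  s1 is the linear
    response of the action to the treatment term of the Hamiltonian,
    evaluated along the untreated optimal path:

        s1 = (nu/beta) * int_0^{x0*} p0(x) / (x0* - x) dx,

    with p0(x) = -ln[R0(1-x)] and x0* = 1 - 1/R0 (the integrand has a
    removable singularity at the endemic endpoint, limit -R0).  Validity
    degrades as kappa grows; a warning flag is returned above
    ``kappa_validity``.

    Returns (s, s0, s1, within_validity).
    """
    r0 = params.beta / params.removal
    if r0 <= 1.0:
        raise NoEndemicStateError(f"R0 = {r0:.4g} <= 1")
    s0 = math.log(r0) - 1.0 + 1.0 / r0
    xs = 1.0 - 1.0 / r0

    def integrand(x):
        u = xs - x
        if u < 1e-9:
            return -r0
        return -math.log(r0 * (1.0 - x)) / u

    val, _ = integrate.quad(integrand, 0.0, xs, limit=200, points=[xs], epsabs=1e-12)
    s1 = policy.nu / params.beta * val
    if order == 0:
        s = s0
    else:
        s = s0 + policy.kappa * s1
    return s, s0, s1, policy.kappa <= kappa_validity


# ----------------------------------------------------------------------
# Prefactor and MTE
# ----------------------------------------------------------------------

def prefactor(params: EpidemicParams, policy: TreatmentPolicy,
              mode: str = "analytic", *, mte_ref: Optional[float] = None,
              s: Optional[float] = None, model=None) -> float:
    """Non-exponential prefactor B (years) of MTE = B * exp(N*s).

    analytic
        Boundary-layer matched prefactor for the constrained model,

            B = sqrt(2*pi/N) * exp(p_f) / ((gamma+mu) * x*^2),

        whose treatment dependence enters through the die-out momentum p_f
        and the endemic fraction x*.  At kappa*nu = 0 this reduces to the
        classical untreated SIS result
        sqrt(2*pi/N) * R0 / ((gamma+mu) * (R0-1)^2).
    calibrated_constant
        B = mte_ref / exp(N*s) at one reference point (mte_ref from the
        master equation or simulation; s the per-capita action), reused
        across a sweep.
    unity
        B = 1 (log-scale comparisons).
    """
    from .models import make_constrained_model

    if mode == "unity":
        return 1.0
    if mode == "calibrated_constant":
        if mte_ref is None or s is None:
            raise ValueError("calibrated mode needs mte_ref and the action s")
        return float(mte_ref * math.exp(-params.N_bar * s))
    if mode != "analytic":
        raise ValueError(f"unknown prefactor mode {mode!r}")

    m = model if model is not None else make_constrained_model(params, policy)
    if m.kind != "constrained_1d":
        raise ValueError("analytic prefactor is defined for the constrained model")
    rt = reproduction_numbers(params, policy).RT
    if rt <= 1.0:
        raise NoEndemicStateError("analytic prefactor requires RT > 1")
    pf = die_out_momentum(m)
    x_star = 1.0 - 1.0 / rt
    return float(math.sqrt(2.0 * math.pi / params.N_bar)
                 * math.exp(pf) / (params.removal * x_star**2))


def mte_wkb(s: float, B: float, N_bar: int, method: str = "wkb_numeric") -> MTEEstimate:
    """Mean time to extinction MTE = B * exp(N*s), overflow-safe via log."""
    if s < 0:
        raise ValueError(f"action must be nonnegative, got {s}")
    if B <= 0:
        raise ValueError(f"prefactor must be positive, got {B}")
    log_mte = math.log(B) + N_bar * s
    overflow = log_mte > 700.0
    mte = math.inf if overflow else math.exp(log_mte)
    return MTEEstimate(s=s, B=B, N_bar=int(N_bar), log_mte=log_mte,
                       mte=mte, overflowed=overflow, method=method)


# ----------------------------------------------------------------------
# Quasi-stationarity map
# ----------------------------------------------------------------------

def quasistationarity_map(params: EpidemicParams, policy: TreatmentPolicy,
                          kappa_grid, beta_grid, threshold: float = 10.0,
                          n_nodes: int = 401) -> dict:
    """Field of N*s over a (kappa, beta) grid with the RT = 1 boundary.

    For each grid cell with RT > 1 the Model 1 action is computed (Newton
    path solve, falling back to branch quadrature, then to the small-kappa
    asymptotic form); cells with RT <= 1 are NaN.  A cell is flagged
    quasi-stationary when N*s >= threshold (default 10), i.e. extinction is
    a rare event lying in the tail of the quasi-stationary distribution.

    Returns a dict with arrays ``Ns`` (beta rows x kappa columns), ``RT``,
    ``quasi_stationary`` (bool mask), the grids, the analytic ``rt1_curve``
    kappa(beta) where RT = 1, and the interpolated ``qs_contour`` kappa(beta)
    where N*s = threshold.
    """
    from .models import make_constrained_model

    kappa_grid = np.asarray(kappa_grid, dtype=float)
    beta_grid = np.asarray(beta_grid, dtype=float)
    N = params.N_bar
    Ns = np.full((beta_grid.size, kappa_grid.size), np.nan)
    RT = np.empty_like(Ns)
    failures = []
    for i, b in enumerate(beta_grid):
        pi = EpidemicParams(beta=float(b), gamma=params.gamma, mu=params.mu, N_bar=N)
        for j, k in enumerate(kappa_grid):
            pol = TreatmentPolicy(kappa=float(k), nu=policy.nu,
                                  schedule=policy.schedule, rounding=policy.rounding)
            rt = reproduction_numbers(pi, pol).RT
            RT[i, j] = rt
            if rt <= 1.0 + 1e-9:
                continue
            m = make_constrained_model(pi, pol)
            try:
                s = optimal_path(m, n_nodes=n_nodes).action
            except Exception:
                try:
                    s = action_branch_quadrature(m)
                except Exception as exc:
                    failures.append((float(b), float(k), repr(exc)))
                    s, *_ = action_asymptotic(pi, pol)
                    if s < 0:  # asymptotic form outside its validity
                        s = np.nan
            Ns[i, j] = N * s

    nu = policy.nu
    rt1_curve = (beta_grid - params.removal) / nu if nu > 0 else np.full_like(beta_grid, np.nan)
    qs_contour = np.full(beta_grid.size, np.nan)
    for i in range(beta_grid.size):
        row = Ns[i]
        ok = np.isfinite(row)
        if not ok.any():
            continue
        kk, vv = list(kappa_grid[ok]), list(row[ok])
        # anchor at the RT = 1 boundary, where the action vanishes exactly
        if nu > 0 and np.isfinite(rt1_curve[i]) and rt1_curve[i] > kk[-1]:
            kk.append(float(rt1_curve[i]))
            vv.append(0.0)
        # N*s decreases with kappa; linear interpolation at the threshold
        for a in range(len(vv) - 1):
            if (vv[a] - threshold) * (vv[a + 1] - threshold) <= 0 and vv[a] != vv[a + 1]:
                w = (threshold - vv[a]) / (vv[a + 1] - vv[a])
                qs_contour[i] = kk[a] + w * (kk[a + 1] - kk[a])
                break
    return {
        "kappa_grid": kappa_grid, "beta_grid": beta_grid,
        "Ns": Ns, "RT": RT, "quasi_stationary": Ns >= threshold,
        "threshold": threshold, "rt1_curve": rt1_curve,
        "qs_contour": qs_contour, "failures": failures,
    }
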