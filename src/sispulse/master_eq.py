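"""Direct numerical treatment of the one-dimensional master equation.

The constrained SIS model with Poisson-scheduled pulses is a continuous-time
Markov chain on I = 0..N with an absorbing state at I = 0.  This module
builds its generator (including the bulk treatment jumps, with the rounding
rule applied exactly on the integer lattice), solves the linear first-passage
system for mean extinction times, extracts the quasi-stationary distribution
from the slowest-decaying eigenmode, and evolves distributions in time.  It
is the exact oracle against which the simulation and WKB routes are checked.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve, eigs, expm_multiply

from .models import ModelSpec
from .params import round_pulse

__all__ = [
    "Generator",
    "LatticeDistribution",
    "build_generator",
    "mean_extinction_time_direct",
    "quasi_stationary_distribution",
    "evolve_distribution",
    "export_generator_coo",
    "export_distribution_csv",
]


@dataclass(frozen=True)
class Generator:
    """Sparse generator Q of the lattice chain; rows are source states.

    Row sums are zero; row 0 (the absorbing extinct state) is identically
    zero.  Q[i, j] for j != i is the rate of the jump i -> j.
    """

    Q: sparse.csr_matrix
    N_bar: int

    @property
    def n_states(self) -> int:
        return self.Q.shape[0]


@dataclass
class LatticeDistribution:
    """Probability mass over I = 0..N at a given time."""

    mass: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        if (self.mass < -1e-12).any():
            raise ValueError("probability mass must be nonnegative")
        total = self.mass.sum()
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"mass must sum to 1 (got {total!r})")

    @property
    def absorbed(self) -> float:
        return float(self.mass[0])


def build_generator(model: ModelSpec, max_states_2d: int = 0) -> Generator:
    """Generator of the constrained model with Poisson pulse arrivals.

    Treatment contributes a rate-nu edge from I to I - round(kappa*I) for
    every I where the rounded pulse is at least one individual; below that
    the pulse is a no-op and contributes nothing (the rounding rule is the
    declared source of the small-kappa fixed-dose effect, so states are kept
    as raw counts).  Periodic schedules are not Markovian and are rejected.
    """
    if model.kind != "constrained_1d":
        raise ValueError(
            "build_generator supports the constrained 1-D model; the 2-D model "
            "is only tractable at tiny N (not implemented here)")
    if model.policy.is_active and model.policy.schedule != "poisson":
        raise ValueError("the generator is Markov: only the poisson schedule is representable")

    p, pol = model.params, model.policy
    N = p.N_bar
    I = np.arange(N + 1)
    up = p.beta * I * (N - I) / N
    down = p.removal * I
    up[0] = down[0] = 0.0

    rows, cols, vals = [], [], []
    rows.append(I[:-1]); cols.append(I[:-1] + 1); vals.append(up[:-1])
    rows.append(I[1:]); cols.append(I[1:] - 1); vals.append(down[1:])
    if pol.is_active:
        for i in range(1, N + 1):
            r = round_pulse(pol.kappa, i, pol.rounding)
            if r >= 1:
                rows.append(np.array([i])); cols.append(np.array([i - r]))
                vals.append(np.array([pol.nu]))
    rows = np.concatenate(rows); cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    Q = sparse.coo_matrix((vals, (rows, cols)), shape=(N + 1, N + 1)).tolil()
    diag = np.asarray(Q.sum(axis=1)).ravel()
    Q.setdiag(-diag)
    Q[0, :] = 0.0
    return Generator(Q=Q.tocsr(), N_bar=N)


def _first_passage_increments(gen: Generator):
    """Stable elimination of the first-passage system of a skip-free-up chain.

    The chain moves up only by +1 (infection), so in the increment variables
    delta_k = tau(k+1) - tau(k) the balance at state I reads

        lam_I * delta_I = sum_j r_{I->j} * (delta_j + ... + delta_{I-1}) - 1,

    which propagates forward once delta_0 = tau(1) is known.  Writing
    delta_I = P_I * delta_0 - M_I gives two recursions whose terms are all
    positive (no cancellation), so they remain accurate even when the MFPT is
    astronomically large -- the naive LU solve of the transient block loses
    all precision once the MFPT exceeds ~1/eps because the system's condition
    number is of the order of the MFPT itself.  The top row (lam_N = 0)
    closes the system and yields delta_0 as a ratio of positive sums.

    The P and M recursions are carried in log space (their entries grow like
    exp(c*N) near the top of the lattice and would overflow in linear
    arithmetic), with window sums done by logsumexp over the short down-jump
    spans.  Returns (log_delta_0, logP, logM) with
    delta_k = exp(logP_k) * delta_0 - exp(logM_k).
    """
    from scipy.special import logsumexp

    Q = gen.Q
    N = gen.n_states - 1
    indptr, indices, data = Q.indptr, Q.indices, Q.data
    logP = np.full(N, -np.inf)
    logM = np.full(N, -np.inf)
    logP[0] = 0.0
    log_delta0 = None
    for I in range(1, N + 1):
        lam = 0.0
        termsP, termsM = [], [0.0]  # the inhomogeneous "+1" seeds M
        for ptr in range(indptr[I], indptr[I + 1]):
            j, r = indices[ptr], data[ptr]
            if j == I + 1:
                lam = r
            elif j < I:
                termsP.append(math.log(r) + logsumexp(logP[j:I]))
                termsM.append(math.log(r) + logsumexp(logM[j:I]))
        accP = logsumexp(termsP) if termsP else -np.inf
        accM = logsumexp(termsM)
        if I == N:
            if accP == -np.inf:
                raise RuntimeError(
                    "singular first-passage system: the absorbing state is "
                    "not reachable from every transient state")
            log_delta0 = accM - accP
            break
        if lam <= 0.0:
            raise RuntimeError(
                f"state {I} has no upward rate: the chain is not skip-free "
                "upward as required by the stable elimination")
        logP[I] = accP - math.log(lam)
        logM[I] = accM - math.log(lam)
    return log_delta0, logP, logM


def _tau_profile(gen: Generator):
    """tau(I) for I = 0..N from the stable increment elimination.

    Increments are clamped at zero where rounding makes them marginally
    negative (far above the endemic state tau is flat and the increments are
    exact differences of two nearly equal positive quantities; their true
    values are negligible there).
    """
    log_delta0, logP, logM = _first_passage_increments(gen)
    if log_delta0 > 700.0:
        raise OverflowError(
            f"MFPT ~ exp({log_delta0:.1f}) exceeds the floating-point range; "
            "report the log-MTE via the quasi-stationary decay rate instead")
    d = log_delta0 + logP
    # far above the endemic state logM -> d (tau is flat, delta ~ 0); once the
    # two logs agree beyond achievable precision the true increment is
    # unresolvable and physically negligible, so it is set to zero
    with np.errstate(over="ignore", invalid="ignore"):
        gap = logM - d
        delta = np.where(
            np.isneginf(d) | (gap > -1e-8),
            0.0,
            -np.exp(np.minimum(d, 709.0)) * np.expm1(np.clip(gap, None, 50.0)))
    delta = np.clip(np.nan_to_num(delta, nan=0.0, posinf=0.0), 0.0, None)
    tau = np.concatenate([[0.0], np.cumsum(delta)])
    return tau


def mean_extinction_time_direct(gen: Generator, start) -> float:
    """Mean first-passage time to I = 0 (years), exact in the rates.

    Solves the first-passage linear system over the transient states by a
    cancellation-free forward elimination (see _first_passage_increments),
    accurate even for astronomically long extinction times.  ``start`` is
    either an integer state or a distribution over all states (giving the
    expectation of tau under it); tau(0) = 0.
    """
    tau = _tau_profile(gen)
    if np.isscalar(start) or np.ndim(start) == 0:
        return float(tau[int(start)])
    w = np.asarray(start, dtype=float)
    if w.size != gen.n_states:
        raise ValueError("start distribution must cover all states 0..N")
    return float(w @ tau)


def quasi_stationary_distribution(gen: Generator, warn_threshold: float = 1.0):
    """Quasi-stationary distribution and decay rate of the transient chain.

    Returns (LatticeDistribution with zero mass on I = 0, lambda_1,
    mte_estimate = 1/lambda_1).  The QSD is the left eigenvector of the
    transient-restricted generator for the eigenvalue of smallest magnitude;
    1/lambda_1 equals the mean extinction time from the QSD start when
    extinction is a rare event.  Warns when the decay is not slow (N*s
    small, quasi-stationarity questionable).
    """
    Qtt = gen.Q[1:, 1:]
    n = Qtt.shape[0]
    if n <= 2:
        w, v = np.linalg.eig(Qtt.toarray().T)
        idx = np.argmin(np.abs(w))
        lam, vec = -w[idx].real, v[:, idx].real
    else:
        try:
            w, v = eigs(Qtt.T.tocsc(), k=1, sigma=0.0, which="LM")
        except Exception as exc:
            raise RuntimeError(f"QSD eigensolve failed to converge: {exc}")
        lam, vec = -w[0].real, v[:, 0].real
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    vec /= vec.sum()
    mass = np.concatenate([[0.0], vec])
    if lam > warn_threshold:
        warnings.warn(
            f"fast decay rate lambda_1 = {lam:.3g}/year: extinction is not a "
            "rare event here and the quasi-stationary picture is marginal")
    return LatticeDistribution(mass=mass), float(lam), float(1.0 / lam)


def export_generator_coo(gen: Generator, path) -> None:
    """Write the generator as text coordinate triplets: row, col, rate."""
    coo = gen.Q.tocoo()
    with open(path, "w") as fh:
        fh.write("row,col,rate\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i},{j},{v!r}\n")


def export_distribution_csv(dist: LatticeDistribution, path) -> None:
    """Write a lattice distribution as CSV columns (I, mass)."""
    with open(path, "w") as fh:
        fh.write("I,mass\n")
        for i, m in enumerate(dist.mass):
            fh.write(f"{i},{m!r}\n")


def evolve_distribution(gen: Generator, p0: LatticeDistribution, t: float) -> LatticeDistribution:
    """Action of the generator semigroup: p(t) = p0 @ exp(Q t).

    Mass is conserved, including what accumulates in the absorbing state.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if p0.mass.size != gen.n_states:
        raise ValueError("distribution size does not match the generator")
    if t == 0.0:
        return LatticeDistribution(mass=p0.mass.copy(), time=p0.time)
    out = expm_multiply(gen.Q.T.tocsc() * t, p0.mass)
    err = abs(out.sum() - 1.0)
    if err > 1e-8:
        raise RuntimeError(f"probability conservation failure: |1 - total| = {err:.3g}")
    out = np.clip(out, 0.0, None)
    out /= out.sum()
    return LatticeDistribution(mass=out, time=p0.time + t)
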