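# Methods

## The models

`sispulse` studies disease extinction in a stochastic SIS
(susceptible–infected–susceptible) population under pulsed treatment.
Rates, all per year: contact rate β, recovery rate γ, and a common birth and
death rate μ chosen equal so the population is constant on average at N̄.
The basic reproduction number is R₀ = β/(γ+μ); deterministically the disease
is endemic when the effective reproduction number exceeds one.

Treatment arrives as instantaneous pulses: each pulse moves a fraction κ of
the currently infected back to the susceptible class (100% efficacy; partial
efficacy is equivalent to a smaller κ).  Pulses are scheduled either at
Poisson-random times with mean frequency ν per year, or strictly
periodically at times k/ν.  Averaged over pulses, treatment adds κν to the
per-capita removal rate, giving the treated reproduction number
R_T = β/(γ + μ + κν); the mean-field endemic state exists iff R_T > 1, at
infected fraction x* = 1 − 1/R_T.

Two stochastic models share this structure:

* **Constrained model** (1-D): S + I = N̄ exactly; channels are infection
  I → I+1 at βI(N̄−I)/N̄, combined recovery-plus-death I → I−1 at (γ+μ)I
  (a death of an infected is immediately balanced by a susceptible birth),
  and the treatment pulse.
* **Full model** (2-D): (S, I) with constant birth S → S+1 at μN̄,
  per-capita deaths at μS and μI, frequency-dependent infection
  (S, I) → (S−1, I+1) at βSI/(S+I), recovery at γI, and the pulse, which
  conserves S + I.

Two full-model conventions were genuinely open.  Births occur at the
constant rate μN̄ rather than per capita: per-capita birth makes the total
population a critical branching process with unbounded excursions, while
constant birth gives an Ornstein–Uhlenbeck-like total with mean N̄ —
"constant on average".  Infection is normalized by the realized population
S+I, not by N̄: with a fixed-N̄ denominator, optimal extinction routes
exploit total-population dips that cheapen per-capita transmission, and the
2-D action stays ~45% below the 1-D action even as fluctuations vanish
(checked against a brute-force 2-D master-equation solve at N = 40–60);
with the S+I denominator the 2-D action approaches the 1-D one, which is the
behavior the constrained approximation is meant to capture.

On the integer lattice a pulse treats round(κI) individuals.  The default is
the integer part (floor), so small pulses on few infecteds do nothing —
treatment "switches off" below I = 1/κ; rounding up (ceil) is available and
keeps pulses active to the last infected.  A 10⁻⁹ guard absorbs binary
representation error in the product κI (0.2 × 5 must floor to 1).

## Routes to the mean time to extinction (MTE)

**Gillespie simulation.**  Exact event-driven sampling (direct method); the
hot loops are numba-compiled.  Poisson pulses are an ordinary channel with
constant propensity ν.  Periodic pulses fire exactly at k/ν; the demographic
exponential clock is capped at the pulse time and redrawn afterwards, which
is statistically exact because the clock is memoryless.  Periodic schedules
start at t = 1/ν (not t = 0) so both schedules have comparable mean
first-pulse times.  Reproducibility contract: realization i of an ensemble
with master seed m uses `PCG64(SeedSequence(entropy=m, spawn_key=(i,)))`,
so ensembles are order-independent and extensible.  Runs alive at t_max
(default 10⁴ years; raise it for rare-event fixtures) are censored, excluded
from the mean, and flagged when they exceed 1% of the ensemble.

**Master equation.**  For the constrained model with Poisson pulses the
process is a Markov chain on I = 0..N̄ with absorbing 0; the generator
includes a rate-ν edge from I to I − round(κI) wherever the pulse is
non-trivial.  Mean first-passage times solve Q_tt τ = −1.  The naive sparse
LU solve of that system is unusable for long extinction times: its condition
number is of order the MFPT itself, and beyond MFPT ~ 1e13 the solution
loses all significance (observed 50×-wrong and even negative values).
Because infection is the only upward channel (+1 jumps), the chain is
skip-free upward, and the system admits a cancellation-free forward
elimination in the increments δ_I = τ(I+1) − τ(I): writing
δ_I = P_I δ₀ − M_I, the recursions for P and M have all-positive terms and
are carried in log space (logsumexp over the short down-jump windows), with
the top row closing for δ₀ = τ(1) as a ratio of positive sums.  The result
was validated against exact rational-arithmetic Gaussian elimination
(N = 120, treated chain, relative error 9e-10) and against the LU solve in
its reliable regime.  Increments far above the endemic state, where τ is
flat and the two log tracks agree to within achievable precision, are set to
zero; their true values are physically negligible there.  MFPTs up to the
float range (~1e300) are supported; beyond that the log of τ(1) is still
well defined internally but the public function raises.

The quasi-stationary distribution is the left eigenvector of the
transient-restricted generator for the eigenvalue λ₁ of smallest magnitude
(shift-invert Arnoldi), with 1/λ₁ the associated MTE estimate; the two
classical definitions (1/λ₁ vs the MFPT from the QSD start) agree to <1%
when extinction is rare.  λ₁ is only meaningful while 1/λ₁ stays well below
1/ε_machine times the rate scale; the QSD fixtures in the tests respect
that.  Distribution evolution uses `expm_multiply` on the full generator and
checks probability conservation to 1e-8.

**WKB / optimal path.**  The eikonal ansatz P(I) ∝ exp(−N̄ s(x)), x = I/N̄,
turns the stationary master equation into H(x, ∂s/∂x) = 0 with

  H(x, p) = βx(1−x)(eᵖ−1) + (γ+μ)x(e⁻ᵖ−1) + ν(e^{−κxp}−1)

for the constrained model (treatment enters through its *linearized* bulk
increment −κx; see the caveat below), and the six-channel analogue for the
full model with the pulse term ν(e^{κx(p_s−p_x)}−1).  Sign convention:
p = ds/dx, extinction paths carry p < 0 and positive action.  Fixed points:
disease-free (x = 0, p = 0); endemic (x*, 0) when R_T > 1; and the
fluctuational die-out point at x = 0 with momentum p_f < 0 solving
β(eᵖ−1) + (γ+μ)(e⁻ᵖ−1) − νκp = 0 (closed form p_f = −ln R₀ untreated).
The root search scans [p_f(κ=0) − 1, 0) and keeps the root closest to
−ln R₀, for continuity in κ.

The optimal path is the zero-energy heteroclinic connection from the endemic
point to the die-out point.  It is computed by a damped Newton iteration on
the characteristic system discretized with second-order central differences
on a uniform mesh (default 2001 nodes), endpoints pinned to the fixed
points, mesh half-width set so the linearized endpoint decay satisfies
e^{−λT} < 1e-8, and a sigmoidal interpolant as the initial guess (the 4-D
full-model solve is seeded from the constrained model's path: y = 1 − x,
p_s = 0).  Converged paths satisfy max|H| ≤ ~1e-6 and Newton residual
≤ 1e-10; the action s = ∫ p·dx is evaluated as the time-parametrized Simpson
integral of p·(∂H/∂p).  For the constrained model an independent route —
solving H(x, p) = 0 for the strictly convex-in-p nontrivial branch p(x) at
each x and integrating — agrees with the Newton path to ~1e-7 and serves as
the fast engine for parameter sweeps.  Mesh convergence of the action is
second order (observed order ≥ 1.9).

**Small-κ expansion.**  s(κ) ≈ s₀ + κs₁ with s₀ = ln R₀ − 1 + 1/R₀ and the
linear response of the action to the treatment Hamiltonian term along the
untreated path,

  s₁ = (ν/β) ∫₀^{x₀*} p₀(x)/(x₀* − x) dx,   p₀(x) = −ln[R₀(1−x)],

whose integrand has a removable singularity (limit −R₀) at the endemic
endpoint.  The expansion parameter is effectively κν/(γ+μ); the default
validity warning triggers at κ > 0.2, and accuracy claims are made for
gentle pulses (ν ~ 1/year at γ+μ = 1), where the first-order truncation
error at κ = 0.05 is ~0.3% (it is quadratic in ν: ~8% at ν = 4).

**MTE and prefactor.**  MTE = B·exp(N̄·s).  Prefactor modes: `unity` (log
comparisons); `calibrated_constant`, B = MTE_ref·exp(−N̄s) from one exact or
simulated reference point, reused across a sweep; and `analytic`,

  B = sqrt(2π/N̄) · e^{p_f} / ((γ+μ) · x*²),

a boundary-layer-matched form whose treatment dependence enters through the
treated p_f and x*.  At κν = 0 it reduces to the classical untreated-SIS
prefactor sqrt(2π/N̄)·R₀/((γ+μ)(R₀−1)²), and against exact MFPTs it is
accurate to O(1/N̄) (4–7% at N̄ = 100–600 untreated; ~2–30% with treatment in
the WKB-dominant regime).

## Validity of the WKB route — a caveat the package itself exposes

The WKB treatment term above uses the linearized pulse increment, treating
the bulk jump −κI as if it were infinitesimal on the s(x) landscape.  That
is the form whose x→0 limit gives the transcendental die-out equation, and
it is accurate when pulses are weak or rare.  But a pulse removes an O(N̄)
number of individuals at an O(1) rate, so a run of k closely spaced pulses
multiplies the infected count by (1−κ)ᵏ at a probability cost that grows
only logarithmically with N̄, not linearly.  Whenever the pulse rate ν
exceeds the endemic relaxation rate and κN̄x* is large, this clumping route
outruns exp(−N̄s): the exact master-equation ln MFPT becomes visibly concave
in N̄ (at β = 2, γ+μ = 1, κ = 0.05, ν = 4 the local slope falls from 0.075
at N̄ ≈ 450 to 0.034 at N̄ ≈ 1350, against a WKB action of 0.120, while the
untreated slope matches its action to 0.3%).  The same mechanism is why
random scheduling beats periodic scheduling in the endemic regime — pulse
clumps exist only under random timing — and why the advantage inverts once
κν exceeds β−γ−μ: with no endemic state left, the hazard is long Poisson
pulse gaps rather than missing clumps, and regular pulses win slightly.
Consequently the three-way MTE agreement (simulation, master equation, WKB)
should be expected only where N̄·s is large *and* treatment is not intense
(ν below the relaxation rate, or κN̄ modest); the quasi-stationarity map's
N̄·s ≥ 10 criterion is necessary but not sufficient.

## Experiments and desk-scale defaults

The `experiments` module scripts the standard studies as tidy DataFrames
with a provenance manifest: treatment sweeps over (κ, ν) by any of the three
methods (simulation default n = 2,000 realizations, endemic start);
paired Poisson-vs-periodic comparisons at matched budgets with per-cell
differences and standard errors; fixed-dose sweeps at constant C = κν
(interpreted as the per-capita dose rate per year) under both rounding
rules; two-model action comparisons; and the extinction-prehistory density
(time-weighted occupancy of the final window, default 5 years, before each
extinction) whose ridge is compared column-wise with the optimal path in
units of the histogram bin width.  A streaming kernel accumulates the
prehistory histogram without storing trajectories (circular event buffer per
realization).

Defaults in the test and acceptance fixtures are desk-scale, chosen by
budget arithmetic (events ≈ MTE × total propensity × realizations): e.g.
N̄ = 42–60 for ensemble statistics, N̄ = 500 with 5,000 realizations for the
prehistory ridge, N̄ ≤ 1,500 for exact solves, N̄ = 8,000 for the (cheap)
quasi-stationarity map.  Reference-scale settings (N̄ = 10,000, 2,000–10,000
realizations per cell, 200,000 prehistory realizations) run through the same
API unchanged.

## What the synthetic conditions do and do not show

All inputs are generated by the models themselves; there is no external
data.  Passing tests demonstrate internal consistency of the three routes
and the claimed orderings within this idealized world: constant-on-average
population, homogeneous mixing, exponential waiting times, perfectly
efficacious pulses with exact fractions, no seasonality, age structure,
spatial structure, or importation.  Real surveillance data would add
overdispersion, reporting noise, and parameter drift that none of these
checks address.

## Known limitations

* The analytic prefactor is a boundary-layer reconstruction validated
  against exact solves, exact only to O(1/N̄), and derived for floor
  rounding with κ < 1 (extinction flux passes through I = 1 via
  recovery/death only).
* The periodic-pulse chain is not Markov on the lattice, so the master
  equation route covers Poisson scheduling only; periodic scheduling is
  evaluated by simulation.
* The 2-D master equation is not built at production sizes (a brute-force
  small-N̄ version was used offline to validate the full model's action);
  the full model is served by simulation and WKB.
* Newton path solves can stall for very stiff settings (μ ≪ γ, or R_T very
  close to 1); continuation in a parameter, passing the previous path as the
  initial guess, is the supported workaround and is what the sweep code does.
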