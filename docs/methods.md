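# Methods

## Models and assumptions

Both models live on normalized, dimensionless cell densities (the
host population starts at H(0) = 1; no carrying-capacity rescaling is
applied).  The estrogen-free system couples host cells H, tumor cells
T and immune effectors I: logistic self-limitation for H and T,
one-sided competition (tumor suppresses host via δ₁, host does not
appear in the tumor equation), mass-action immune predation γ₂IT and
inactivation γ₃IT, a constant thymic immune source s with linear
death μ, and Michaelis–Menten immune recruitment ρIT/(ω+T) so that
recruitment saturates instead of producing immune crowding.

The estrogen extension treats 17-β estradiol as a well-mixed
compartment with constant source π and first-order clearance θ, so
E(t) = π/θ + (E₀ − π/θ)e^(−θt) exactly; this closed form doubles as
an integrator oracle in the tests.  Estrogen damages host DNA
(conversion flux σ₁HE out of H, of which σ₂HE ≤ σ₁HE lands in T),
raises the intrinsic tumor growth rate to α₃ > α₂, and suppresses
immune proliferation through the saturating term σ₃IE/(υ+E).

The nonnegative orthant is forward-invariant for both vector fields
(each derivative is nonnegative on its own zero plane; dI/dt = s > 0
at I = 0), which the test suite checks as a property.

## Parameters

The estrogen-free rates are the published table values (per day):
α₁ = 0.70, β₁ = 0.30, δ₁ = 1.0, α₂ = 0.98, β₂ = 0.40, γ₂ = 0.9,
s = 0.4, ρ = 0.2, ω = 0.3, μ = 0.29.  Two gaps are filled by package
defaults, both configurable and labeled non-published:

* γ₃ = 0.1/day — no published value; chosen small against γ₂ = 0.9 so
  predation dominates inactivation, consistent with the published
  conclusion that the tumor-free state is stable at the table values.
* The estrogen-specific rates α₃ = 1.0, σ₁ = 0.3, σ₂ = 0.2, σ₃ = 0.1,
  υ = 0.5, θ = 0.97, π = 0.2 (sweep default grid [0, 1] in 11 points)
  — no published values exist; these satisfy the stated orderings
  (σ₂ < σ₁, α₃ > α₂) and keep the steady estrogen level π/θ below
  α₁/σ₁ at small sources so the tumor-free closed form stays in the
  feasible region there.

Two published initial conditions disagree on the tumor burden
(T(0) = 1e-5 in the estrogen-free sections, T(0) = 10 in the estrogen
section); both are shipped as presets (`ic_estrogen_free_paper`,
`ic_estrogen_paper`) rather than silently reconciled.

## Equilibria

Feasibility is operational: a state is a feasible equilibrium iff its
coordinates are finite and nonnegative, its label-specific existence
conditions hold, and the scaled residual max|RHS|/max(1, |state|∞) is
below 1e-10 — i.e. it actually zeroes the implemented vector field.
Printed closed forms that fail this gate are still returned with
their residuals and failed conditions, because three of them are
instructive inconsistencies of the source analysis:

* **Estrogen-model tumor-free state.**  The published closed form
  (E = π/θ, H = (α₁−σ₁E)/β₁, I = s(E+υ)/(μ(E+υ)+σ₃E), T = 0) does not
  zero dT/dt when π > 0: the conversion influx σ₂HE is strictly
  positive at T = 0.  It is the exact fixed point only in the σ₂ → 0
  (or π → 0) limit and is reported as a quasi-equilibrium: the
  existence bound E ≤ α₁/σ₁ is exposed as a condition flag, and a
  `zero_tumor_influx` condition records why the residual gate fails.
  Biologically: while estrogen keeps converting host cells, a truly
  tumor-free tissue is impossible.
* **Host-free (dead1) state, estrogen-free model.**  The published
  construction takes T* as a root of γ₃T² + (μ+ωγ₃−ρ)T + μω and
  I* = s/(μ − ρT*/(ω+T*) + γ₃T*).  That quadratic factors as (ω+T)
  times the immune denominator, so its root is a pole of I*: the
  printed state never has a finite immune coordinate.  Both quadratic
  branches are computed (the printed "+√" branch tagged primary),
  with the conditions μ+ωγ₃ < ρ and (μ+ωγ₃−ρ)² ≥ 4γ₃ωμ reported; the
  state is infeasible by construction, matching the source's own
  remark that it requires vanishing immune dynamics.  The estrogen
  model's host-free state is instead solved self-consistently from
  T = (α₃ − γ₂I(T))/β₂ (the printed form carries a sign flip, which
  would not zero the vector field).
* **Coexistence.**  T and I are mutually coupled; substituting
  I(T) = s/(μ ± suppression − ρT/(ω+T) + γ₃T) reduces the system to
  one scalar equation in T, solved by a 2001-point bracketed scan
  with Brent refinement on (1e-12, α₂/β₂] (estrogen model: the "+√"
  branch of the quadratic β₁β₂T² + BT − σ₂E(α₁−σ₁E) = 0, scanned to a
  bound derived from the I = 0 root).  Every sign-change root is
  returned, ordered by T; scan intervals containing poles of I(T) are
  skipped.  Note that for 0 < E < α₁/σ₁ the quadratic's constant term
  is negative, so a positive tumor root always exists — the published
  claim that coexistence needs E ≥ α₁/σ₁ does not hold for the
  implemented field, and that condition is reported as a flag, not
  enforced.

## Stability

Eigenvalues come from the analytic Jacobian (verified against central
finite differences at step 1e-6 over random states); the published
characteristic polynomials are not reconstructed — one is truncated
in the source text and one contains a coefficient ("3σ₁E") that does
not follow from the Jacobian.  Classification uses a marginality band
of 1e-9 on real parts to absorb double-precision eigensolves near
bifurcations.  Diagnostics carry the closed-form tumor-free triple
(−α₁, α₂−γ₂s/μ, −μ), the resistance coefficient sγ₂/μ, the 2×2
tumor–immune block's trace/determinant at coexistence, and the
published λ²-coefficient of the estrogen coexistence cubic (as a
report-only quantity).

Routh–Hurwitz is implemented for monic quadratics (both lower
coefficients positive) and cubics (a > 0, c > 0, ab > c) and is
cross-checked against companion-matrix eigenvalues in the tests.

Global stability splits the state into undamaged compartments X
(H, I and, with estrogen, E) and the damaged compartment Z = T, and
requires H1 (the tumor-free subsystem dX/dt = F(X,0) globally stable
— logistic plus linear dynamics, so it holds whenever the effective
host growth α₁ − σ₁π/θ is positive) and H2 (the remainder
G* = AZ − G(X,Z) evaluated at the tumor-free state is nonnegative).
Estrogen-free: G* = −β₂T* = 0, so the tumor-free state is the
globally stable one.  With estrogen: G* = −(β₂T + σ₂HE) < 0 whenever
π > 0 — no parameter adjustment restores global stability while
estrogen is sourced.  The growth rate entering A is α₃ by default
(consistent with the implemented field); the published α₂ variant is
available as `growth_rate_option="alpha2_as_printed"` and does not
change any verdict.

The published claim that the estrogen tumor-free state is *always*
locally unstable rests on the non-Jacobian coefficient above; over
random valid parameter draws the Jacobian frequently has a strictly
negative spectrum there.  The claim is therefore a *monitored*
invariant (`monitor_tumor_free_instability`): violations are counted
and reported, never asserted away.

## Simulation and outcomes

Integration uses adaptive RK45 with rtol 1e-8 / atol 1e-10, at least
201 saved points, default horizons of 200 days (estrogen-free) and
100 days (estrogen) — at least ten multiples of the slowest canonical
rate.  Negative values are never clipped: undershoot beyond −1e-8 is
an error (clipping would mask field or solver bugs); smaller
undershoot is tolerated and recorded in the trajectory's warnings.
Outcomes are labeled by terminal-state proximity (relative tolerance
1e-3) to the feasible equilibria with precedence tumor_clearance >
host_extinction > coexistence > tumor_escape > undecided; clearance
additionally requires terminal T < 1e-6, and escape requires the
terminal burden to exceed every feasible equilibrium's with
dT/dt ≥ 0 at the horizon.

## Dose sweep and boundaries

The sweep re-solves equilibria, the tumor-free linearisation and a
full simulation at each π, using terminal values at the fixed horizon
rather than asymptotics (escape trajectories need not converge).
At the default conditions the runs do converge — terminal states sit
on the coexisting branch to ~1e-6 — and the dose response is: host
strictly decreasing in π; tumor burden rising steeply, peaking near
π = 0.8, then easing as host depletion starves the σ₂HE influx;
immune level unimodal (tumor-stimulated recruitment lifts it before
estrogen suppression wins).  The frequently-stated three-way
monotonicity (tumor up, host and immune down) therefore holds only
piecewise at these defaults, and `SweepResult` exposes the three
monotonicity flags explicitly.  Stability boundaries are located by
bisection on the leading tumor-free eigenvalue to a bracket of 1e-8;
for α₂ in the estrogen-free model the result reproduces the closed
form α₂ = sγ₂/μ.

On the default grid π ∈ [0, 1] the steady estrogen level π/θ ≤ 1.03
stays below the existence bound α₁/σ₁ = 2.33, so the tumor-free
existence flag does not flip there (the flip would require
π > θα₁/σ₁ ≈ 2.26); boundary lists are empty unless the grid crosses
a sign change.

## Synthetic data and recovery

Parameter sets are drawn uniformly and independently per rate from
intervals of ±20% around the canonical values, rejection-sampled
(budget 1000) against the validity constraints.  Observations are
tight-tolerance (rtol 1e-10) forward simulations on 41 equally spaced
times over (0, t_end] plus additive Gaussian noise truncated at zero —
the simplest observation model consistent with nonnegative densities;
no published data model exists.  The default recovery scenario starts
the tumor at T(0) = 0.1 rather than the near-extinct 1e-5: a
vanishing tumor leaves no signature of α₂ or γ₂ in the trajectory, so
nothing could be recovered from it.  Recovery is bounded local least
squares (scipy trf) over ≤ 3 free parameters from a supplied initial
guess; no global search is attempted, and full 11-parameter fits are
deliberately out of scope (known sloppiness).

What the synthetic data do **not** emulate: measurement processes of
real tumor burden (imaging resolution, detection thresholds),
inter-patient parameter heterogeneity, and model misspecification —
observations come from the same vector field that is fitted.  Passing
recovery tests therefore demonstrate identifiability and optimizer
correctness under the stated noise model, not clinical estimability.

## Numerical choices

* equilibrium residual gate 1e-10 (scaled), coordinate nonnegativity
  tolerance 1e-12, root scan 2001 points with Brent refinement at
  xtol 1e-12, duplicate roots merged below 1e-9;
* eigenvalue marginality band 1e-9; boundary bisection bracket 1e-8;
* solver rtol 1e-8 / atol 1e-10 (1e-10/1e-12 for synthetic truth);
  undershoot tolerance 1e-8; clearance threshold 1e-6; equilibrium
  match tolerance 1e-3 (relative);
* least-squares xtol/ftol/gtol 1e-12, default bounds [truth/5,
  truth·5] clipped into the valid region.

## Known limitations

No delay terms, spatial structure, treatment terms, stochastic or
event-driven dynamics; no Lyapunov construction or center-manifold
analysis at marginal points; no continuation of equilibria across
parameters (the sweep re-solves per grid point); recovery offers no
Bayesian uncertainty, only point estimates.  The published figures
for the estrogen model cannot be reproduced point-for-point because
the estrogen-specific parameter values behind them were never
printed; all estrogen-model quantitative results here are stated at
the package defaults above.
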