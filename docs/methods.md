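# Methods

## Model

A plant is a biochemical reaction network (X, S, λ): L species, K reactions
with integer stoichiometry columns ζ_k and nonnegative propensities λ_k. A
controller is a second network over species Z₁..Z_M that may read only the
plant output X_L and act only on the plant input X₁; composition stacks the
stoichiometry blocks (S₁ for the input row, S_L for the output row, S_c for
controller species). One network object carries both interpretations —
deterministic concentrations (dx/dt = S·λ(x)) and stochastic copy numbers
(CTMC with the same propensities). All reactions here are at most bimolecular
between distinct species, so the two readings share propensity formulas.
Units are arbitrary concentration units with per-hour rates; this is a
convention, not an enforcement.

Propensities come from a closed factor vocabulary — linear (x^p), Hill
activation/repression ((x/κ)ⁿ terms), and Michaelis saturation (x/(x+κ)) —
multiplied by a rate constant. Every consumed species must appear through a
factor that vanishes at zero, which guarantees nonnegativity of both the ODE
flow and the jump chain. Factors carry exact derivatives, so every
linearization in the package is analytic; finite differences appear only in
tests, as an independent check.

## Controller library

All topologies share the antithetic integral core (reference g(μ,x_L)→Z₁,
sensing θ·x_L→Z₂, annihilation η·z₁z₂, actuation h = h⁺ − h⁻ on X₁). The
canonical proportional mechanisms are, for Class 1 (output inhibits input):
additive h⁺ = k·z₁ + α/(1+(x_L/κ)ⁿ); multiplicative h⁺ = k·z₁/(1+(x_L/κ)ⁿ);
degradation h⁻ = δ·x_L·x₁/(x₁+κ₁). Class 2 replaces x_L by z₂ in the
inhibition; Class 3 moves the inhibition into the reference (multiplicative
g = μ/(1+(x_L/κ)ⁿ), additive g = μ + α/(1+(x_L/κ)ⁿ)); Class 3 with
degradation would break adaptation and is rejected at validation. Setpoints
solve g(μ, x̄) = θ·x̄: μ/θ for affine references, μ/(θ−β) for the order-2
aPID (requiring β < θ), the positive root of a degree-(n+1) polynomial for
Class 3 (unique because g decreases in x_L; solved by bracketing).

Derivative action:

* **order 2** — one added reaction, X_L →^{β} X_L + Z₁, turning the Z₁
  channel into an inseparable low-pass-filtered PID (its filter pole is the
  sequestration pole η(z̄₁+z̄₂), so its effective K_D is only substantial at
  moderate η — which is exactly the regime the pole-placement design picks).
* **order 3** — an incoherent feedforward loop: X_L →^{α₀} Z₃, Z₃ →^{γ₀} ∅,
  with Z₃ activating X₁ at δ₀·z₃ while the aPI's direct arm degrades X₁ at
  δ. The exact linearization gives K_Dω = δ₀α₀/γ₀, ω = γ₀ and
  K_P = δ_eff − K_Dω with δ_eff = δ·x̄₁/(x̄₁+κ₁). Because δ_eff ≤ δ, the
  validated region δ·γ₀ ≤ 2·δ₀·α₀ makes the coverage constraint
  K_P ≤ K_D·ω structural for every accepted spec;
  negative K_P (down to −K_Dω) comes for free, without rewiring.
* **order 4** — an antithetic differentiator: ∅→^{μ₀}Z₃, Z₃+Z₄→^{η₀}∅, and a
  mutual reaction producing Z₄ while acting on X₁ at rate g(z₃,x_L)
  (canonically k₀·z₃·x_L for the degradation variant). Because the same rate
  g both drains the inner integrator and actuates, the linearized channel is
  an exactly pure filtered derivative: u_D(s) = g_x·s/(s+ω)·x_L(s) with
  ω = k₀·x̄_L, K_D = μ₀/(k₀·x̄_L²). The four gains decouple
  (K_P = δ_eff, K_I ≈ k·θ, K_D, ω), which is why the inverse design map is
  essentially closed-form for this order.
* **alternative differentiators** — the same integrator-in-self-feedback
  trick with zero-order (inflow/outflow, Michaelis constant κ₀) or
  saturating autocatalytic integrators. A pure filtered derivative requires
  the non-feedback flux to be zero-order in Z₃; operating outside the
  saturating regime κ₀ ≪ z̄₃ leaves a proportional leakage of size
  ~μ₀κ₀/z̄₃², which is why the frequency-response contract is stated in that
  regime. The autocatalytic variant's self-production vanishes at z₃ = 0, so
  z₃(0) > 0 is required and validated.

N-type/P-type is a per-component sign flag (i_sign/p_sign/d_sign) flipping
each actuation between production and Michaelis degradation, enabling hybrid
designs.

## Deterministic and linear analysis

Integration uses LSODA with the analytic Jacobian (rtol 1e−8, atol 1e−10
defaults; η up to 1e6 makes the loops stiff); scheduled rate steps restart
the integrator. Settling is defined as final entry into a ±2% band around
the setpoint (band configurable), rise time as 10→90%, and the performance
index J = overshoot/100 + settling/T_ref + rise/T_ref with a +10 penalty for
unsettled responses — the index formula is a package convention; sweeps also
expose the raw metrics.

Stability verdicts come from the exact Jacobian at the fixed point. For
chain plants the fixed point is computed analytically (output = setpoint,
chain profile backwards, Z₁ from the input balance by bracketed
root-finding); the generic path seeds a damped Newton solve from a long
integration. Routh–Hurwitz uses the standard array with ε-perturbation;
marginal cases (zero pivots / all-zero rows) are reported unstable with a
flag.

In the fast-sequestration limit the gene-expression closed loop reduces to a
cubic with characteristic polynomial s³+(a+γ₂)s²+(aγ₂+bk₁)s+θk₁h_z₁, where
a = γ₁−∂h/∂x₁ and b = −∂h/∂x_L, giving the closed-form verdicts: ρ < 1 for
aI and Class 2; ρ < 1 + k₁b/γ₁γ₂ with α < α_TH = (γ₁γ₂/k₁)r(1+(r/κ)ⁿ) for
Class-1 additive; bounds never below 1 for multiplicative/degradation; and a
bound strictly below 1 for Class 3. Two limit-order subtleties matter and
are handled explicitly:

* the supremum of stabilizable ρ for the additive mechanism is
  1 + n·q/(1+q) ≤ 1+n (q = (r/κ)ⁿ); the classical boundary value 2 is the
  Hill-1 case. At any *fixed* finite η, α close enough to α_TH drives
  z̄₁ → 0, exits the fast-sequestration regime (z̄₂ ≫ z̄₁) and stabilizes
  arbitrarily large ρ; `additive_rho_supremum` therefore realizes the
  η→∞ limit by raising η per operating point until z̄₂ ≪ z̄₁.
* the root-locus asymptote of the degradation aPI (complex pair →
  −(γ₁+γ₂)/2 as δ grows, one real pole → 0⁻) presumes the input degradation
  stays saturated, i.e. δ·κ₁·r/x̄₁² ≪ γ₁ along the sweep; the fixture for
  the asymptote study uses a small k₁ (large x̄₁) so the regime holds up to
  δ = 1e6 with κ₁ = 1e−3.

PID gains are extracted from the exact linearization of the controller
subsystem (plant input frozen at its stationary value): the transfer from an
output perturbation to the net actuation is expanded in partial fractions;
the structurally exact origin pole of the antithetic pair gives K_I, the
slowest nonzero pole gives ω and K_D, the direct term plus the remaining
residues give K_P. Supplementary closed forms are deliberately not
transcribed as the implementation — where simple limits exist (K_P → δ for
small κ₁, K_I → kθ, the order-4 formulas above) they serve as cross-checks
in tests. The inverse map seeds from those limits and polishes with damped
least squares to 1e−6 relative on re-extraction.

Quadruple pole placement at s = −a matches the exact closed-loop quartic
(order 2: the 4-state loop itself, with the saturated-degradation
approximation; orders 3–4: the reduced large-η quartic) coefficient by
coefficient. For order 2 the matching plus positivity constraints reduce to
the solvability of a quadratic in t = θ·k, which fails precisely beyond
a = (2+√2)(γ₁+γ₂)/2 — the implementation reports infeasibility from the
matching equations, and the closed-form bound is an independent check.
Orders 3 and 4 remain feasible at any depth (verified at 10× the order-2
bound). A quadruple root splits like ε^{1/4} under coefficient perturbation,
so verified poles at large a scatter by tens of percent around −a while
remaining deep in the left-half plane; verification asserts depth, not exact
multiplicity.

## Stochastic analysis

SSA is the direct method, compiled with numba from the same propensity
tables; one seeded stream per trajectory. Stationary moments are
time-weighted (holding times), pooled across trajectories, with batch-means
standard errors; an accumulator kernel supports long ensembles without
storing paths. The moment-closure variance for Class-1 aPI loops closes the
CME moment hierarchy by linearizing every non-affine propensity (the
bilinear sequestration and the Hill/Michaelis terms) about the stationary
mean, reducing the stationary second moments to a Lyapunov equation at the
fixed point; it is validated against SSA (within 15% for the degradation and
multiplicative mechanisms away from the stability boundary — the additive
mechanism near α_TH is genuinely less accurate, and ergodicity loss at
α ≥ α_TH is flagged rather than silently returned). PSDs are mean-removed,
Hann-windowed periodograms averaged across cells, with the peak detector
reporting prominence relative to the median spectral level.

The stochastic study conditions mirror the deterministic setpoint r = μ/θ =
5 with unit plant rates and a moderate sequestration rate (η = 10), where
copy numbers are tens of molecules. Under these conditions degradation
inhibition pushes the output variance below the Poisson level (below the
mean 5), multiplicative saturates slightly above it, and additive inhibition
at 80% of α_TH is the strongest ergodic setting of its mechanism — the
ordering degradation < multiplicative < additive is asserted with SSA at
those settings.

## Hybrid sampled loop

The in-silico controller network is the compiled controller fragment with
actuation rerouted into an intensity species X₀ (first-order decay, default
rate 1) and the sensed output replaced by a measurement slot frozen over
each sampling interval (zero-order hold, default 2 time units). The plant —
an independent SSA instance per cell, or a replayed uniformly-sampled CSV —
receives the intensity as a zero-order input production held over the
interval. The exact reaction set linking the actuation species to the
controller in the experimental platform is not reproduced here; this routing
is the package's default and is pluggable.

## Synthetic plants

`gene_expression_plant` is the two-species mRNA/protein module used in all
threshold studies. `chain_feedback_plant` builds L-species cascades with an
optional degradation of X₂ by the output: bilinear (γ_F·x₂·x_L) by default,
or substrate-saturated (γ_F·x_L·x₂/(x₂+κ_F)) — the bilinear form can never
destabilize the open loop (its DC loop gain is γ_F·x̄_L-limited below 1 at
any rates), so the unstable six-species fixture uses the saturated,
protease-like form with uniform k = 1, γ = 0.5, γ_F = 1, κ_F = 0.01, chosen
once so the open loop oscillates and no integral-only gain stabilizes it.
`random_plant` draws log-uniform chain rates from a seed for the adaptation
property tests. What the generator does *not* emulate: transcriptional
bursting, cell division/dilution of controller species, delays, and
extrinsic noise — passing tests therefore certify the controller machinery
on well-mixed mass-action/Hill kinetics, not those effects.

## Numerical choices and limitations

Verdict tolerance: an eigenvalue is "unstable" when its real part exceeds
1e−9 times its own magnitude (scaling by the dominant mode, not the fast
sequestration mode, matters at η = 1e6). Fixed-point residual tolerance is
1e−8 relative to the propensity scale; setpoint roots are bracketed to
machine precision. Root-locus branches are matched between grid points by
nearest-neighbour assignment, which can mislabel branches at locus
collisions. Problem sizes used throughout the suite (ensembles of 16–100
trajectories of a few hundred time units, grids of tens of points) are
chosen to give 3-sigma margins at desk scale. The SSA guards against rate
blow-up (total propensity > 1e12 aborts with an error). Known limitations:
no delays or compartments; no dilution of controller species; the Class-2
additive regime where Z₂ takes over the integral action is detected and
warned about, not analyzed; SBML export is not provided (the Hill/Michaelis
composites map awkwardly onto SBML kinetic laws and nothing downstream needs
it).
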