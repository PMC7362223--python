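# Methods

## Model and scope

`saosfit` treats a material as a linear viscoelastic network of springs
(Hookean, σ = Eε) and dashpots (Newtonian, σ = ηε̇).  Any such network
obeys a linear constitutive differential equation; written in σ-form it
expresses the stress as a combination of main effects drawn from
{ε, ε̇, ε̈, σ̇, σ̈}.  The registered catalogue:

| model | σ-form terms | parameters | behaviour |
|---|---|---|---|
| spring | ε | E | elastic solid |
| dashpot | ε̇ | η | Newtonian liquid |
| Maxwell | ε̇, σ̇ | E, η | viscoelastic liquid, non-recoverable flow |
| Kelvin–Voigt | ε, ε̇ | E, η | viscoelastic solid, full recovery |
| Zener (K and M forms) | ε, ε̇, σ̇ | E₁, E₂, η | standard linear solid |
| Lethersich / Jeffreys | ε̇, ε̈, σ̇ | E, η₁, η₂ | three-element liquids |
| Burgers | ε̇, ε̈, σ̇, σ̈ | E₁, E₂, η₁, η₂ | Maxwell + Kelvin–Voigt in series |

The two Zener variants share one σ-form structure, as do Lethersich and
Jeffreys: members of such a *degeneracy class* produce identical
regression problems and are only alternative parameterizations of the
same response.  Fits are therefore performed once per class and reported
with every member's parameterization.  Everything is restricted to the
linear (small-amplitude) regime; large-amplitude, fractional-derivative
and nonlinear constitutive laws are out of scope, as are instrument
geometry corrections (inputs are the already-reduced moduli).

## Signal reconstruction

For ε(t) = ε̃ sin(ωt), the measured moduli determine the stress
σ(t) = G′ε̃ sin(ωt) + G″ε̃ cos(ωt) and all derivatives analytically;
finite differences are never used, so the identities ε̈ = −ω²ε and
σ̈ = −ω²σ hold to machine precision row by row.  One period per
frequency is sampled at t_ij = i·(2π/ω_j)/n, i = 0…n−1, default
n = 10 (configurable, minimum 4; below that the in-phase and quadrature
components are sampled without redundancy).  The phase offset is fixed
at zero: for full-period sampling all regression quantities are
phase-invariant.  The strain amplitude ε̃ defaults to 1 when unknown —
response and regressors scale linearly in ε̃, so coefficients, R² and
inverted parameters are unaffected; only absolute stress scales change.

## Regression and model choice

Coefficients are estimated by least squares *through the origin* over
all frequencies jointly (the σ-form is homogeneous; an intercept is
physically meaningless and would absorb signal), solved by QR
decomposition with a condition-number report (warning above 1e8 — the
ε̇/ε̈ columns differ by ω factors spanning decades, so conditioning is
the practical failure mode).  Because the regression has no intercept,
R² is the uncentered 1 − SSR/Σσ², and adj R² = 1 − (1 − R²)(n−1)/(n−p);
noise-free data give 1 under any convention.  Coefficient covariance is
s²(XᵀX)⁻¹ with s² = SSR/(n − p).

Rows are equally weighted by default.  High-frequency rows carry larger
stresses and dominate the objective; an optional per-frequency
normalization (dividing each frequency's rows by ε̃√(G′²+G″²)) is
provided but off by default, since weighting changes estimates only
under model misspecification.

Model ranking is by adjusted R² per degeneracy class, with a parsimony
rule: any class within `tie_tolerance` (default 0.002) of the best
adjusted R² and with fewer elements is preferred; residual SD breaks
remaining ties.  The tolerance reflects that adjusted-R² differences of
a few 10⁻³ are not decisive on their own and the simpler model should
win such comparisons; residual-distribution width (`residual_summary`)
is the finer diagnostic.  Information criteria (AIC/BIC) are
deliberately not used — the selection criteria here are adjusted R²,
parsimony and residual width.

Models containing ε̈ or σ̈ require at least three distinct frequencies:
at a single frequency ε̈ ∝ ε and σ̈ ∝ σ, making the design singular
(this is reported as a collinearity error naming the cause).

## Parameter inversion and uncertainty

Each model's K → parameter inverse is closed-form, derived by
coefficient comparison with its σ-form.  For Burgers: η₁ = K₁,
E₁ = −K₂/K₄, E₂ = K₁/(−K₃ − K₁/E₁ − K₂/K₁), η₂ = K₂E₂/K₁.  All inverses
are validated by round-trip property tests against the forward maps
(forward-then-invert is the identity to ≲1e−13 over 10⁻¹–10² parameter
ranges) rather than trusted as transcriptions.  Standard errors
propagate from the OLS coefficient covariance by first-order delta
method with a central-difference Jacobian (step 1e−7 relative); a
residual-bootstrap alternative (`bootstrap_parameters`) is available.
Negative inverted parameters are flagged (`physical = False`) but always
reported: a wrong sign is diagnostic evidence against the model, not a
numerical failure.  Coefficients that must be non-zero (e.g. Burgers K₄)
raise a degeneracy error naming the nested simpler model when they
vanish numerically (|K| ≤ 1e−12 × the coefficient scale).

Characteristic-time uncertainties (τ₁ = η₁/E₁, τ₂ = η₂/E₂) and condition
ratios neglect cross-covariances between inverted parameters, which the
parameter container does not carry; with the small relative errors
typical here the first-order independent-error formula is adequate.
Ratios between conditions are also expressed as ratio × 100 rounded to
the nearest percent (a 4.18× change reads as 418%).

## Synthetic data

The generator produces sweeps from any registered model's exact complex
modulus G*(ω) (σ-form under d/dt → iω) on a default grid of 20
log-spaced frequencies over 0.1–100 rad/s — the standard three-decade
window for gels and solutions, capped where machine inertia corrupts
real measurements.  Noise is multiplicative Gaussian on G′ and G″
independently (instrument error scales with signal); strut series get
additive Gaussian noise (optical diameter error is roughly constant).
Default parameter scales in tests and examples follow values identified
for alginate inks: moduli of order 500–700 Pa, viscosities of order
10 Pa·s, hence relaxation times near 0.016 s — with ωτ ≤ ~2 across the
sweep.  Materials whose relaxation times are much longer than 1/ω_min
push the regression into a near-cancellation between the large σ̇/σ̈
terms, where even 1% modulus noise degrades coefficient recovery; this
is an intrinsic sensitivity of the σ-form regression at deep-plateau
conditions, and the condition-number warning flags it.

What the generator does *not* emulate: per-frequency amplitude
adjustment in controlled-stress instruments (one global ε̃ only),
machine-inertia artifacts, wall slip, drying, and any nonlinearity.
Passing tests on synthetic sweeps therefore demonstrate correctness of
the identification machinery under the stated noise model, not
robustness to every instrument artifact.

## Nonlinear fits

Concentration scaling value(c) = prefactor·(1 + c/c̃)^exponent and
spreading kinetics d(t) = A[1 − e^{−(t+t₀)/τ_s}] use
Levenberg–Marquardt least squares with deterministic, data-driven
starting values: for scaling, the prefactor from the smallest value, c̃
from where the data first exceed 10× the prefactor, the exponent from a
log–log slope; for spreading, A at 1.05× the observed maximum and
(t₀, τ_s) from the log-linearization ln(1 − d/A) = −(t + t₀)/τ_s, which
stays informative when the first measured diameter is already a large
fraction of the plateau.  Any subset of the scaling parameters can be
fixed (e.g. solvent viscosity 0.001 Pa·s, or exponent 3 per isotropic
scaling theory); the fixed-exponent fit is nested in the free fit, so
its residual sum can never be smaller.  Spreading fits require ≥ 4
points and a series within 60% of its plateau (otherwise A is
unconstrained), and only t + t₀ enters the model — a joint shift of
clock and delay is a documented non-identifiability.  Concentration is
treated as a raw number with the caller's unit; no unit conversion is
attempted.

## Problem sizes

Default test and acceptance runs use 20-frequency sweeps (200 regression
rows), 50–100 random parameter sets per model for round-trip and
recovery properties, 50 seeds for the noisy model-selection rate, and
50-point spreading series — sizes at which every quantity is stable to
well inside its test tolerance while the whole suite runs in seconds.

## Known limitations

* Degeneracy classes are fundamental, not numerical: no amount of SAOS
  data distinguishes the two Zener forms or Lethersich from Jeffreys.
* The regression propagates modulus noise into both the response and the
  design columns (errors-in-variables); at 1% noise and gel-scale
  parameters the bias is below a few percent, but it grows at
  deep-plateau conditions (see Synthetic data).
* A single global strain amplitude is assumed; sweeps recorded with
  per-frequency amplitude adjustment lose only absolute stress scale,
  not identifiability.
* YAML-declared custom models define design columns for fitting, but no
  closed-form parameter inversion is synthesized for them.
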