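# saosfit

Identify a material's linear viscoelastic constitutive equation directly
from ordinary frequency-sweep data.

Oscillatory (SAOS) frequency sweeps — storage modulus G′(ω) and loss
modulus G″(ω) over two to three decades of angular frequency — are the
most widely available rheological characterization for polymer solutions,
melts, gels and bioinks.  `saosfit` turns such a sweep into a
constitutive model: it reconstructs the periodic stress and strain
signals and their exact time derivatives, benchmarks the canonical
spring–dashpot networks (spring, dashpot, Maxwell, Kelvin–Voigt, both
Zener variants, Lethersich/Jeffreys, Burgers) by intercept-free linear
regression, and inverts the regression coefficients into spring moduli
E (Pa) and dashpot viscosities η (Pa·s).  Application layers derive the
Cox–Merz flow curve, quasi-power-law concentration scaling of the fitted
parameters, and the strut-spreading kinetics that govern shape fidelity
in extrusion bioprinting.

It is written for rheologists and biofabrication researchers who have
frequency-sweep exports (CSV/TSV) and want model parameters without
running stress-relaxation or creep experiments.

## Method

For a strain-controlled oscillation ε(t) = ε̃ sin(ωt), the linear
response is σ(t) = G′ε̃ sin(ωt) + G″ε̃ cos(ωt).  Sampling one period at
n = 10 points per frequency (t_ij = i·(2π/ω_j)/n) and differentiating
analytically gives, for each frequency, exact rows of
(ε, ε̇, ε̈, σ, σ̇, σ̈).  Every linear spring–dashpot network obeys a
homogeneous constitutive equation

    σ = K₁·x₁ + K₂·x₂ + …,   x_m ∈ {ε, ε̇, ε̈, σ̇, σ̈},

so the coefficients K are estimated by least squares through the origin
over all frequencies jointly, and goodness of fit uses the uncentered
R² = 1 − SSR/Σσ² with adj R² = 1 − (1 − R²)(n − 1)/(n − p).  For the
four-parameter Burgers model (Maxwell + Kelvin–Voigt in series),

    K₁ = η₁,  K₂ = η₁η₂/E₂,
    K₃ = −(E₁η₁ + E₁η₂ + E₂η₁)/(E₁E₂),  K₄ = −η₁η₂/(E₁E₂),

inverted in closed form (η₁ = K₁, E₁ = −K₂/K₄, …) with delta-method
standard errors.  Each model's complex modulus G*(ω) follows from its
σ-form by d/dt → iω, which powers both the synthetic-sweep generator and
round-trip validation of every inversion.  Characteristic times
τ₁ = η₁/E₁ (Maxwell part) and τ₂ = η₂/E₂ (Kelvin–Voigt part) connect the
fit to printability: the spreading time of a printed strut,
d(t) = A[1 − e^{−(t+t₀)/τ_s}], scales with τ₁ across ink formulations.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import saosfit as sf

truth = {"E1": 697.69, "E2": 511.27, "eta1": 11.07, "eta2": 8.38}
burgers = sf.get_model("burgers")
sweep = sf.generate_sweep(burgers, truth, noise=sf.NoiseSpec(0.01, seed=42))

ranking = sf.benchmark_models(sf.reconstruct(sweep))
print(ranking.selected)                      # burgers
res = ranking.results["burgers"]
params = sf.invert_parameters(burgers, res.k, res.k_covariance)
print(params.estimates)
```

Running `python examples/01_identify_model_from_sweep.py` (the full
version of the snippet) prints:

```
model applicability (adjusted R², higher is better):
  burgers                 0.9995   (4 elements)
  lethersich_jeffreys     0.9760   (3 elements)
  zener                   0.9507   (3 elements)
  maxwell                 0.9448   (2 elements)
  ...
selected: burgers

inverted Burgers parameters (truth in brackets):
  E1 =    706.19 ± 1.74 Pa   [697.69]
  E2 =    507.96 ± 2.40 Pa   [511.27]
  eta1 =     11.16 ± 0.03 Pa·s   [11.07]
  eta2 =      8.25 ± 0.03 Pa·s   [8.38]

characteristic times: tau1 = 0.0158 s (Maxwell part, flow), tau2 = 0.0162 s ...
```

The Burgers class tops the ranking, every inverted parameter lands within
~1.5% of the generating value despite 1% modulus noise, and the Maxwell
characteristic time τ₁ ≈ 0.016 s is the quantity that tracks strut
spreading.  The other examples cover the Cox–Merz flow curve,
concentration scaling and spreading kinetics.

A thin CLI wraps the same calls:

```bash
saosfit simulate burgers --params E1=697.69,E2=511.27,eta1=11.07,eta2=8.38 \
        --noise 0.01 --seed 42 --out sweep.csv
saosfit fit sweep.csv --report out/
saosfit spreading struts.csv
```

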