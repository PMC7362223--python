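"""Catalogue of linear spring–dashpot constitutive models.

Every model here obeys a linear differential equation relating stress and
strain, written in "σ-form" with the stress isolated on the left:

    σ = K₁·term₁ + K₂·term₂ + …         terms ⊂ {ε, ε̇, ε̈, σ̇, σ̈}

The regression coefficients K carry the model's material parameters
(spring moduli E in Pa, dashpot viscosities η in Pa·s) through fixed
algebraic combinations.  Each registry entry therefore bundles:

* the ordered main-effect terms (the regression design columns),
* the forward map parameters → K (coefficient comparison with the σ-form),
* the closed-form inverse K → parameters,
* a degeneracy class: the two Zener variants share one σ-form structure,
  as do Lethersich and Jeffreys, so the members of a class cannot be
  distinguished by regression — only re-parameterized.

The complex modulus follows from the σ-form by the harmonic substitution
d/dt → iω.  Splitting terms into strain-side (orders s) and stress-side
(orders r):

    G*(ω) = Σ_strain K·(iω)^s  /  (1 − Σ_stress K·(iω)^r)

which gives G' = Re G*, G'' = Im G* — the forward simulator used to
generate synthetic sweeps and to verify inversions by round trip.

The four-parameter Burgers model (Maxwell and Kelvin–Voigt in series;
σ = K₁ε̇ + K₂ε̈ + K₃σ̇ + K₄σ̈) is the workhorse for polymer solutions:

    K₁ = η₁,  K₂ = η₁η₂/E₂,
    K₃ = −(E₁η₁ + E₁η₂ + E₂η₁)/(E₁E₂),  K₄ = −η₁η₂/(E₁E₂)

inverted as η₁ = K₁, E₁ = −K₂/K₄, E₂ = K₁/(−K₃ − K₁/E₁ − K₂/K₁),
η₂ = K₂E₂/K₁.  The inverse is validated by round-trip property tests
against the forward map rather than trusted as transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .sweeps import FrequencySweep

__all__ = [
    "ConstitutiveModel",
    "MaterialParameters",
    "DegenerateModelError",
    "NonPhysicalParameterError",
    "REGISTRY",
    "TERM_ORDER",
    "get_model",
    "degeneracy_classes",
    "design_terms",
    "forward_coefficients",
    "complex_modulus",
    "forward_moduli",
    "invert_parameters",
    "registry_to_yaml",
    "registry_from_yaml",
]

# canonical main-effect ordering and the d/dt order of each term
TERM_ORDER = ("epsilon", "epsilon_dot", "epsilon_ddot", "sigma_dot", "sigma_ddot")
_DERIV_ORDER = {"epsilon": 0, "epsilon_dot": 1, "epsilon_ddot": 2,
                "sigma_dot": 1, "sigma_ddot": 2}
_STRAIN_TERMS = frozenset(("epsilon", "epsilon_dot", "epsilon_ddot"))


class DegenerateModelError(ValueError):
    """A coefficient that must be non-zero is (numerically) zero, so the
    model collapses onto a nested simpler one."""


class NonPhysicalParameterError(ValueError):
    """Material parameters must be strictly positive for a forward model."""


@dataclass(frozen=True)
class ConstitutiveModel:
    """A spring–dashpot network with a linear constitutive equation."""

    name: str
    terms: tuple[str, ...]
    param_names: tuple[str, ...]
    degeneracy_class: str
    description: str = ""
    # forward: parameter vector -> K vector; inverse: K vector -> parameters.
    # Fit-only models (declared from YAML) leave these as None.
    _k_from_params: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False)
    _params_from_k: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False)

    def __post_init__(self) -> None:
        unknown = set(self.terms) - set(TERM_ORDER)
        if unknown:
            raise ValueError(f"unknown main-effect terms: {sorted(unknown)}")

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def invertible(self) -> bool:
        return self._params_from_k is not None

    def k_from_params(self, params: np.ndarray) -> np.ndarray:
        if self._k_from_params is None:
            raise NotImplementedError(
                f"model {self.name!r} is fit-only (no parameter map declared)")
        return np.asarray(self._k_from_params(np.asarray(params, float)), float)

    def params_from_k(self, k: np.ndarray) -> np.ndarray:
        if self._params_from_k is None:
            raise NotImplementedError(
                f"model {self.name!r} is fit-only (no parameter map declared)")
        return np.asarray(self._params_from_k(np.asarray(k, float)), float)


@dataclass(frozen=True)
class MaterialParameters:
    """Inverted material parameters with delta-method standard errors.

    ``physical`` is True iff every estimate is strictly positive; negative
    estimates are reported, not suppressed — an unphysical sign is itself
    a diagnostic that the model does not describe the material.
    """

    model_name: str
    values: dict[str, tuple[float, float]]   # symbol -> (estimate, std error)
    physical: bool

    def estimate(self, symbol: str) -> float:
        return self.values[symbol][0]

    def stderr(self, symbol: str) -> float:
        return self.values[symbol][1]

    @property
    def estimates(self) -> dict[str, float]:
        return {k: v[0] for k, v in self.values.items()}

    def as_array(self) -> np.ndarray:
        return np.array([v[0] for v in self.values.values()])


# --- forward K maps and closed-form inversions ------------------------------

def _check_degenerate(value: float, scale: float, model: str, suggest: str,
                      what: str) -> None:
    if abs(value) <= 1e-12 * max(scale, 1e-300):
        raise DegenerateModelError(
            f"{model}: {what} is numerically zero — the fit degenerates; "
            f"consider the nested {suggest} model"
        )


def _burgers_k(p: np.ndarray) -> np.ndarray:
    e1, e2, n1, n2 = p
    return np.array([
        n1,
        n1 * n2 / e2,
        -(e1 * n1 + e1 * n2 + e2 * n1) / (e1 * e2),
        -n1 * n2 / (e1 * e2),
    ])


def _burgers_p(k: np.ndarray) -> np.ndarray:
    k1, k2, k3, k4 = k
    scale = np.max(np.abs(k))
    _check_degenerate(k4, scale, "burgers", "zener / lethersich-jeffreys", "K4")
    _check_degenerate(k1, scale, "burgers", "kelvin-voigt", "K1")
    n1 = k1
    e1 = -k2 / k4
    denom = -k3 - k1 / e1 - k2 / k1
    _check_degenerate(denom, scale, "burgers", "maxwell", "the E2 denominator")
    e2 = k1 / denom
    n2 = k2 * e2 / k1
    return np.array([e1, e2, n1, n2])


def _maxwell_p(k: np.ndarray) -> np.ndarray:
    k1, k2 = k
    _check_degenerate(k2, np.max(np.abs(k)), "maxwell", "dashpot", "K2")
    return np.array([-k1 / k2, k1])          # (E, eta)


def _zener_k_p(k: np.ndarray) -> np.ndarray:
    k1, k2, k3 = k
    scale = np.max(np.abs(k))
    _check_degenerate(k3, scale, "zener_k", "kelvin-voigt", "K3")
    e2 = -k2 / k3
    _check_degenerate(e2 - k1, scale, "zener_k", "spring", "E2 - K1")
    e1 = k1 * e2 / (e2 - k1)
    eta = -k3 * (e1 + e2)
    return np.array([e1, e2, eta])


def _zener_m_p(k: np.ndarray) -> np.ndarray:
    k1, k2, k3 = k
    _check_degenerate(k3, np.max(np.abs(k)), "zener_m", "kelvin-voigt", "K3")
    e2 = k1
    eta = k2 + k1 * k3
    e1 = -eta / k3
    return np.array([e1, e2, eta])


def _lethersich_p(k: np.ndarray) -> np.ndarray:
    k1, k2, k3 = k
    scale = np.max(np.abs(k))
    denom = -k1 * k3 - k2
    _check_degenerate(denom, scale * max(scale, 1.0), "lethersich",
                      "maxwell", "-K1*K3 - K2")
    n2 = k1
    e = k1 * k1 / denom
    n1 = k2 * e / k1
    return np.array([e, n1, n2])


def _jeffreys_p(k: np.ndarray) -> np.ndarray:
    k1, k2, k3 = k
    _check_degenerate(k3, np.max(np.abs(k)), "jeffreys", "dashpot", "K3")
    n2 = -k2 / k3
    n1 = k1 - n2
    e = -n1 / k3
    return np.array([e, n1, n2])


def _build_registry() -> dict[str, ConstitutiveModel]:
    m = [
        ConstitutiveModel(
            "spring", ("epsilon",), ("E",), "spring",
            "Hookean solid: σ = Eε",
            lambda p: p.copy(), lambda k: k.copy()),
        ConstitutiveModel(
            "dashpot", ("epsilon_dot",), ("eta",), "dashpot",
            "Newtonian liquid: σ = ηε̇",
            lambda p: p.copy(), lambda k: k.copy()),
        ConstitutiveModel(
            "maxwell", ("epsilon_dot", "sigma_dot"), ("E", "eta"), "maxwell",
            "spring and dashpot in series: σ = ηε̇ − (η/E)σ̇",
            lambda p: np.array([p[1], -p[1] / p[0]]), _maxwell_p),
        ConstitutiveModel(
            "kelvin_voigt", ("epsilon", "epsilon_dot"), ("E", "eta"),
            "kelvin_voigt",
            "spring and dashpot in parallel: σ = Eε + ηε̇",
            lambda p: p.copy(), lambda k: k.copy()),
        ConstitutiveModel(
            "zener_k", ("epsilon", "epsilon_dot", "sigma_dot"),
            ("E1", "E2", "eta"), "zener",
            "standard linear solid, Kelvin form: "
            "σ = (E1E2/(E1+E2))ε + (E2η/(E1+E2))ε̇ − (η/(E1+E2))σ̇",
            lambda p: np.array([
                p[0] * p[1] / (p[0] + p[1]),
                p[1] * p[2] / (p[0] + p[1]),
                -p[2] / (p[0] + p[1]),
            ]),
            _zener_k_p),
        ConstitutiveModel(
            "zener_m", ("epsilon", "epsilon_dot", "sigma_dot"),
            ("E1", "E2", "eta"), "zener",
            "standard linear solid, Maxwell form: "
            "σ = E2ε + (η(E1+E2)/E1)ε̇ − (η/E1)σ̇",
            lambda p: np.array([
                p[1],
                p[2] * (p[0] + p[1]) / p[0],
                -p[2] / p[0],
            ]),
            _zener_m_p),
        ConstitutiveModel(
            "lethersich", ("epsilon_dot", "epsilon_ddot", "sigma_dot"),
            ("E", "eta1", "eta2"), "lethersich_jeffreys",
            "three-element viscoelastic liquid: "
            "σ = η2ε̇ + (η1η2/E)ε̈ − ((η1+η2)/E)σ̇",
            lambda p: np.array([
                p[2],
                p[1] * p[2] / p[0],
                -(p[1] + p[2]) / p[0],
            ]),
            _lethersich_p),
        ConstitutiveModel(
            "jeffreys", ("epsilon_dot", "epsilon_ddot", "sigma_dot"),
            ("E", "eta1", "eta2"), "lethersich_jeffreys",
            "three-element viscoelastic liquid: "
            "σ = (η1+η2)ε̇ + (η1η2/E)ε̈ − (η1/E)σ̇",
            lambda p: np.array([
                p[1] + p[2],
                p[1] * p[2] / p[0],
                -p[1] / p[0],
            ]),
            _jeffreys_p),
        ConstitutiveModel(
            "burgers",
            ("epsilon_dot", "epsilon_ddot", "sigma_dot", "sigma_ddot"),
            ("E1", "E2", "eta1", "eta2"), "burgers",
            "Maxwell and Kelvin–Voigt in series: "
            "σ = η1ε̇ + (η1η2/E2)ε̈ − ((E1η1+E1η2+E2η1)/(E1E2))σ̇ "
            "− (η1η2/(E1E2))σ̈",
            _burgers_k, _burgers_p),
    ]
    return {mod.name: mod for mod in m}


#: the built-in model registry, ordered from simplest upward
REGISTRY: dict[str, ConstitutiveModel] = _build_registry()


def get_model(name: str) -> ConstitutiveModel:
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {list(REGISTRY)}") from None


def degeneracy_classes(models: Sequence[ConstitutiveModel] | None = None
                       ) -> dict[str, list[ConstitutiveModel]]:
    """Group models by degeneracy class, preserving registry order."""
    out: dict[str, list[ConstitutiveModel]] = {}
    for mod in (models if models is not None else REGISTRY.values()):
        out.setdefault(mod.degeneracy_class, []).append(mod)
    return out


# --- design matrix ----------------------------------------------------------

def design_terms(model: ConstitutiveModel, sampled) -> tuple[np.ndarray, np.ndarray]:
    """Effects matrix (one column per σ-form term, registry order) and the
    stress response vector.  No intercept column is ever added: every
    σ-form is homogeneous, and a constant offset is physically meaningless
    in oscillatory stress."""
    X = np.column_stack([sampled.column(t) for t in model.terms])
    y = np.asarray(sampled.sigma, float)
    return X, y


# --- forward complex modulus ------------------------------------------------

def _coerce_params(model: ConstitutiveModel,
                   params: "MaterialParameters | Mapping[str, float] | Sequence[float]"
                   ) -> np.ndarray:
    if isinstance(params, MaterialParameters):
        if params.model_name != model.name:
            raise ValueError(
                f"parameters are for {params.model_name!r}, not {model.name!r}")
        return np.array([params.estimate(s) for s in model.param_names])
    if isinstance(params, Mapping):
        missing = [s for s in model.param_names if s not in params]
        if missing:
            raise ValueError(f"missing parameters for {model.name}: {missing}")
        return np.array([float(params[s]) for s in model.param_names])
    arr = np.asarray(params, float)
    if arr.shape != (model.n_params,):
        raise ValueError(
            f"{model.name} takes {model.n_params} parameters "
            f"{model.param_names}, got shape {arr.shape}")
    return arr


def forward_coefficients(model: ConstitutiveModel, params) -> np.ndarray:
    """σ-form coefficient vector K for given material parameters."""
    return model.k_from_params(_coerce_params(model, params))


def complex_modulus(model: ConstitutiveModel, params, omegas: np.ndarray
                    ) -> np.ndarray:
    """G*(ω) from the σ-form via d/dt → iω."""
    k = forward_coefficients(model, params)
    iw = 1j * np.asarray(omegas, float)
    num = np.zeros_like(iw)
    den = np.ones_like(iw)
    for coeff, term in zip(k, model.terms):
        contrib = coeff * iw ** _DERIV_ORDER[term]
        if term in _STRAIN_TERMS:
            num = num + contrib
        else:
            den = den - contrib
    return num / den


def forward_moduli(model: ConstitutiveModel, params, omegas) -> FrequencySweep:
    """Exact noise-free sweep G'(ω), G''(ω) for physical parameters.

    Raises :class:`NonPhysicalParameterError` unless every modulus and
    viscosity is strictly positive.
    """
    p = _coerce_params(model, params)
    if not np.all(p > 0):
        raise NonPhysicalParameterError(
            f"{model.name}: all material parameters must be > 0, got "
            f"{dict(zip(model.param_names, p))}")
    omegas = np.asarray(omegas, float)
    if not np.all(omegas > 0):
        raise ValueError("frequencies must be positive")
    gstar = complex_modulus(model, p, omegas)
    gp = np.real(gstar)
    gpp = np.imag(gstar)
    # physical spring–dashpot networks cannot produce negative moduli;
    # clip only the negative-zero rounding left by the complex division
    gp[np.abs(gp) < 1e-30] = 0.0
    gpp[np.abs(gpp) < 1e-30] = 0.0
    return FrequencySweep(omega=omegas, g_prime=gp, g_double_prime=gpp,
                          metadata={"model": model.name})


# --- inversion with uncertainty propagation ---------------------------------

def _numeric_jacobian(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray
                      ) -> np.ndarray:
    """Central-difference Jacobian of the inversion map (delta method)."""
    n = x.size
    f0 = f(x)
    J = np.empty((f0.size, n))
    for j in range(n):
        h = 1e-7 * max(abs(x[j]), 1.0)
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        J[:, j] = (f(xp) - f(xm)) / (2 * h)
    return J


def invert_parameters(model: ConstitutiveModel, k: np.ndarray,
                      k_covariance: np.ndarray | None = None
                      ) -> MaterialParameters:
    """Material parameters from σ-form regression coefficients.

    Standard errors are propagated from the coefficient covariance by
    first-order (delta-method) linearization of the closed-form inverse.
    Non-physical (negative) estimates are flagged, never hidden: a wrong
    sign is evidence the model does not describe the data.
    """
    k = np.asarray(k, float)
    if k.shape != (len(model.terms),):
        raise ValueError(
            f"{model.name} has {len(model.terms)} coefficients, got {k.shape}")
    est = model.params_from_k(k)
    if k_covariance is not None:
        J = _numeric_jacobian(model.params_from_k, k)
        cov = J @ np.asarray(k_covariance, float) @ J.T
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    else:
        se = np.full(est.size, np.nan)
    values = {s: (float(e), float(s_)) for s, e, s_ in
              zip(model.param_names, est, se)}
    return MaterialParameters(model_name=model.name, values=values,
                              physical=bool(np.all(est > 0)))


# --- declarative YAML registry ----------------------------------------------

def registry_to_yaml(models: Sequence[ConstitutiveModel] | None = None) -> str:
    """Serialize registry entries (name, terms, parameter symbols,
    degeneracy class, σ-form description) as a YAML document."""
    entries = [
        {
            "name": m.name,
            "terms": list(m.terms),
            "param_names": list(m.param_names),
            "degeneracy_class": m.degeneracy_class,
            "description": m.description,
        }
        for m in (models if models is not None else REGISTRY.values())
    ]
    return yaml.safe_dump({"models": entries}, sort_keys=False)


def registry_from_yaml(text: str) -> dict[str, ConstitutiveModel]:
    """Load a model registry from YAML.

    Names matching built-in models recover the full entry, including the
    parameter maps; unknown names produce fit-only models (their terms
    define the regression design, but no closed-form inversion is
    synthesized from YAML).
    """
    doc = yaml.safe_load(text)
    out: dict[str, ConstitutiveModel] = {}
    for entry in doc["models"]:
        name = entry["name"]
        if name in REGISTRY:
            builtin = REGISTRY[name]
            if tuple(entry["terms"]) != builtin.terms:
                raise ValueError(
                    f"YAML terms for built-in model {name!r} do not match "
                    f"its σ-form: {entry['terms']} vs {list(builtin.terms)}")
            out[name] = builtin
        else:
            out[name] = ConstitutiveModel(
                name=name,
                terms=tuple(entry["terms"]),
                param_names=tuple(entry.get("param_names", ())),
                degeneracy_class=entry.get("degeneracy_class", name),
                description=entry.get("description", ""),
            )
    return out
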