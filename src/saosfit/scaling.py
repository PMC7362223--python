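"""Concentration scaling, strut-spreading kinetics and condition ratios.

Two application layers sit on top of the identified Burgers parameters:

* **Concentration scaling.**  For polymer solutions viewed as a
  solvent/polymer composite, moduli and viscosities follow a quasi
  power law in concentration,

      η(c) = η₀ (1 + c/c̃)ⁿ        E(c) = E₀ (1 + c/c̃)ᵐ

  with prefactor the zero-concentration value (e.g. η₀ = 1 mPa·s for
  water), characteristic concentration c̃, and exponent n or m (theory
  for isotropic properties suggests fixing n = m = 3).  Any subset of
  the three parameters can be held fixed during the fit.

* **Strut spreading.**  After deposition a printed hydrogel strut's
  diameter relaxes exponentially toward its equilibrium value,

      d(t) = A·[1 − exp(−(t + t₀)/τ_s)]

  where t₀ is a delay allowing a finite diameter at t = 0 and τ_s is the
  characteristic spreading time: at elapsed time t with t + t₀ = τ_s the
  strut has reached 1 − e⁻¹ = 63.2% of A.  Only the sum t + t₀ enters the
  model, so a joint shift t → t + Δ, t₀ → t₀ − Δ leaves the fit invariant
  — t and t₀ are identified separately only because measurement clocks
  start at deposition.

The Burgers model carries two characteristic times of its own,
τ₁ = η₁/E₁ (Maxwell part, non-recoverable flow) and τ₂ = η₂/E₂
(Kelvin–Voigt part, recoverable deformation); empirically the spreading
time ratio between inks tracks the Maxwell ratio, τ_s(b)/τ_s(a) ≈
τ₁(b)/τ₁(a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .models import MaterialParameters
from .sweeps import StrutSeries

__all__ = [
    "ScalingFit",
    "SpreadingKinetics",
    "CharacteristicTimes",
    "FitConvergenceError",
    "fit_concentration_scaling",
    "fit_strut_spreading",
    "characteristic_times",
    "compare_conditions",
]

_SCALING_FIELDS = ("prefactor", "c_tilde", "exponent")


class FitConvergenceError(RuntimeError):
    """Nonlinear least squares failed to converge or gave unphysical values."""


@dataclass(frozen=True)
class ScalingFit:
    """Quasi-power-law fit value(c) = prefactor · (1 + c/c̃)^exponent."""

    quantity: str                      # e.g. "eta1", "E2"
    prefactor: float                   # η₀ (Pa·s) or E₀ (Pa)
    c_tilde: float                     # characteristic concentration
    exponent: float                    # n or m, dimensionless
    fixed_fields: tuple[str, ...]      # parameters held constant in the fit
    standard_errors: dict[str, float]  # SEs of the free parameters
    rss: float

    def __post_init__(self) -> None:
        if self.prefactor <= 0 or self.c_tilde <= 0:
            raise FitConvergenceError(
                f"{self.quantity}: prefactor and c_tilde must be positive "
                f"(got {self.prefactor}, {self.c_tilde})")

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, float)
        return self.prefactor * (1.0 + c / self.c_tilde) ** self.exponent


@dataclass(frozen=True)
class SpreadingKinetics:
    """Exponential approach of strut diameter to its equilibrium value."""

    A: float                           # equilibrium strut diameter, mm
    t0: float                          # delay time, s
    tau_s: float                       # characteristic spreading time, s
    standard_errors: dict[str, float]
    fit_rss: float

    def __post_init__(self) -> None:
        if self.A <= 0 or self.tau_s <= 0:
            raise FitConvergenceError(
                f"spreading fit gave unphysical parameters "
                f"A={self.A}, tau_s={self.tau_s}")

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        return self.A * (1.0 - np.exp(-(t + self.t0) / self.tau_s))


@dataclass(frozen=True)
class CharacteristicTimes:
    """Burgers characteristic times τ₁ = η₁/E₁ and τ₂ = η₂/E₂ in seconds."""

    tau1: float
    tau2: float
    tau1_stderr: float
    tau2_stderr: float
    source_params: MaterialParameters


def _scaling_law(c, prefactor, c_tilde, exponent):
    # guard against optimizer excursions into c_tilde <= 0, where the base
    # goes negative and a fractional power is undefined
    with np.errstate(invalid="ignore", divide="ignore"):
        out = prefactor * np.power(1.0 + c / c_tilde, exponent)
    return np.nan_to_num(out, nan=1e30, posinf=1e30, neginf=-1e30)


def fit_concentration_scaling(
    data: Sequence[tuple[float, float]],
    quantity: str,
    fixed: Mapping[str, float] | None = None,
) -> ScalingFit:
    """Fit value(c) = prefactor·(1 + c/c̃)^exponent to concentration data.

    Parameters
    ----------
    data
        (concentration, parameter value) pairs.  Concentration is treated
        as a raw number — the caller owns the unit.
    quantity
        Label for the fitted Burgers parameter ("E1", "E2", "eta1", "eta2").
    fixed
        Subset of {"prefactor", "c_tilde", "exponent"} held constant, e.g.
        ``{"prefactor": 0.001}`` to pin η₀ at the solvent viscosity or
        ``{"exponent": 3}`` for the theoretical isotropic-scaling value.

    Initial guesses are deterministic data heuristics: prefactor from the
    smallest value, c̃ from the concentration where the data first exceed
    10× the prefactor, exponent from a log–log slope.
    """
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(_SCALING_FIELDS)
    if unknown:
        raise ValueError(f"unknown fixed fields: {sorted(unknown)}")
    free = [f for f in _SCALING_FIELDS if f not in fixed]
    arr = np.asarray(sorted(data), float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("data must be (concentration, value) pairs")
    c, v = arr[:, 0], arr[:, 1]
    if len(c) < len(free) + 1:
        raise ValueError(
            f"{len(free)} free parameters need at least {len(free) + 1} "
            f"concentration points, got {len(c)}")

    # deterministic initial guesses
    p0_full = {
        "prefactor": fixed.get("prefactor", max(float(v.min()), 1e-12)),
        "exponent": fixed.get("exponent", 3.0),
    }
    pref = p0_full["prefactor"]
    above = c[v > 10.0 * pref]
    p0_full["c_tilde"] = fixed.get(
        "c_tilde", float(above[0]) if above.size else float(np.median(c)))
    if "exponent" in free and len(c) >= 2:
        x = np.log1p(c / p0_full["c_tilde"])
        yv = np.log(v / pref)
        slope = np.polyfit(x, yv, 1)[0]
        p0_full["exponent"] = float(np.clip(slope, 0.5, 10.0))

    def f(cc, *theta):
        full = dict(fixed)
        full.update(zip(free, theta))
        return _scaling_law(cc, full["prefactor"], full["c_tilde"],
                            full["exponent"])

    p0 = [p0_full[name] for name in free]
    try:
        popt, pcov = curve_fit(f, c, v, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"concentration-scaling fit for {quantity} did not converge "
            f"(p0={dict(zip(free, p0))}): {exc}") from exc
    full = dict(fixed)
    full.update(zip(free, popt))
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    rss = float(np.sum((v - f(c, *popt)) ** 2))
    return ScalingFit(
        quantity=quantity,
        prefactor=float(full["prefactor"]),
        c_tilde=float(full["c_tilde"]),
        exponent=float(full["exponent"]),
        fixed_fields=tuple(f_ for f_ in _SCALING_FIELDS if f_ in fixed),
        standard_errors={name: float(s) for name, s in zip(free, se)},
        rss=rss,
    )


def fit_strut_spreading(series: StrutSeries) -> SpreadingKinetics:
    """Fit d(t) = A·[1 − exp(−(t + t₀)/τ_s)] to a strut-diameter series.

    Requires at least 4 time points and a series that has substantially
    approached its plateau (last diameter ≥ 60% of the maximum), since
    A is otherwise unconstrained.
    """
    t, d = series.time, series.diameter
    if t.size < 4:
        raise ValueError(f"need at least 4 time points, got {t.size}")
    dmax = float(d.max())
    if d[-1] < 0.6 * dmax:
        raise ValueError(
            "series has not approached its plateau (last diameter "
            f"{d[-1]:.3g} < 60% of max {dmax:.3g}); the equilibrium "
            "diameter would be unconstrained")

    # deterministic initial guesses: A slightly above the observed maximum;
    # t0 and τ_s from the log-linearization ln(1 − d/A) = −(t + t0)/τ_s,
    # which stays informative when the series starts at a finite diameter
    A0 = 1.05 * dmax
    z = np.log(np.clip(1.0 - d / A0, 1e-9, None))
    slope, intercept = np.polyfit(t, z, 1)
    if slope < 0:
        tau0 = -1.0 / slope
        t0_guess = max(-intercept * tau0, 1e-6)
    else:
        tau0 = max(float(t[-1]) / 2.0, 1e-6)
        t0_guess = 1e-6

    def f(tt, A, t0, tau_s):
        return A * (1.0 - np.exp(-(tt + t0) / tau_s))

    try:
        popt, pcov = curve_fit(f, t, d, p0=[A0, t0_guess, tau0], maxfev=20000)
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"spreading fit did not converge (p0={[A0, t0_guess, tau0]}): {exc}"
        ) from exc
    A, t0, tau_s = popt
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    rss = float(np.sum((d - f(t, *popt)) ** 2))
    if tau_s <= 0:
        raise FitConvergenceError(
            f"spreading fit converged to non-positive tau_s = {tau_s:.3g}")
    return SpreadingKinetics(
        A=float(A), t0=float(t0), tau_s=float(tau_s),
        standard_errors={"A": float(se[0]), "t0": float(se[1]),
                         "tau_s": float(se[2])},
        fit_rss=rss,
    )


def _ratio_se(num: float, num_se: float, den: float, den_se: float) -> float:
    """First-order SE of num/den treating the two estimates as independent."""
    r = num / den
    return abs(r) * math.sqrt((num_se / num) ** 2 + (den_se / den) ** 2)


def characteristic_times(params: MaterialParameters) -> CharacteristicTimes:
    """Burgers characteristic times τ₁ = η₁/E₁ and τ₂ = η₂/E₂.

    Uncertainties by first-order propagation from the parameter standard
    errors (cross-covariances between inverted parameters are not carried
    by ``MaterialParameters`` and are neglected here).
    """
    if params.model_name != "burgers":
        raise ValueError(
            f"characteristic times are defined for the burgers model, "
            f"got {params.model_name!r}")
    if not params.physical:
        raise ValueError("characteristic times need positive Burgers parameters")
    e1, se_e1 = params.values["E1"]
    e2, se_e2 = params.values["E2"]
    n1, se_n1 = params.values["eta1"]
    n2, se_n2 = params.values["eta2"]
    tau1 = n1 / e1
    tau2 = n2 / e2

    def se(tau, n, sn, e, sem):
        if any(map(math.isnan, (sn, sem))):
            return float("nan")
        return _ratio_se(n, sn, e, sem)

    return CharacteristicTimes(
        tau1=tau1, tau2=tau2,
        tau1_stderr=se(tau1, n1, se_n1, e1, se_e1),
        tau2_stderr=se(tau2, n2, se_n2, e2, se_e2),
        source_params=params,
    )


def _as_quantity_map(obj) -> dict[str, tuple[float, float]]:
    if isinstance(obj, MaterialParameters):
        return dict(obj.values)
    if isinstance(obj, CharacteristicTimes):
        return {"tau1": (obj.tau1, obj.tau1_stderr),
                "tau2": (obj.tau2, obj.tau2_stderr)}
    raise TypeError(f"cannot compare objects of type {type(obj).__name__}")


def compare_conditions(a, b) -> dict[str, dict[str, float]]:
    """Per-quantity ratio b/a between two conditions (e.g. 3% vs 4% ink,
    pure vs fiber-filled gel).

    Returns, per shared quantity, the ratio, its first-order standard
    error, and the ratio expressed as a percentage of the reference
    (ratio × 100, rounded to the nearest percent — a 4.18× increase
    reads as 418%).
    """
    qa, qb = _as_quantity_map(a), _as_quantity_map(b)
    if set(qa) != set(qb):
        raise ValueError(
            f"conditions carry different quantities: {sorted(qa)} vs {sorted(qb)}")
    out: dict[str, dict[str, float]] = {}
    for name in qa:
        va, sa = qa[name]
        vb, sb = qb[name]
        if va == 0:
            raise ZeroDivisionError(f"reference value for {name} is zero")
        ratio = vb / va
        if math.isnan(sa) or math.isnan(sb):
            se = float("nan")
        else:
            se = _ratio_se(vb, sb, va, sa)
        out[name] = {
            "ratio": ratio,
            "stderr": se,
            "percent": float(round(ratio * 100.0)),
        }
    return out
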