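"""Core containers for oscillatory rheometry data.

A small-amplitude oscillatory shear (SAOS) frequency sweep reports the
storage modulus G'(ω) and loss modulus G''(ω) over a grid of angular
frequencies — the standard reduced output of a rotational rheometer or a
DMA.  These containers validate the physical constraints (positive,
strictly increasing ω; non-negative moduli) once at construction so that
downstream signal reconstruction and regression can assume clean input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "FrequencySweep",
    "FlowCurve",
    "StrutSeries",
    "SweepValidationError",
    "NarrowFrequencyRangeWarning",
    "cox_merz_viscosity",
]


class SweepValidationError(ValueError):
    """Raised when ingested rheometry data violates a physical invariant."""


class NarrowFrequencyRangeWarning(UserWarning):
    """Emitted when a sweep spans fewer than three decades of frequency.

    Reliable constitutive-model identification needs the ω grid to probe
    both the terminal (flow) and the plateau regime; a narrow sweep makes
    higher-order models poorly conditioned.
    """


@dataclass(frozen=True)
class FrequencySweep:
    """An oscillatory frequency sweep: G'(ω), G''(ω) at fixed strain amplitude.

    Parameters
    ----------
    omega : array of angular frequency, rad/s; strictly positive, strictly
        increasing.
    g_prime : storage modulus G' per frequency, Pa; non-negative.
    g_double_prime : loss modulus G'' per frequency, Pa; non-negative.
    strain_amplitude : the applied deformation amplitude (dimensionless);
        defaults to 1.  All regression coefficients downstream are invariant
        to it (response and regressors scale linearly), so an unknown
        amplitude is harmless for model identification.
    metadata : free-form text map (sample id, temperature, geometry ...).
    """

    omega: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray
    strain_amplitude: float = 1.0
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        omega = np.asarray(self.omega, dtype=float)
        gp = np.asarray(self.g_prime, dtype=float)
        gpp = np.asarray(self.g_double_prime, dtype=float)
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "g_prime", gp)
        object.__setattr__(self, "g_double_prime", gpp)
        if omega.ndim != 1 or omega.size < 2:
            raise SweepValidationError(
                f"a frequency sweep needs at least 2 points, got {omega.size}"
            )
        if gp.shape != omega.shape or gpp.shape != omega.shape:
            raise SweepValidationError("omega, g_prime, g_double_prime must align")
        if not np.all(omega > 0):
            raise SweepValidationError("angular frequencies must be strictly positive")
        if not np.all(np.diff(omega) > 0):
            raise SweepValidationError(
                "angular frequencies must be strictly increasing (no duplicates)"
            )
        bad = np.flatnonzero((gp < 0) | (gpp < 0))
        if bad.size:
            raise SweepValidationError(
                f"negative modulus at row index {bad[0]}: moduli must be >= 0"
            )
        if self.strain_amplitude <= 0:
            raise SweepValidationError("strain amplitude must be positive")
        if self.decades_spanned < 3.0:
            warnings.warn(
                f"frequency sweep spans {self.decades_spanned:.2f} decades; "
                "at least three decades are recommended for reliable model "
                "identification",
                NarrowFrequencyRangeWarning,
                stacklevel=2,
            )

    @property
    def n_points(self) -> int:
        return int(self.omega.size)

    @property
    def decades_spanned(self) -> float:
        """Width of the ω range in decades, log10(ω_max/ω_min)."""
        return float(np.log10(self.omega[-1] / self.omega[0]))

    @property
    def complex_modulus(self) -> np.ndarray:
        """G*(ω) = G' + iG'' as a complex array."""
        return self.g_prime + 1j * self.g_double_prime


@dataclass(frozen=True)
class FlowCurve:
    """Steady-shear viscosity curve η(γ̇), e.g. from the Cox–Merz rule."""

    shear_rate: np.ndarray
    viscosity: np.ndarray

    def __post_init__(self) -> None:
        rate = np.asarray(self.shear_rate, dtype=float)
        visc = np.asarray(self.viscosity, dtype=float)
        object.__setattr__(self, "shear_rate", rate)
        object.__setattr__(self, "viscosity", visc)
        if rate.shape != visc.shape:
            raise SweepValidationError("shear_rate and viscosity must align")
        if not np.all(rate > 0):
            raise SweepValidationError("shear rates must be strictly positive")
        if not np.all(visc > 0):
            raise SweepValidationError("viscosities must be positive")


@dataclass(frozen=True)
class StrutSeries:
    """Optically measured diameter d(t) of a printed hydrogel strut over time."""

    time: np.ndarray
    diameter: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.diameter, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "diameter", d)
        if t.shape != d.shape or t.ndim != 1:
            raise SweepValidationError("time and diameter must be aligned 1-D arrays")
        if t.size and t[0] < 0:
            raise SweepValidationError("times must be non-negative")
        if not np.all(np.diff(t) > 0):
            raise SweepValidationError("times must be strictly increasing")
        # zero is allowed only as the deposition instant (t = 0, no delay)
        if not np.all(d >= 0):
            raise SweepValidationError("diameters must be non-negative")


def cox_merz_viscosity(sweep: FrequencySweep) -> FlowCurve:
    """Steady-shear viscosity from oscillatory moduli via the Cox–Merz rule.

    The empirical Cox–Merz rule identifies the steady-shear viscosity with
    the magnitude of the complex viscosity evaluated at γ̇ = ω:

        η(γ̇) = |η*(ω = γ̇)| = sqrt(G'² + G''²) / ω

    For viscoelastic liquids (Maxwell, Burgers) this curve is shear
    thinning; for a pure dashpot it is flat at the dashpot viscosity.
    """
    eta = np.hypot(sweep.g_prime, sweep.g_double_prime) / sweep.omega
    return FlowCurve(shear_rate=sweep.omega.copy(), viscosity=eta)
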