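"""Synthetic data generation for the full identification pipeline.

Sweeps are generated from a registered model's exact complex modulus and
perturbed with multiplicative Gaussian noise on G' and G'' independently
— instrument error on a rheometer scales with the signal, so relative
noise is the realistic corruption model.  Strut-diameter series come from
the exponential spreading law with additive noise (optical diameter
measurements have a roughly constant pixel-scale error).

Everything is deterministic under a seed, so property tests and the
acceptance checks are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import ConstitutiveModel, forward_moduli
from .sweeps import FrequencySweep, StrutSeries

__all__ = ["NoiseSpec", "default_omega_grid", "generate_sweep",
           "generate_strut_series"]


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian noise on the moduli.

    ``relative_sd`` is the standard deviation of the relative error: each
    modulus value is multiplied by an independent draw of
    ``1 + relative_sd * N(0, 1)``.
    """

    relative_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")


def default_omega_grid(n_points: int = 20, omega_min: float = 0.1,
                       omega_max: float = 100.0) -> np.ndarray:
    """20 log-spaced frequencies over 0.1–100 rad/s — the standard
    three-decade sweep range for gel-like materials (higher frequencies
    are typically contaminated by machine inertia)."""
    return np.logspace(np.log10(omega_min), np.log10(omega_max), n_points)


def generate_sweep(
    model: ConstitutiveModel,
    params,
    omega_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
    strain_amplitude: float = 1.0,
) -> FrequencySweep:
    """Noise-free or noisy frequency sweep from a registered model.

    With ``noise.relative_sd == 0`` the output is identical to
    :func:`saosfit.models.forward_moduli`.  Noisy values that fall
    negative are clipped to 0 with a warning (moduli are non-negative by
    definition; clipping only occurs at unrealistically large noise).
    """
    if omega_grid is None:
        omega_grid = default_omega_grid()
    clean = forward_moduli(model, params, omega_grid)
    if noise.relative_sd == 0.0:
        return FrequencySweep(
            omega=clean.omega, g_prime=clean.g_prime,
            g_double_prime=clean.g_double_prime,
            strain_amplitude=strain_amplitude,
            metadata={"model": model.name, "noise": "0"},
        )
    rng = np.random.default_rng(noise.seed)
    factors = 1.0 + noise.relative_sd * rng.standard_normal((2, omega_grid.size))
    gp = clean.g_prime * factors[0]
    gpp = clean.g_double_prime * factors[1]
    n_clipped = int(np.sum(gp < 0) + np.sum(gpp < 0))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} noisy modulus values fell below zero and were "
            "clipped to 0",
            UserWarning,
            stacklevel=2,
        )
        gp = np.clip(gp, 0.0, None)
        gpp = np.clip(gpp, 0.0, None)
    return FrequencySweep(
        omega=omega_grid.copy(), g_prime=gp, g_double_prime=gpp,
        strain_amplitude=strain_amplitude,
        metadata={"model": model.name, "noise": repr(noise.relative_sd)},
    )


def generate_strut_series(
    A: float,
    t0: float,
    tau_s: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    replicate_id: str = "synthetic",
) -> StrutSeries:
    """Strut-diameter series d(t) = A·[1 − exp(−(t + t₀)/τ_s)] with
    additive Gaussian noise of SD ``noise_sd`` (mm)."""
    if A <= 0 or tau_s <= 0:
        raise ValueError("A and tau_s must be positive")
    times = np.asarray(times, float)
    d = A * (1.0 - np.exp(-(times + t0) / tau_s))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d = d + noise_sd * rng.standard_normal(times.size)
        d = np.clip(d, 1e-9, None)
    return StrutSeries(time=times, diameter=d, replicate_id=replicate_id)
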