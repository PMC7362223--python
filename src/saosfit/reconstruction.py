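"""Reconstruction of periodic stress/strain signals from sweep moduli.

In a strain-controlled oscillatory experiment the applied deformation is

    ε(t) = ε̃ sin(ωt)

and the stress response within the linear regime is fully determined by
the measured storage and loss moduli:

    σ(t) = G'(ω) ε̃ sin(ωt) + G''(ω) ε̃ cos(ωt)

All time derivatives follow analytically (never by finite differences):

    ε̇ = ε̃ ω cos(ωt)          ε̈ = −ω² ε
    σ̇ = G' ε̃ ω cos(ωt) − G'' ε̃ ω sin(ωt)          σ̈ = −ω² σ

Because the signals are periodic, sampling one full period per frequency
suffices; the sampling times are t_ij = i · (2π/ω_j) / n per frequency
ω_j, i = 0 … n−1, with n = 10 by default.  Stacking these rows over all
frequencies yields the dataset on which constitutive models are
benchmarked by linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd

from .sweeps import FrequencySweep

__all__ = ["SampledResponse", "reconstruct"]

#: tidy export column order: strain, its derivatives, stress, its
#: derivatives, then the frequency label
COLUMNS = ("epsilon", "epsilon_dot", "epsilon_ddot",
           "sigma", "sigma_dot", "sigma_ddot", "omega", "t")


@dataclass(frozen=True)
class SampledResponse:
    """Sampled ε, ε̇, ε̈, σ, σ̇, σ̈ over one period per frequency.

    Each field is a flat array of length ``n_per_period × n_frequencies``,
    grouped by frequency in ascending ω order.  The identities
    ε̈ = −ω²ε and σ̈ = −ω²σ hold row-wise to machine precision by
    construction.
    """

    epsilon: np.ndarray
    epsilon_dot: np.ndarray
    epsilon_ddot: np.ndarray
    sigma: np.ndarray
    sigma_dot: np.ndarray
    sigma_ddot: np.ndarray
    omega: np.ndarray          # per-row frequency label, rad/s
    t: np.ndarray              # per-row sampling time, s
    n_per_period: int
    strain_amplitude: float

    @property
    def n_rows(self) -> int:
        return int(self.sigma.size)

    @property
    def frequencies(self) -> np.ndarray:
        """Distinct frequencies, ascending."""
        return np.unique(self.omega)

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame with one row per sample."""
        return pd.DataFrame({name: getattr(self, name) for name in COLUMNS})

    def to_csv(self, path: str | PathLike) -> None:
        self.to_frame().to_csv(path, index=False)

    def column(self, name: str) -> np.ndarray:
        """Fetch a signal column by canonical name (e.g. ``"epsilon_dot"``)."""
        if name not in COLUMNS:
            raise KeyError(f"unknown signal column {name!r}")
        return getattr(self, name)


def reconstruct(sweep: FrequencySweep, n_per_period: int = 10) -> SampledResponse:
    """Build the sampled stress/strain dataset from a frequency sweep.

    Parameters
    ----------
    sweep
        Validated frequency sweep (ω ascending).
    n_per_period
        Samples per oscillation period (default 10).  At least 4 are
        required: fewer samples cannot separate the in-phase and
        quadrature components with any redundancy.

    Returns
    -------
    SampledResponse with ``n_per_period × sweep.n_points`` rows.
    """
    if n_per_period < 4:
        raise ValueError(
            f"n_per_period must be >= 4 (got {n_per_period}): fewer samples "
            "per period give an under-determined sampling of the oscillation"
        )
    amp = sweep.strain_amplitude
    i = np.arange(n_per_period)
    # shape (n_freq, n_per_period); period T_j = 2π/ω_j
    omega = sweep.omega[:, None]
    t = i[None, :] * (2.0 * np.pi / omega) / n_per_period
    phase = omega * t                      # = 2π i / n, exact per row
    sin, cos = np.sin(phase), np.cos(phase)
    gp = sweep.g_prime[:, None]
    gpp = sweep.g_double_prime[:, None]

    eps = amp * sin
    eps_dot = amp * omega * cos
    eps_ddot = -(omega ** 2) * eps
    sig = gp * amp * sin + gpp * amp * cos
    sig_dot = gp * amp * omega * cos - gpp * amp * omega * sin
    sig_ddot = -(omega ** 2) * sig

    flat = lambda a: np.ascontiguousarray(a.reshape(-1))
    return SampledResponse(
        epsilon=flat(eps),
        epsilon_dot=flat(eps_dot),
        epsilon_ddot=flat(eps_ddot),
        sigma=flat(sig),
        sigma_dot=flat(sig_dot),
        sigma_ddot=flat(sig_ddot),
        omega=flat(np.broadcast_to(omega, eps.shape)),
        t=flat(t),
        n_per_period=int(n_per_period),
        strain_amplitude=float(amp),
    )
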