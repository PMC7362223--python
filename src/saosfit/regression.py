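"""Intercept-free least squares on σ-form main effects, and model ranking.

The constitutive equations are homogeneous in stress, so the regression of
σ on each model's main effects is always through the origin.  Goodness of
fit therefore uses the *uncentered* coefficient of determination

    R² = 1 − SSR / Σσ²

with the adjusted form  adj R² = 1 − (1 − R²)(n − 1)/(n − p).  Models are
compared per degeneracy class (the two Zener variants, and
Lethersich/Jeffreys, share identical design columns) and ranked by
adjusted R²; among near-ties the model with fewer spring–dashpot elements
wins (parsimony), with residual SD as the final tie-break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .models import (
    REGISTRY,
    ConstitutiveModel,
    MaterialParameters,
    degeneracy_classes,
    design_terms,
    invert_parameters,
)
from .reconstruction import SampledResponse

__all__ = [
    "RegressionResult",
    "ModelRanking",
    "RankingEntry",
    "CollinearDesignError",
    "IllConditionedWarning",
    "fit_model",
    "fit_and_invert",
    "benchmark_models",
    "residual_summary",
    "observed_vs_predicted",
    "bootstrap_parameters",
]

#: condition-number threshold above which a warning is emitted — the ε̇/ε̈
#: columns differ by ω factors that span decades, so conditioning is the
#: practical failure mode
CONDITION_WARN = 1e8


class CollinearDesignError(ValueError):
    """The effects matrix is rank deficient, so coefficients are not
    identifiable."""


class IllConditionedWarning(UserWarning):
    """Effects matrix condition number is large; coefficients may be noisy."""


@dataclass(frozen=True)
class RegressionResult:
    """One intercept-free fit of σ on a model's main effects."""

    model_name: str
    terms: tuple[str, ...]
    k: np.ndarray                      # coefficient estimates, σ-form order
    k_covariance: np.ndarray
    r2: float                          # uncentered
    adj_r2: float
    n_obs: int
    residuals: np.ndarray              # observed − calculated stress, Pa
    predicted: np.ndarray              # calculated stress, Pa
    observed: np.ndarray
    condition_number: float

    @property
    def residual_sd(self) -> float:
        return float(np.std(self.residuals))

    @property
    def k_stderr(self) -> np.ndarray:
        return np.sqrt(np.diag(self.k_covariance))


@dataclass(frozen=True)
class RankingEntry:
    model_or_class: str
    member_names: tuple[str, ...]
    adj_r2: float
    r2: float
    residual_sd: float
    n_params: int


@dataclass(frozen=True)
class ModelRanking:
    """Per-degeneracy-class benchmark sorted by adjusted R² (descending)."""

    entries: tuple[RankingEntry, ...]
    selected: str
    tie_tolerance: float
    results: dict[str, RegressionResult] = field(repr=False, default_factory=dict)
    failures: dict[str, str] = field(repr=False, default_factory=dict)


def _per_frequency_scale(sampled: SampledResponse) -> np.ndarray:
    """Row-wise normalizer ε̃·sqrt(G'² + G''²), constant within a frequency.

    Computed directly from the sampled signals: (σ/ε̃)² + (σ̇/(ε̃ω))²
    equals G'² + G''² at every sampling time.
    """
    amp = sampled.strain_amplitude
    mag = np.hypot(sampled.sigma / amp, sampled.sigma_dot / (amp * sampled.omega))
    return amp * mag


def fit_model(
    sampled: SampledResponse,
    model: ConstitutiveModel,
    normalize_per_frequency: bool = False,
) -> RegressionResult:
    """Least-squares fit of the stress on one model's main effects.

    Parameters
    ----------
    sampled
        Reconstructed stress/strain dataset (all frequencies jointly —
        the σ-form holds at every frequency with one coefficient vector).
    model
        Registry entry whose ``terms`` define the design columns.
    normalize_per_frequency
        Optional weighting that divides each frequency's rows by
        ε̃·sqrt(G'²+G''²) so every frequency contributes equally to the
        objective.  Off by default: unweighted least squares matches the
        plain regression of the identification procedure, and weighting
        changes estimates only under model misspecification.

    Notes
    -----
    Solved by orthogonal (QR) decomposition.  The coefficient covariance
    is s²(XᵀX)⁻¹ with s² = SSR/(n − p).
    """
    X, y = design_terms(model, sampled)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more than {p} rows to fit {model.name}, got {n}")
    uses_second_deriv = {"epsilon_ddot", "sigma_ddot"} & set(model.terms)
    if uses_second_deriv and sampled.frequencies.size < 3:
        raise CollinearDesignError(
            f"{model.name} includes second-derivative terms; at a single "
            "frequency ε̈ ∝ ε and σ̈ ∝ σ, so at least 3 distinct "
            f"frequencies are required (got {sampled.frequencies.size})"
        )
    if normalize_per_frequency:
        w = _per_frequency_scale(sampled)
        X = X / w[:, None]
        y = y / w

    cond = float(np.linalg.cond(X))
    if cond > CONDITION_WARN:
        warnings.warn(
            f"effects matrix for {model.name} has condition number "
            f"{cond:.2e} (> {CONDITION_WARN:.0e}); coefficient estimates "
            "may be unstable",
            IllConditionedWarning,
            stacklevel=2,
        )
    k, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        norms = np.linalg.norm(X, axis=0)
        raise CollinearDesignError(
            f"effects matrix for {model.name} is rank deficient "
            f"(rank {rank} < {p}); columns {model.terms} with norms "
            f"{norms.round(3).tolist()} are linearly dependent — single-"
            "frequency data makes ε̈ ∝ ε and σ̈ ∝ σ"
        )
    predicted = X @ k
    residuals = y - predicted
    ssr = float(residuals @ residuals)
    sst = float(y @ y)
    r2 = 1.0 - ssr / sst
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    s2 = ssr / (n - p)
    # covariance via the R factor of the thin QR decomposition
    _, R = np.linalg.qr(X)
    Rinv = np.linalg.solve(R, np.eye(p))
    cov = s2 * (Rinv @ Rinv.T)
    if normalize_per_frequency:
        # report residuals/prediction on the original stress scale
        predicted = predicted * w
        residuals = residuals * w
        y = y * w
    return RegressionResult(
        model_name=model.name,
        terms=model.terms,
        k=k,
        k_covariance=cov,
        r2=r2,
        adj_r2=adj_r2,
        n_obs=n,
        residuals=residuals,
        predicted=predicted,
        observed=y,
        condition_number=cond,
    )


def fit_and_invert(
    sampled: SampledResponse,
    model: ConstitutiveModel,
    normalize_per_frequency: bool = False,
) -> tuple[RegressionResult, MaterialParameters]:
    """Convenience: regression followed by closed-form parameter inversion."""
    res = fit_model(sampled, model, normalize_per_frequency)
    return res, invert_parameters(model, res.k, res.k_covariance)


def benchmark_models(
    sampled: SampledResponse,
    models: Sequence[ConstitutiveModel] | None = None,
    tie_tolerance: float = 0.002,
    normalize_per_frequency: bool = False,
) -> ModelRanking:
    """Fit every candidate model and rank degeneracy classes.

    One fit is performed per degeneracy class (members share identical
    design columns).  Ranking is by adjusted R² descending.  Selection
    applies parsimony: among classes within ``tie_tolerance`` of the best
    adjusted R², the one with the fewest spring–dashpot elements is
    chosen; remaining ties break on residual SD.
    """
    classes = degeneracy_classes(models if models is not None
                                 else list(REGISTRY.values()))
    entries: list[RankingEntry] = []
    results: dict[str, RegressionResult] = {}
    failures: dict[str, str] = {}
    for cls, members in classes.items():
        rep = members[0]
        try:
            res = fit_model(sampled, rep, normalize_per_frequency)
        except (CollinearDesignError, ValueError) as exc:
            failures[cls] = str(exc)
            continue
        results[cls] = res
        entries.append(RankingEntry(
            model_or_class=cls,
            member_names=tuple(m.name for m in members),
            adj_r2=res.adj_r2,
            r2=res.r2,
            residual_sd=res.residual_sd,
            n_params=rep.n_params,
        ))
    if not entries:
        raise RuntimeError(
            "no candidate model could be fitted: "
            + "; ".join(f"{k}: {v}" for k, v in failures.items())
        )
    entries.sort(key=lambda e: -e.adj_r2)
    best = entries[0].adj_r2
    contenders = [e for e in entries if best - e.adj_r2 <= tie_tolerance]
    selected = min(contenders, key=lambda e: (e.n_params, e.residual_sd))
    return ModelRanking(
        entries=tuple(entries),
        selected=selected.model_or_class,
        tie_tolerance=tie_tolerance,
        results=results,
        failures=failures,
    )


def residual_summary(
    results: Sequence[RegressionResult],
    bins: int = 20,
) -> list[dict]:
    """Residual-distribution comparison across fitted models.

    Returns one record per model, ordered by residual SD ascending (the
    narrowest residual distribution marks the smallest deviations between
    calculated and measured stress).  Histograms share a symmetric range
    across models so their widths are directly comparable.
    """
    if not results:
        raise ValueError("need at least one regression result")
    span = max(float(np.max(np.abs(r.residuals))) for r in results)
    span = span if span > 0 else 1.0
    edges = np.linspace(-span, span, bins + 1)
    out = []
    for r in sorted(results, key=lambda r: r.residual_sd):
        counts, _ = np.histogram(r.residuals, bins=edges)
        if r.residuals.size >= 8 and r.residual_sd > 0:
            stat, pval = stats.normaltest(r.residuals)
        else:
            stat, pval = float("nan"), float("nan")
        out.append({
            "model_name": r.model_name,
            "residual_sd": r.residual_sd,
            "bin_edges": edges,
            "counts": counts,
            "normality_stat": float(stat),
            "normality_p": float(pval),
        })
    return out


def observed_vs_predicted(result: RegressionResult
                          ) -> tuple[np.ndarray, np.ndarray, float]:
    """Measured vs calculated stress pairs, plus the through-origin slope.

    A perfect description puts every pair on y = x, so the slope of the
    through-origin regression of calculated on measured equals 1.
    """
    measured = result.observed
    calculated = result.predicted
    slope = float(np.mean(calculated * measured) / np.mean(measured ** 2))
    return measured, calculated, slope


def bootstrap_parameters(
    sampled: SampledResponse,
    model: ConstitutiveModel,
    n_boot: int = 500,
    seed: int | None = None,
) -> MaterialParameters:
    """Residual-bootstrap alternative to delta-method standard errors.

    Resamples regression residuals with replacement, refits, and inverts;
    reports the point estimate from the original fit with bootstrap SDs.
    """
    res = fit_model(sampled, model)
    X, _ = design_terms(model, sampled)
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_boot):
        y_star = res.predicted + rng.choice(res.residuals, size=res.n_obs)
        k_star, *_ = np.linalg.lstsq(X, y_star, rcond=None)
        try:
            draws.append(model.params_from_k(k_star))
        except ValueError:
            continue
    point = invert_parameters(model, res.k)
    sds = np.std(np.array(draws), axis=0) if draws else \
        np.full(model.n_params, np.nan)
    values = {s: (point.estimate(s), float(sd))
              for s, sd in zip(model.param_names, sds)}
    return MaterialParameters(model_name=model.name, values=values,
                              physical=point.physical)
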