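"""Bootstrap standard errors and significance summaries.

The direct-effect estimator is built from an SVD projection, so no closed
form for its sampling variance exists; standard errors come from a
residual bootstrap tailored to beta values.  Residuals are first
standardized by sqrt(μ(1−μ)) — the mean–variance relation of a beta
distribution — then whole *columns* (samples) are resampled with
replacement, preserving the correlation of errors across CpGs, and the
draws are rescaled by the un-resampled means.  Refitting the entire
pipeline on each pseudo-dataset at the chosen latent dimension and taking
entrywise standard deviations yields the standard errors; the same
machinery drives an array-wide omnibus test of the target covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .linear_core import (
    DesignMatrix,
    DirectEffectEstimate,
    MethylationMatrix,
    UnadjustedFit,
    estimate_direct_effects,
    fit_unadjusted,
    ols_standard_errors,
)

__all__ = [
    "BootstrapSpec",
    "InferenceResult",
    "standardize_residuals",
    "make_bootstrap_sample",
    "bootstrap_standard_errors",
    "wald_summaries",
    "qvalue_summaries",
    "omnibus_test",
]


@dataclass
class BootstrapSpec:
    """Bootstrap control knobs.

    replicates: number of bootstrap datasets R (250–500 is typical).
    seed: master seed for the resampling stream.
    clamp_epsilon: fitted means are clamped to [ε, 1−ε] before the
        sqrt(μ(1−μ)) standardization, so means that drift outside (0, 1)
        under the linear fit still standardize finitely.
    """

    replicates: int = 250
    seed: int = 0
    clamp_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        if not (0.0 < self.clamp_epsilon < 0.5):
            raise ValueError("clamp_epsilon must lie in (0, 0.5)")


@dataclass
class InferenceResult:
    se_direct: np.ndarray
    se_unadjusted: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray | None
    pi0: np.ndarray | None
    omnibus_p: float | None
    direct_effects: np.ndarray
    unadjusted: np.ndarray
    dimension_used: int
    n_replicates: int


def _clamped_scale(fitted: np.ndarray, eps: float) -> np.ndarray:
    mu = np.clip(fitted, eps, 1.0 - eps)
    return np.sqrt(mu * (1.0 - mu))


def standardize_residuals(fit: UnadjustedFit, clamp_epsilon: float = 1e-6) -> np.ndarray:
    """Divide each residual by sqrt(μ̃(1−μ̃)) of its clamped fitted mean."""
    if not (0.0 < clamp_epsilon < 0.5):
        raise ValueError("clamp_epsilon must lie in (0, 0.5)")
    return fit.residuals / _clamped_scale(fit.fitted_means, clamp_epsilon)


def make_bootstrap_sample(
    fit: UnadjustedFit,
    standardized: np.ndarray,
    rng: np.random.Generator,
    clamp_epsilon: float = 1e-6,
    indices: np.ndarray | None = None,
) -> MethylationMatrix:
    """One bootstrap pseudo-dataset Y* = M̂ + resampled, rescaled errors.

    Columns of the standardized residual matrix are drawn with replacement
    and rescaled by sqrt(μ̃(1−μ̃)) of the *un-resampled* fitted means.
    Missingness travels with the resampled columns, and Y* is deliberately
    not clipped to [0, 1] (the refit is linear; clipping would bias means).
    """
    m, n = standardized.shape
    if indices is None:
        indices = rng.integers(0, n, size=n)
    estar = standardized[:, indices]
    values = fit.fitted_means + estar * _clamped_scale(fit.fitted_means, clamp_epsilon)
    return MethylationMatrix(
        values=values,
        cpg_ids=[f"cpg{j}" for j in range(m)],
        sample_ids=[f"s{i}" for i in range(n)],
        check_range=False,
    )


def bootstrap_standard_errors(
    Y: MethylationMatrix,
    X: DesignMatrix,
    d: int,
    spec: BootstrapSpec,
    compute_qvalues: bool = True,
    omnibus_covariate: int | None = None,
) -> InferenceResult:
    """Bootstrap SEs for Δ̂ and B̃, with Wald and q-value summaries.

    Each replicate resamples residual columns, refits the unadjusted model
    and recomputes the SVD projection at the *same* dimension d; SEs are
    entrywise standard deviations over replicates.  ``se_unadjusted`` from
    the bootstrap is also returned for B̃.  Deterministic given spec.seed.
    """
    fit, decomp, est = estimate_direct_effects(Y, X, d)
    standardized = standardize_residuals(fit, spec.clamp_epsilon)
    rng = np.random.default_rng(spec.seed)

    m, p = fit.coefficients.shape
    R = spec.replicates
    boot_direct = np.empty((R, m, p))
    boot_unadj = np.empty((R, m, p))
    failures = 0
    for r in range(R):
        Ystar = make_bootstrap_sample(fit, standardized, rng, spec.clamp_epsilon)
        try:
            _, _, est_r = estimate_direct_effects(Ystar, X, d)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            boot_direct[r] = np.nan
            boot_unadj[r] = np.nan
            if failures > 0.1 * R:
                raise RuntimeError(
                    f"{failures} of {r + 1} bootstrap replicates failed"
                )
            continue
        boot_direct[r] = est_r.direct_effects
        boot_unadj[r] = est_r.unadjusted

    se_direct = np.nanstd(boot_direct, axis=0, ddof=1)
    se_unadjusted = np.nanstd(boot_unadj, axis=0, ddof=1)

    z, p_values = wald_summaries(est, se_direct)
    q_values = pi0 = None
    if compute_qvalues:
        q_values = np.full_like(p_values, np.nan)
        pi0 = np.full(p, np.nan)
        for c in range(p):
            if c == X.intercept_column:
                continue
            pc = p_values[:, c]
            ok = ~np.isnan(pc)
            if ok.sum() >= 2:
                q_values[ok, c], pi0[c] = qvalue_summaries(pc[ok])

    omnibus_p = None
    if omnibus_covariate is not None:
        omnibus_p = omnibus_test(Y, X, d, omnibus_covariate, spec)

    return InferenceResult(
        se_direct=se_direct,
        se_unadjusted=se_unadjusted,
        z=z,
        p_values=p_values,
        q_values=q_values,
        pi0=pi0,
        omnibus_p=omnibus_p,
        direct_effects=est.direct_effects,
        unadjusted=est.unadjusted,
        dimension_used=d,
        n_replicates=R,
    )


def wald_summaries(
    est: DirectEffectEstimate | np.ndarray, se: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided normal Wald z and p for estimate/SE; SE = 0 yields NaN."""
    effects = est.direct_effects if isinstance(est, DirectEffectEstimate) else est
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, effects / se, np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def qvalue_summaries(p_values: np.ndarray, lambdas: np.ndarray | None = None,
                     pi0_method: str = "smoother") -> tuple[np.ndarray, float]:
    """Storey q-values with smoothed π₀ estimation.

    π̂₀(λ) = #{p > λ} / (m(1−λ)) is evaluated on λ ∈ {0.05, …, 0.95},
    smoothed by a cubic polynomial and read off at λ = 0.95 (or taken at a
    fixed λ = 0.5 with ``pi0_method='fixed'``), truncated to (0, 1]; then
    q_j = min over p ≥ p_j of π̂₀·m·p/rank(p), monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    if np.isnan(p).any():
        raise ValueError("p values must not be missing")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)

    if pi0_method == "fixed":
        lam = 0.5
        pi0 = (p > lam).sum() / (m * (1.0 - lam))
    else:
        pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lambdas])
        coef = np.polynomial.polynomial.polyfit(lambdas, pi0_lam, deg=3)
        pi0 = float(np.polynomial.polynomial.polyval(lambdas[-1], coef))
    pi0 = float(min(max(pi0, 1.0 / m), 1.0))

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, pi0


def omnibus_test(
    Y: MethylationMatrix,
    X: DesignMatrix,
    d: int,
    target_covariate: int,
    spec: BootstrapSpec,
    statistic: str = "mean_sq",
) -> float:
    """Array-wide bootstrap test: does the target covariate affect anything?

    The observed statistic is the mean over CpGs of Δ̂²(target) (or
    max |Δ̂| with ``statistic='max_abs'``).  Null pseudo-datasets are built
    by the column bootstrap around fitted means from a *null* refit with
    the target covariate removed, so the resampled data carry no target
    effect; the full model is then re-estimated on each and p is the
    exceedance rank (1 + #{T* ≥ T}) / (R + 1).
    """
    if target_covariate == X.intercept_column:
        raise ValueError("cannot run the omnibus test on the intercept")
    p_cols = X.n_covariates

    def stat(effects: np.ndarray) -> float:
        col = effects[:, target_covariate]
        if statistic == "mean_sq":
            return float(np.mean(col**2))
        if statistic == "max_abs":
            return float(np.max(np.abs(col)))
        raise ValueError(f"unknown statistic {statistic!r}")

    _, _, est = estimate_direct_effects(Y, X, d)
    t_obs = stat(est.direct_effects)

    keep = [c for c in range(p_cols) if c != target_covariate]
    X0 = DesignMatrix(
        values=X.values[:, keep],
        column_names=[X.column_names[c] for c in keep],
        intercept_column=keep.index(X.intercept_column),
    )
    fit0 = fit_unadjusted(Y, X0)
    standardized0 = standardize_residuals(fit0, spec.clamp_epsilon)

    rng = np.random.default_rng(spec.seed)
    R = spec.replicates
    exceed = 0
    failures = 0
    for r in range(R):
        Ystar = make_bootstrap_sample(fit0, standardized0, rng, spec.clamp_epsilon)
        try:
            _, _, est_r = estimate_direct_effects(Ystar, X, d)
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            if failures > 0.1 * R:
                raise RuntimeError(f"{failures} of {r + 1} null replicates failed")
            continue
        if stat(est_r.direct_effects) >= t_obs:
            exceed += 1
    n_ok = R - failures
    return (1.0 + exceed) / (n_ok + 1.0)


def asymptotic_unadjusted_se(fit: UnadjustedFit) -> np.ndarray:
    """Alias for the standard linear-model SEs of the unadjusted fit."""
    return ols_standard_errors(fit)
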