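"""Per-CpG linear models and the reference-free direct-effect estimator.

The estimator targets the *direct* effect of a covariate on DNA methylation,
i.e. the part of the association that is not mediated by shifts in the
tissue's cell-type composition.  It works entirely on the beta-value scale
(methylated fraction, in [0, 1]), where cell mixing is linear:

1. fit the ordinary unadjusted per-CpG regression ``Y = B Xᵀ + E``;
2. take the thin SVD of the concatenation ``[B̃ | Ẽ]`` of coefficient and
   residual matrices and keep the leading ``d`` left-singular directions as
   a CpG-space loading matrix ``Λ`` (these span the cell-type methylation
   signatures plus any other latent factor structure);
3. report ``Δ̂ = B̃ − Λ(ΛᵀΛ)⁻¹ΛᵀB̃``, the residual of projecting the
   unadjusted coefficients onto the latent loadings.

No reference methylome panel for purified cell types is needed at any step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MethylationMatrix",
    "DesignMatrix",
    "UnadjustedFit",
    "LatentDecomposition",
    "DirectEffectEstimate",
    "fit_unadjusted",
    "concat_and_decompose",
    "impute_loadings_for_incomplete_rows",
    "direct_effects",
    "estimate_direct_effects",
    "ols_standard_errors",
]


@dataclass
class MethylationMatrix:
    """m×n matrix of beta values; rows are CpG loci, columns are samples.

    Missing entries are stored as NaN.  ``check_range`` is disabled for
    bootstrap pseudo-data, which is deliberately not clipped to [0, 1].
    """

    values: np.ndarray
    cpg_ids: list[str]
    sample_ids: list[str]
    check_range: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        m, n = self.values.shape
        self.cpg_ids = list(self.cpg_ids)
        self.sample_ids = list(self.sample_ids)
        if len(self.cpg_ids) != m:
            raise ValueError(f"{len(self.cpg_ids)} cpg_ids for {m} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} columns")
        if len(set(self.cpg_ids)) != m:
            raise ValueError("duplicate CpG identifiers")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers")
        if self.check_range:
            obs = self.values[~np.isnan(self.values)]
            if obs.size and (obs.min() < 0.0 or obs.max() > 1.0):
                raise ValueError("observed beta values must lie in [0, 1]")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DesignMatrix:
    """n×p covariate matrix with an all-ones intercept column."""

    values: np.ndarray
    column_names: list[str]
    intercept_column: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design must be 2-D")
        n, p = self.values.shape
        self.column_names = list(self.column_names)
        if len(self.column_names) != p:
            raise ValueError("column_names length mismatch")
        if not (0 <= self.intercept_column < p):
            raise ValueError("intercept_column out of range")
        if not np.allclose(self.values[:, self.intercept_column], 1.0):
            raise ValueError("intercept column must be all ones")
        if np.linalg.matrix_rank(self.values) < p:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]


@dataclass
class UnadjustedFit:
    """Row-wise OLS fit of beta values on the design.

    ``coefficients`` is B̃ (m×p), ``residuals`` Ẽ (m×n, NaN where the data
    were missing) and ``fitted_means`` M̂ = B̃Xᵀ materialised at *every*
    position including missing ones — the bootstrap needs full means.
    """

    coefficients: np.ndarray
    residuals: np.ndarray
    fitted_means: np.ndarray
    complete_rows: np.ndarray
    design: DesignMatrix


@dataclass
class LatentDecomposition:
    """Rank-d factorisation of the concatenated matrix [B̃ | Ẽ].

    ``loadings`` (Λ, m×d) carry the singular values; ``factors`` are the
    orthonormal right-singular directions over the p+n concatenated columns.
    Rows not covered by the SVD (incomplete rows before imputation) are NaN.
    """

    loadings: np.ndarray
    factors: np.ndarray
    singular_values: np.ndarray
    d: int
    rows_used: np.ndarray


@dataclass
class DirectEffectEstimate:
    direct_effects: np.ndarray
    dimension_used: int
    unadjusted: np.ndarray


def _row_ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS coefficients of one response vector on X (least-squares solve)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_unadjusted(Y: MethylationMatrix, X: DesignMatrix) -> UnadjustedFit:
    """Fit the unadjusted per-CpG model Y = B Xᵀ + E by row-wise OLS.

    Rows with missing samples are fitted by complete-case OLS on their
    observed columns.  Every row must retain at least p+1 observed samples
    (one residual degree of freedom) and a full-rank observed design.
    """
    vals = Y.values
    m, n = vals.shape
    Xm = X.values
    p = X.n_covariates
    if n != X.n_samples:
        raise ValueError("sample count mismatch between Y and X")
    if n <= p:
        raise ValueError("need more samples than covariates")

    missing = np.isnan(vals)
    complete = ~missing.any(axis=1)

    B = np.empty((m, p))
    if complete.any():
        # all complete rows share the same design: one vectorised solve
        B[complete] = np.linalg.lstsq(Xm, vals[complete].T, rcond=None)[0].T
    for j in np.flatnonzero(~complete):
        obs = ~missing[j]
        n_obs = int(obs.sum())
        if n_obs < p + 1:
            raise ValueError(
                f"row {Y.cpg_ids[j]!r} has {n_obs} observed samples; "
                f"need at least {p + 1}"
            )
        Xo = Xm[obs]
        if np.linalg.matrix_rank(Xo) < p:
            raise ValueError(
                f"design rank-deficient on observed samples of row {Y.cpg_ids[j]!r}"
            )
        B[j] = _row_ols(vals[j, obs], Xo)

    fitted = B @ Xm.T
    resid = vals - fitted  # NaN propagates to missing positions
    return UnadjustedFit(
        coefficients=B,
        residuals=resid,
        fitted_means=fitted,
        complete_rows=complete,
        design=X,
    )


def _concat(fit: UnadjustedFit) -> np.ndarray:
    return np.hstack([fit.coefficients, fit.residuals])


def concat_and_decompose(fit: UnadjustedFit, d: int) -> LatentDecomposition:
    """Thin SVD of [B̃ | Ẽ] over completely observed rows, truncated at d.

    No centering or scaling is applied: the intercept column of B̃
    deliberately carries the mean methylation structure.  Loadings are
    U_d·diag(s_d); the sign of each singular triple is fixed so that the
    largest-magnitude loading entry is positive (backend-independent).
    """
    if d < 0:
        raise ValueError("d must be nonnegative")
    Z = _concat(fit)
    m, c = Z.shape
    complete = fit.complete_rows
    n_complete = int(complete.sum())
    p = fit.coefficients.shape[1]
    if n_complete < max(d, p + 1):
        raise ValueError("too few completely observed rows for the SVD")

    Zc = Z[complete]
    loadings = np.full((m, d), np.nan)
    if d == 0:
        loadings[complete] = np.empty((n_complete, 0))
        return LatentDecomposition(
            loadings=loadings,
            factors=np.empty((c, 0)),
            singular_values=np.empty(0),
            d=0,
            rows_used=complete.copy(),
        )

    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    tol = s[0] * max(Zc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if d > rank:
        raise ValueError(f"d={d} exceeds the rank ({rank}) of [B|E]")
    U, s, Vt = U[:, :d], s[:d], Vt[:d]
    # deterministic sign: largest-|.| entry of each left-singular vector > 0
    flip = np.sign(U[np.abs(U).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    U *= flip
    Vt *= flip[:, None]
    loadings[complete] = U * s
    return LatentDecomposition(
        loadings=loadings,
        factors=Vt.T,
        singular_values=s,
        d=d,
        rows_used=complete.copy(),
    )


def impute_loadings_for_incomplete_rows(
    fit: UnadjustedFit, decomp: LatentDecomposition
) -> LatentDecomposition:
    """Fill in loadings for rows excluded from the SVD.

    Each incomplete row's observed concatenated entries [b̃ | ẽ_observed]
    are regressed on the corresponding rows of the factor matrix; because
    the factors are orthonormal, for a complete row this regression
    reproduces the SVD loading exactly.
    """
    Z = _concat(fit)
    d = decomp.d
    F = decomp.factors
    loadings = decomp.loadings.copy()
    for j in np.flatnonzero(~decomp.rows_used):
        obs = ~np.isnan(Z[j])
        n_obs = int(obs.sum())
        if n_obs < d:
            raise ValueError(
                f"row {j} has {n_obs} observed concatenated entries; need >= d={d}"
            )
        if d == 0:
            loadings[j] = np.empty(0)
            continue
        lam, *_ = np.linalg.lstsq(F[obs], Z[j, obs], rcond=None)
        loadings[j] = lam
    return LatentDecomposition(
        loadings=loadings,
        factors=F,
        singular_values=decomp.singular_values,
        d=d,
        rows_used=np.ones(Z.shape[0], dtype=bool),
    )


def direct_effects(
    fit: UnadjustedFit, decomp: LatentDecomposition
) -> DirectEffectEstimate:
    """Direct-effect estimate Δ̂ = B̃ − Λ(ΛᵀΛ)⁻¹ΛᵀB̃.

    The projection is computed through a thin QR factorisation of Λ rather
    than the normal-equations inverse; by the estimator's scale-invariance
    (Δ̂ is unchanged under Λ → Λ·R for invertible R) the answer is the
    same, with better conditioning.
    """
    B = fit.coefficients
    L = decomp.loadings
    if np.isnan(L).any():
        raise ValueError(
            "loadings do not cover all rows; run impute_loadings_for_incomplete_rows"
        )
    if decomp.d == 0:
        return DirectEffectEstimate(
            direct_effects=B.copy(), dimension_used=0, unadjusted=B.copy()
        )
    sv = np.linalg.svd(L, compute_uv=False)
    if sv[-1] <= sv[0] * max(L.shape) * np.finfo(float).eps:
        raise ValueError("loading columns are collinear at working precision")
    Q, _ = np.linalg.qr(L)
    delta = B - Q @ (Q.T @ B)
    return DirectEffectEstimate(
        direct_effects=delta, dimension_used=decomp.d, unadjusted=B.copy()
    )


def estimate_direct_effects(
    Y: MethylationMatrix, X: DesignMatrix, d: int
) -> tuple[UnadjustedFit, LatentDecomposition, DirectEffectEstimate]:
    """Full estimation pass: row OLS → concatenated SVD → projection residual.

    Imputes loadings for incomplete rows when Y has missing entries, so the
    returned decomposition covers all m rows.
    """
    fit = fit_unadjusted(Y, X)
    decomp = concat_and_decompose(fit, d)
    if not decomp.rows_used.all():
        decomp = impute_loadings_for_incomplete_rows(fit, decomp)
    est = direct_effects(fit, decomp)
    return fit, decomp, est


def ols_standard_errors(fit: UnadjustedFit) -> np.ndarray:
    """Textbook asymptotic OLS standard errors, per row and covariate.

    Uses the row's residual variance with n_obs − p degrees of freedom and
    the observed-sample (XᵀX)⁻¹.  These are the standard errors an
    unadjusted EWAS would report for B̃.
    """
    X = fit.design.values
    n, p = X.shape
    m = fit.coefficients.shape[0]
    resid = fit.residuals
    missing = np.isnan(resid)
    se = np.empty((m, p))
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    complete = ~missing.any(axis=1)
    if complete.any():
        s2 = (resid[complete] ** 2).sum(axis=1) / (n - p)
        se[complete] = np.sqrt(np.outer(s2, xtx_inv_diag))
    for j in np.flatnonzero(~complete):
        obs = ~missing[j]
        Xo = X[obs]
        dof = int(obs.sum()) - p
        s2 = np.nansum(resid[j] ** 2) / dof
        se[j] = np.sqrt(s2 * np.diag(np.linalg.inv(Xo.T @ Xo)))
    return se
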