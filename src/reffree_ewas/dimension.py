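"""Latent-dimension selection for the concatenated matrix [B̃ | Ẽ].

The default estimator is the random-matrix-theory (RMT) rule popularised in
surrogate-variable analysis: standardize each row, take the eigenvalues of
the column-space sample correlation matrix, and count how many exceed the
upper edge of the Marchenko–Pastur null spectrum.  Information-criterion
(AIC/BIC) selection over a factor-model profile likelihood is provided as a
comparator; it is known to be less reliable here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DimensionEstimate", "est_dim_rmt", "est_dim_ic"]


@dataclass
class DimensionEstimate:
    d: int
    method: str  # "rmt" | "aic" | "bic" | "fixed"
    eigenvalues: np.ndarray
    threshold: float | None = None
    criterion_values: np.ndarray | None = None


def est_dim_rmt(M: np.ndarray) -> DimensionEstimate:
    """Estimate the number of latent factors by Marchenko–Pastur exceedance.

    Rows of the m×c input (m > c ≥ 2, no missing values) are standardized
    to mean 0 and unit variance; the eigenvalues of the c×c sample
    correlation matrix across rows are compared with the null upper edge
    (1 + sqrt(c/m))², and d is the count of eigenvalues above it.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be 2-D")
    m, c = M.shape
    if c < 2:
        raise ValueError("need at least 2 columns")
    if m <= c:
        raise ValueError("need more rows than columns (m > c)")
    if np.isnan(M).any():
        raise ValueError("M must be fully observed; pass complete rows only")

    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0.0):
        raise ValueError("rows with zero variance cannot be standardized")
    Z = (M - mu) / sd

    corr = (Z.T @ Z) / (m - 1)
    eig = np.linalg.eigvalsh(corr)[::-1]
    edge = (1.0 + np.sqrt(c / m)) ** 2
    d = int((eig > edge).sum())
    return DimensionEstimate(d=d, method="rmt", eigenvalues=eig, threshold=edge)


def _profile_loglik(R: np.ndarray) -> float:
    """Gaussian log-likelihood of residuals profiled over a common variance."""
    N = R.size
    s2 = float((R**2).mean())
    s2 = max(s2, np.finfo(float).tiny)
    return -0.5 * N * (np.log(2.0 * np.pi * s2) + 1.0)


def est_dim_ic(M: np.ndarray, d_max: int, criterion: str = "bic") -> DimensionEstimate:
    """Select d by AIC or BIC over truncated-SVD factor models of M.

    For each candidate d the uniqueness residual M − Λ_d F_dᵀ enters a
    profile Gaussian likelihood with the standard factor-model parameter
    count m·d + c·d − d² (plus one variance).
    """
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    M = np.asarray(M, dtype=float)
    m, c = M.shape
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    tol = s[0] * max(m, c) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if d_max > rank:
        raise ValueError(f"d_max={d_max} exceeds matrix rank {rank}")
    N = M.size
    crits = np.empty(d_max + 1)
    for d in range(d_max + 1):
        if d == 0:
            R = M
        else:
            R = M - (U[:, :d] * s[:d]) @ Vt[:d]
        k = m * d + c * d - d * d + 1
        ll = _profile_loglik(R)
        crits[d] = -2.0 * ll + (2.0 * k if criterion == "aic" else k * np.log(N))
    d_best = int(np.argmin(crits))
    return DimensionEstimate(
        d=d_best,
        method=criterion,
        eigenvalues=s[: d_max + 1] ** 2,
        criterion_values=crits,
    )
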