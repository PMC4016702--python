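"""End-to-end analysis pipeline: fit → dimension → estimate → inference.

``run_pipeline`` is the programmatic equivalent of the ``reffree-ewas fit``
command: it reads (or receives) a methylation matrix and covariate table,
chooses the latent dimension, computes the direct-effect estimates with
bootstrap standard errors, and writes a per-CpG results table plus a JSON
run-metadata record.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dimension import DimensionEstimate, est_dim_ic, est_dim_rmt
from .inference import BootstrapSpec, InferenceResult, bootstrap_standard_errors
from .io import read_design, read_methylation, write_results_table
from .linear_core import (
    DesignMatrix,
    MethylationMatrix,
    fit_unadjusted,
)

__all__ = ["AnalysisConfig", "choose_dimension", "run_pipeline"]


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run.

    ``dimension`` is "rmt", "aic", "bic" or a fixed nonnegative integer.
    ``omnibus`` optionally names a covariate for the array-wide test.
    """

    methylation_path: str | Path | None = None
    covariate_path: str | Path | None = None
    covariates: list[str] = field(default_factory=list)
    sample_column: str | None = None
    dimension: str | int = "rmt"
    bootstrap: int = 250
    seed: int = 0
    clamp_epsilon: float = 1e-6
    omnibus: str | None = None
    out_prefix: str | Path | None = None


def choose_dimension(
    Y: MethylationMatrix, X: DesignMatrix, policy: str | int, d_max: int = 20
) -> DimensionEstimate:
    """Apply the configured dimension policy to [B̃ | Ẽ] (complete rows)."""
    if isinstance(policy, int) or (isinstance(policy, str) and policy.isdigit()):
        d = int(policy)
        if d < 0:
            raise ValueError("fixed dimension must be nonnegative")
        return DimensionEstimate(d=d, method="fixed", eigenvalues=np.empty(0))
    fit = fit_unadjusted(Y, X)
    Z = np.hstack([fit.coefficients, fit.residuals])[fit.complete_rows]
    if policy in ("rmt", "auto"):
        return est_dim_rmt(Z)
    if policy in ("aic", "bic"):
        return est_dim_ic(Z, d_max=min(d_max, min(Z.shape) - 1), criterion=policy)
    raise ValueError(f"unknown dimension policy {policy!r}")


def run_pipeline(
    config: AnalysisConfig,
    Y: MethylationMatrix | None = None,
    X: DesignMatrix | None = None,
) -> InferenceResult:
    """Run the full reference-free EWAS analysis.

    Inputs may be given in memory or as paths in ``config``; when
    ``config.out_prefix`` is set, writes ``<prefix>_results.tsv`` and
    ``<prefix>_run.json``.
    """
    if Y is None:
        if config.methylation_path is None:
            raise ValueError("no methylation data provided")
        Y = read_methylation(config.methylation_path)
    if X is None:
        if config.covariate_path is None:
            raise ValueError("no covariate table provided")
        X = read_design(
            config.covariate_path,
            Y.sample_ids,
            config.covariates,
            sample_column=config.sample_column,
        )

    dim = choose_dimension(Y, X, config.dimension)
    omnibus_idx = None
    if config.omnibus is not None:
        omnibus_idx = X.column_names.index(config.omnibus)
    spec = BootstrapSpec(
        replicates=config.bootstrap,
        seed=config.seed,
        clamp_epsilon=config.clamp_epsilon,
    )
    result = bootstrap_standard_errors(
        Y, X, dim.d, spec, compute_qvalues=True, omnibus_covariate=omnibus_idx
    )

    if config.out_prefix is not None:
        prefix = Path(config.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        write_results_table(
            f"{prefix}_results.tsv",
            Y.cpg_ids,
            X,
            result.direct_effects,
            result.unadjusted,
            se=result.se_direct,
            z=result.z,
            p=result.p_values,
            q=result.q_values,
        )
        n_incomplete = int(Y.missing_mask.any(axis=1).sum())
        meta = {
            "version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "m_cpgs": Y.shape[0],
            "n_samples": Y.shape[1],
            "covariates": X.column_names,
            "dimension": dim.d,
            "dimension_method": dim.method,
            "bootstrap_replicates": spec.replicates,
            "seed": spec.seed,
            "clamp_epsilon": spec.clamp_epsilon,
            "rows_with_missing_values": n_incomplete,
            "imputed_loading_rows": n_incomplete,
            "pi0": None if result.pi0 is None else [
                None if np.isnan(v) else float(v) for v in result.pi0
            ],
            "omnibus_covariate": config.omnibus,
            "omnibus_p": result.omnibus_p,
        }
        with open(f"{prefix}_run.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return result
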