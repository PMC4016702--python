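"""Delimited-text readers and writers for methylation and covariate tables.

Methylation matrices: header row of sample identifiers, first column of CpG
identifiers, entries in [0, 1] with "NA"/empty for missing.  Covariate
tables: one row per sample, joined to the matrix by sample identifier (not
column order).  CSV and TSV are auto-detected from the header line.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .linear_core import DesignMatrix, MethylationMatrix

__all__ = [
    "read_methylation",
    "write_methylation",
    "read_design",
    "write_results_table",
]

_NA_TOKENS = ["NA", "NaN", "nan", ""]


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_methylation(path: str | Path) -> MethylationMatrix:
    """Read a CpG × sample beta-value matrix from delimited text."""
    sep = _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=_NA_TOKENS, keep_default_na=False
    )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate CpG identifiers: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in header")
    values = df.to_numpy(dtype=float)
    bad = np.argwhere((values < 0.0) | (values > 1.0))
    if bad.size:
        j, i = bad[0]
        raise ValueError(
            f"beta value {values[j, i]} out of [0, 1] at CpG "
            f"{df.index[j]!r}, sample {df.columns[i]!r}"
        )
    return MethylationMatrix(
        values=values,
        cpg_ids=[str(c) for c in df.index],
        sample_ids=[str(s) for s in df.columns],
    )


def write_methylation(Y: MethylationMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(Y.values, index=Y.cpg_ids, columns=Y.sample_ids)
    df.to_csv(path, sep=sep, na_rep="NA")


def read_design(
    path: str | Path,
    sample_ids: list[str],
    covariates: list[str],
    sample_column: str | None = None,
) -> DesignMatrix:
    """Read a covariate table and build an intercept + covariates design.

    Rows are matched to ``sample_ids`` by identifier (first column unless
    ``sample_column`` names another), so file order is irrelevant; every
    sample in the matrix must appear exactly once.
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, na_values=_NA_TOKENS, keep_default_na=False)
    key = sample_column or df.columns[0]
    if key not in df.columns:
        raise ValueError(f"sample column {key!r} not found")
    df[key] = df[key].astype(str)
    if df[key].duplicated().any():
        raise ValueError("duplicate sample identifiers in covariate table")
    df = df.set_index(key)
    missing = [s for s in sample_ids if s not in df.index]
    if missing:
        raise ValueError(f"covariates missing for samples: {missing[:5]}")
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"covariate column {c!r} not found")
    sub = df.loc[sample_ids, covariates].apply(pd.to_numeric)
    if sub.isna().any().any():
        raise ValueError("missing covariate values are not supported")
    values = np.column_stack([np.ones(len(sample_ids)), sub.to_numpy(dtype=float)])
    return DesignMatrix(values=values, column_names=["intercept", *covariates])


def write_results_table(
    path: str | Path,
    cpg_ids: list[str],
    design: DesignMatrix,
    estimates: np.ndarray,
    unadjusted: np.ndarray,
    se: np.ndarray | None = None,
    z: np.ndarray | None = None,
    p: np.ndarray | None = None,
    q: np.ndarray | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Per-CpG results: one (estimate, se, z, p, q) block per covariate."""
    cols: dict[str, np.ndarray] = {}
    for c, name in enumerate(design.column_names):
        if c == design.intercept_column:
            continue
        cols[f"{name}_estimate"] = estimates[:, c]
        for label, block in (("se", se), ("z", z), ("p", p), ("q", q)):
            if block is not None:
                cols[f"{name}_{label}"] = block[:, c]
        cols[f"{name}_unadjusted"] = unadjusted[:, c]
    df = pd.DataFrame(cols, index=pd.Index(cpg_ids, name="cpg_id"))
    df.to_csv(path, sep=sep, na_rep="NA")
    return df
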