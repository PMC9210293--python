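"""Readers and writers for labeled delimited matrices and fit artifacts.

Matrices travel as delimited text (TSV by default, comma accepted): first
row holds column labels, first column holds row labels.  Default
orientation is samples in rows; a genes-in-rows flag transposes on read.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CovariateMatrix,
    ExpressionMatrix,
    FitResult,
    InvalidInputError,
)

logger = logging.getLogger("remlvc")


@dataclass
class RunConfig:
    """Configuration of one command-line fit run."""

    expression: str
    covariates: str | None = None
    rho: float = 0.5
    theta: float = 0.0
    genes_in_rows: bool = False
    delimiter: str | None = None
    seed: int = 0
    out: str = "remlvc_out"
    verbosity: int = 1

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise InvalidInputError(f"rho must be in (0, 1), got {self.rho}")
        if not 0 <= self.theta < 1:
            raise InvalidInputError(f"theta must be in [0, 1), got {self.theta}")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_matrix(
    path: str | Path,
    genes_in_rows: bool = False,
    delimiter: str | None = None,
) -> pd.DataFrame:
    """Read a labeled matrix from delimited text.

    Returns a DataFrame (rows = samples unless ``genes_in_rows``, in which
    case the file is transposed on read).  Rejects ragged rows, duplicate
    labels, and non-numeric or non-finite cells, naming the offending cell.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise InvalidInputError(f"{path}: malformed (ragged?) delimited matrix: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InvalidInputError(f"{path}: duplicate row label {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise InvalidInputError(f"{path}: duplicate column label {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise InvalidInputError(
            f"{path}: non-numeric or non-finite value {df.iat[i, j]!r} at "
            f"row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    df = numeric.astype(float)
    if genes_in_rows:
        df = df.T
    return df


def read_expression(path, genes_in_rows=False, delimiter=None) -> ExpressionMatrix:
    df = read_matrix(path, genes_in_rows=genes_in_rows, delimiter=delimiter)
    return ExpressionMatrix(
        df.to_numpy(), sample_ids=list(df.index), gene_ids=list(df.columns)
    )


def read_covariates(path, delimiter=None) -> CovariateMatrix:
    df = read_matrix(path, delimiter=delimiter)
    return CovariateMatrix(df.to_numpy(), covariate_ids=list(df.columns))


def write_matrix(values, path, row_labels=None, col_labels=None, row_name="id") -> None:
    """Write a labeled matrix as TSV at full precision."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    nr, nc = values.shape
    df = pd.DataFrame(
        values,
        index=row_labels if row_labels is not None else [f"r{i + 1}" for i in range(nr)],
        columns=col_labels if col_labels is not None else [f"c{j + 1}" for j in range(nc)],
    )
    df.index.name = row_name
    df.to_csv(path, sep="\t", float_format="%.17g")


def save_fit(result: FitResult, outdir: str | Path, sample_ids=None, covariate_ids=None) -> dict:
    """Serialize a FitResult: latent factors, component blocks and the
    variance ledger as TSV, scalars as a JSON sidecar.  Returns the scalar
    summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n, p = result.latent.n, result.latent.p
    samples = sample_ids if sample_ids is not None else [f"sample{i + 1}" for i in range(n)]
    factors = [f"latent_{j + 1}" for j in range(p)]
    write_matrix(result.latent.values, outdir / "latent_factors.tsv",
                 row_labels=samples, col_labels=factors, row_name="sample")
    vc = result.components
    covs = covariate_ids if covariate_ids is not None else [f"cov{i + 1}" for i in range(vc.d)]
    write_matrix(vc.B, outdir / "B.tsv", row_labels=covs, col_labels=covs, row_name="covariate")
    write_matrix(vc.D, outdir / "D.tsv", row_labels=covs, col_labels=factors, row_name="covariate")
    write_matrix(vc.A, outdir / "A.tsv", row_labels=factors, col_labels=factors, row_name="factor")
    write_matrix(result.K_hat, outdir / "K_hat.tsv", row_labels=samples, col_labels=samples,
                 row_name="sample")
    result.variance_ledger.to_csv(outdir / "variance_ledger.tsv", sep="\t", index=False,
                                  float_format="%.17g")
    summary = {
        "sigma2": result.sigma2,
        "loglik": result.loglik,
        "L1": result.loglik_terms[0],
        "L2": result.loglik_terms[1],
        "p": result.p,
        "rho_achieved": result.rho_achieved,
        "effective_rank": result.effective_rank,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
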