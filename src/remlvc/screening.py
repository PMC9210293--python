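"""Known-covariate preprocessing: genotype PCs and variance screening.

When more covariates than samples are available (e.g. SNPs in an eQTL
study), any n linearly independent covariates explain all expression
variance, so covariates must be screened first.  Each candidate is scored
by the variance beta^2 it explains on its own under the single-covariate
model K = beta^2 z z^T + sigma^2 I, and kept only if
beta^2 >= theta * tr(C).  Screening is recommended on genotype principal
components rather than raw SNPs: PCs are linearly independent by
construction and capture population structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .core import CovariateMatrix, InvalidInputError, SampleCovariance, _as_cov_array


@dataclass
class ScreeningReport:
    """Per-candidate variance explained and selection decisions."""

    covariate_ids: list[str]
    beta2: np.ndarray
    fraction: np.ndarray  # beta2 / tr(C)
    selected: np.ndarray  # boolean
    clipped: np.ndarray  # True when z'Cz < sigma2 (nothing to explain)
    theta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariate_ids,
                "beta2": self.beta2,
                "fraction": self.fraction,
                "selected": self.selected,
                "clipped": self.clipped,
            }
        )


def genotype_pcs(G: np.ndarray, k: int, ids: list[str] | None = None):
    """Top-k L2-normalized principal components of a genotype matrix.

    Rows (samples) of G are centered to mean zero, then the first k left
    singular vectors are returned as unit-norm covariate columns, together
    with the fraction of genotype variance each explains.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2:
        raise InvalidInputError("genotype matrix must be 2-dimensional")
    n, s = G.shape
    if not 1 <= k <= min(n, s):
        raise InvalidInputError(f"need 1 <= k <= min(n, s) = {min(n, s)}, got k={k}")
    Gc = G - G.mean(axis=1, keepdims=True)
    U, sv, _ = scipy.linalg.svd(Gc, full_matrices=False)
    total = float(np.sum(sv**2))
    if total <= 0:
        raise InvalidInputError("genotype matrix is constant: no variation to decompose")
    from .core import fix_signs

    pcs = fix_signs(U[:, :k])
    fractions = (sv[:k] ** 2) / total
    labels = ids if ids is not None else [f"PC{i + 1}" for i in range(k)]
    return CovariateMatrix(pcs, covariate_ids=labels), fractions


def single_covariate_variance(C: SampleCovariance | np.ndarray, z: np.ndarray):
    """Analytic ML fit of the single-covariate model K = beta^2 z z^T + sigma^2 I.

    For a unit vector z the likelihood is maximized at
    sigma2 = (tr(C) - z'Cz) / (n - 1) and beta2 = z'Cz - sigma2.  A
    negative beta2 means the covariate explains less than the residual
    variance (the existence condition fails); it is clipped to zero and
    flagged.  Returns (beta2, sigma2, clipped).
    """
    Cv = _as_cov_array(C)
    z = np.asarray(z, dtype=float).ravel()
    n = Cv.shape[0]
    nrm = np.linalg.norm(z)
    if nrm == 0:
        raise InvalidInputError("covariate vector has zero norm")
    if abs(nrm - 1.0) > 1e-8:
        z = z / nrm
    zCz = float(z @ Cv @ z)
    sigma2 = (float(np.trace(Cv)) - zCz) / (n - 1)
    beta2 = zCz - sigma2
    clipped = beta2 < 0
    return max(beta2, 0.0), sigma2, clipped


def screen_covariates(
    C: SampleCovariance | np.ndarray,
    Z_candidates: CovariateMatrix | np.ndarray,
    theta: float,
    raw_snps: bool = False,
):
    """Retain candidate covariates explaining at least theta * tr(C) on
    their own.

    Candidates are L2-normalized and screened independently (one at a
    time); joint redundancy among the survivors is handled downstream by
    the rank tolerance and existence condition.  theta is a fraction of
    tr(C), making the threshold scale-free.  Returns (selected
    CovariateMatrix, ScreeningReport) with candidate order preserved.
    """
    if not 0 <= theta < 1:
        raise InvalidInputError(f"theta must be in [0, 1), got {theta}")
    if raw_snps:
        warnings.warn(
            "screening raw SNPs: collinear markers may be jointly redundant; "
            "screening principal components is recommended",
            stacklevel=2,
        )
    if not isinstance(Z_candidates, CovariateMatrix):
        Z_candidates = CovariateMatrix(np.asarray(Z_candidates, dtype=float))
    Cv = _as_cov_array(C)
    trC = float(np.trace(Cv))
    d = Z_candidates.d
    beta2 = np.zeros(d)
    clipped = np.zeros(d, dtype=bool)
    cols = []
    for j in range(d):
        z = Z_candidates.values[:, j]
        nrm = np.linalg.norm(z)
        if nrm == 0:
            clipped[j] = True
            cols.append(z)
            continue
        cols.append(z / nrm)
        beta2[j], _, clipped[j] = single_covariate_variance(Cv, z)
    selected = beta2 >= theta * trC
    # beta2 == 0 candidates only pass at theta == 0; keep strict positivity
    selected &= beta2 > 0 if theta == 0 else np.ones(d, dtype=bool)
    report = ScreeningReport(
        covariate_ids=list(Z_candidates.covariate_ids),
        beta2=beta2,
        fraction=beta2 / trC if trC > 0 else np.zeros(d),
        selected=selected,
        clipped=clipped,
        theta=theta,
    )
    kept = CovariateMatrix(
        np.column_stack(cols)[:, selected] if d else np.zeros((Z_candidates.n, 0)),
        covariate_ids=[cid for cid, s in zip(Z_candidates.covariate_ids, selected) if s],
    )
    return kept, report
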