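"""Analytic REML solver for latent variance components.

The latent factors of the random-effects model can always be chosen
orthogonal to the known covariates: any overlap is absorbed into the
known-covariate effects by a linear reparameterization of (B, D).  On the
orthogonal complement of span(Z) the log-likelihood decomposes as
L = L1 + L2, where L2 is the probabilistic-PCA likelihood on that
complement.  The solver therefore:

1. splits sample space into span(Z) and its orthogonal complement,
2. runs PPCA on the complement (top eigenvectors of Q2^T C Q2) to get the
   latent factors — the REML estimate,
3. treats the fitted latents as known and recovers B, D, A, sigma^2 by the
   analytic known-covariates solution K = P C P + sigma^2 (I - P), with P
   the projector on span(Z) + span(X).

The number of latent factors p is chosen as the smallest p whose explained
variance reaches the target fraction rho, then raised further if needed so
that the existence condition holds: every retained variance direction must
explain strictly more than the residual sigma^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .core import (
    CovariateMatrix,
    ExistenceError,
    ExpressionMatrix,
    FitResult,
    InvalidInputError,
    LatentFactors,
    SampleCovariance,
    VarianceComponents,
    _as_cov_array,
    build_K,
    center_samples,
    fix_signs,
    log_likelihood,
    sample_covariance,
)

logger = logging.getLogger("remlvc")

RANK_TOL = 1e-10


@dataclass
class SubspaceSplit:
    """Orthogonal decomposition of sample space relative to span(Z).

    Q1 (n x r) spans span(Z) (r = effective rank of Z), Q2 (n x (n-r))
    spans the orthogonal complement; P1 = Q1 Q1^T and P2 = Q2 Q2^T are the
    corresponding projectors with P1 + P2 = I.
    """

    Q1: np.ndarray
    Q2: np.ndarray
    singular_values: np.ndarray
    V_r: np.ndarray  # d x r right singular vectors of Z (for back-substitution)
    d: int

    @property
    def n(self) -> int:
        return self.Q1.shape[0]

    @property
    def r(self) -> int:
        return self.Q1.shape[1]

    @property
    def P1(self) -> np.ndarray:
        return self.Q1 @ self.Q1.T

    @property
    def P2(self) -> np.ndarray:
        return self.Q2 @ self.Q2.T


def subspace_split(Z: CovariateMatrix | np.ndarray, tol: float = RANK_TOL) -> SubspaceSplit:
    """Split sample space into span(Z) and its orthogonal complement.

    Singular values of Z at or below ``tol * s_max`` are dropped, so
    duplicated or near-collinear covariates do not inflate the rank.
    With no covariates (d = 0), Q1 is empty and P2 = I.
    """
    Zv = Z.values if isinstance(Z, CovariateMatrix) else np.asarray(Z, dtype=float)
    if Zv.ndim == 1:
        Zv = Zv[:, None]
    n, d = Zv.shape
    if d == 0 or not np.any(Zv):
        return SubspaceSplit(
            Q1=np.zeros((n, 0)),
            Q2=np.eye(n),
            singular_values=np.zeros(0),
            V_r=np.zeros((d, 0)),
            d=d,
        )
    U, s, Vt = scipy.linalg.svd(Zv, full_matrices=True)
    r = int(np.sum(s > tol * s[0]))
    return SubspaceSplit(
        Q1=U[:, :r],
        Q2=U[:, r:],
        singular_values=s[:r],
        V_r=Vt[:r].T,
        d=d,
    )


def ppca(C: SampleCovariance, p: int):
    """Closed-form probabilistic PCA for K = X A X^T + sigma^2 I.

    The likelihood is maximized by the top-p eigenvectors of C;
    sigma^2 is the mean of the n-p excluded eigenvalues and
    A = diag(lambda_i - sigma^2).  Returns (latent, A, sigma2, K_hat).
    """
    n = C.n
    if not 0 <= p < n:
        raise InvalidInputError(f"need 0 <= p < n, got p={p}, n={n}")
    lam = C.eigenvalues
    sigma2 = float(np.mean(lam[p:]))
    if sigma2 <= 0:
        raise ExistenceError("residual variance would be zero: C has rank <= p")
    if p > 0 and lam[p - 1] <= sigma2:
        raise ExistenceError(
            f"existence condition violated: eigenvalue {p} of C "
            f"({lam[p - 1]:.6g}) does not exceed the residual variance "
            f"({sigma2:.6g}); reduce p"
        )
    V = fix_signs(C.eigenvectors[:, :p])
    A = np.diag(lam[:p] - sigma2)
    K_hat = sigma2 * np.eye(n)
    if p:
        K_hat += (V * (lam[:p] - sigma2)) @ V.T
    return LatentFactors(V), A, sigma2, (K_hat + K_hat.T) / 2.0


def known_covariate_solution(C: SampleCovariance, split: SubspaceSplit):
    """Analytic ML solution for the model with known covariates only,
    K = Z B Z^T + sigma^2 I.

    The optimum has the PPCA form K = P1 C P1 + sigma^2 P2 with P1 the
    projector onto span(Z); B is recovered in the original Z column
    coordinates by back-substitution through the SVD of Z.
    Returns (B_hat, sigma2, K_hat).
    """
    Cv = _as_cov_array(C)
    n, r = split.n, split.r
    if r == 0:
        sigma2 = float(np.trace(Cv)) / n
        if sigma2 <= 0:
            raise ExistenceError("total variance is zero")
        return np.zeros((split.d, split.d)), sigma2, sigma2 * np.eye(n)
    if r >= n:
        raise ExistenceError(
            "known covariates span the whole sample space; residual variance "
            "is undefined (screen or reduce the covariates)"
        )
    C1 = split.Q1.T @ Cv @ split.Q1
    sigma2 = (float(np.trace(Cv)) - float(np.trace(C1))) / (n - r)
    if sigma2 <= 0:
        raise ExistenceError("residual variance would be zero")
    w1 = scipy.linalg.eigvalsh(C1)
    if w1[0] <= sigma2:
        raise ExistenceError(
            f"existence condition violated: principal axis {r} of span(Z) "
            f"explains {w1[0]:.6g} <= residual variance {sigma2:.6g}; "
            "reconsider the relevance or redundancy of the known covariates"
        )
    M = C1 - sigma2 * np.eye(r)
    s_inv = 1.0 / split.singular_values
    B = (split.V_r * s_inv) @ M @ (split.V_r * s_inv).T
    K_hat = split.Q1 @ C1 @ split.Q1.T + sigma2 * split.P2
    return (B + B.T) / 2.0, sigma2, (K_hat + K_hat.T) / 2.0


def restricted_ppca(C: SampleCovariance, split: SubspaceSplit, p: int):
    """PPCA on the orthogonal complement of span(Z): the REML estimate of
    the latent factors.

    Forms C2 = Q2^T C Q2, takes its top-p eigenvectors and maps them back
    to sample space through Q2, so the factors are orthonormal and
    orthogonal to span(Z) by construction.  Returns (latent, spectrum2)
    with spectrum2 the full nonincreasing spectrum of C2.
    """
    n, r = split.n, split.r
    if p > n - r:
        raise InvalidInputError(f"p={p} exceeds complement dimension n-r={n - r}")
    Cv = _as_cov_array(C)
    C2 = split.Q2.T @ Cv @ split.Q2
    w, v = scipy.linalg.eigh((C2 + C2.T) / 2.0)
    w, v = w[::-1].copy(), v[:, ::-1].copy()
    X = split.Q2 @ fix_signs(v[:, :p])
    return LatentFactors(fix_signs(X)), np.clip(w, 0.0, None)


def select_p(C: SampleCovariance, split: SubspaceSplit, rho: float) -> int:
    """Smallest number of latent factors p such that the variance explained
    by span(Z) plus the top-p complement eigenvalues reaches rho * tr(C).

    Capped at n - r - 1 so at least one dimension remains for the residual.
    """
    if not 0.0 < rho < 1.0:
        raise InvalidInputError(f"rho must be in the open interval (0, 1), got {rho}")
    trC = C.trace
    if trC <= 0:
        raise InvalidInputError("tr(C) = 0: no variance to explain")
    Cv = _as_cov_array(C)
    n, r = split.n, split.r
    known = float(np.trace(split.Q1.T @ Cv @ split.Q1)) if r else 0.0
    _, spectrum2 = restricted_ppca(C, split, 0)
    explained = known + np.concatenate([[0.0], np.cumsum(spectrum2)])
    p_max = max(n - r - 1, 0)
    for p in range(p_max + 1):
        if explained[p] / trC >= rho:
            return p
    return p_max


def _sigma2_at(spectrum2: np.ndarray, p: int) -> float:
    """Residual variance when p complement eigenvalues are retained: the
    mean of the excluded ones."""
    if p >= len(spectrum2):
        raise InvalidInputError("no excluded dimensions left for the residual")
    return float(np.mean(spectrum2[p:]))


def enforce_existence(C: SampleCovariance, split: SubspaceSplit, p: int) -> int:
    """Raise p until the analytic solution exists.

    The solution exists iff the minimum variance explained by a principal
    axis of span(Z) and the smallest retained complement eigenvalue both
    exceed sigma^2(p) (the mean excluded eigenvalue).  Including more
    latent factors lowers sigma^2, so the smallest p' >= p satisfying the
    condition is returned; if none exists the known covariates need
    re-screening.
    """
    Cv = _as_cov_array(C)
    n, r = split.n, split.r
    _, spectrum2 = restricted_ppca(C, split, 0)
    min_known = np.inf
    if r:
        min_known = float(scipy.linalg.eigvalsh(split.Q1.T @ Cv @ split.Q1)[0])
    p_max = n - r - 1
    for p_try in range(p, p_max + 1):
        sigma2 = _sigma2_at(spectrum2, p_try)
        ok_known = min_known > sigma2
        ok_latent = p_try == 0 or spectrum2[p_try - 1] > sigma2
        if ok_known and ok_latent:
            return p_try
    raise ExistenceError(
        "no number of latent factors p <= n - r - 1 satisfies the existence "
        "condition; the relevance or possible redundancy of (some of) the "
        "known covariates needs to be reconsidered (re-screen with a larger "
        "theta or drop covariates)"
    )


def estimate_variance_components(
    C: SampleCovariance,
    split: SubspaceSplit,
    X: LatentFactors,
) -> VarianceComponents:
    """Analytic estimate of (B, D, A, sigma^2) once the latent factors are
    fixed: treat (Z, X) jointly as known covariates.

    With G = [Q1, X] and projector P = G G^T, the optimum is
    K = P C P + sigma^2 (I - P) with sigma^2 the mean eigenvalue of C on
    the excluded complement; matching blocks of G^T K G gives A and D and,
    after SVD back-substitution, B in the original Z coordinates.
    """
    Cv = _as_cov_array(C)
    n, r, p = split.n, split.r, X.p
    if r + p >= n:
        raise ExistenceError("span(Z) + span(X) leaves no residual dimensions")
    if p and not X.check_orthonormal():
        raise InvalidInputError("latent factors must be orthonormal")
    if p and r and np.abs(split.Q1.T @ X.values).max() > 1e-8:
        raise InvalidInputError("latent factors must be orthogonal to span(Z)")

    C1 = split.Q1.T @ Cv @ split.Q1 if r else np.zeros((0, 0))
    CX = Cv @ X.values if p else np.zeros((n, 0))
    AXX = X.values.T @ CX if p else np.zeros((0, 0))
    explained = float(np.trace(C1)) + float(np.trace(AXX))
    sigma2 = (float(np.trace(Cv)) - explained) / (n - r - p)
    if sigma2 <= 0:
        raise ExistenceError("residual variance would be zero")

    Xv = X.values
    A_raw = AXX - sigma2 * np.eye(p)
    if p and not np.allclose(A_raw, np.diag(np.diag(A_raw)), atol=1e-12 * max(1.0, np.abs(A_raw).max())):
        # rotational symmetry of the latent factors: re-diagonalize A
        wA, R = scipy.linalg.eigh((A_raw + A_raw.T) / 2.0)
        wA, R = wA[::-1], R[:, ::-1]
        Xv = fix_signs(Xv @ R)
        A_raw = np.diag(wA)
        CX = Cv @ Xv
    A = np.diag(np.diag(A_raw)) if p else np.zeros((0, 0))
    if p and np.any(np.diag(A) <= 0):
        raise ExistenceError(
            "existence condition violated: a retained latent eigenvalue does "
            "not exceed the residual variance"
        )

    if r:
        M = C1 - sigma2 * np.eye(r)
        if scipy.linalg.eigvalsh(M)[0] <= 0:
            raise ExistenceError(
                "existence condition violated: a principal axis of span(Z) "
                "explains no more than the residual variance"
            )
        s_inv = 1.0 / split.singular_values
        B = (split.V_r * s_inv) @ M @ (split.V_r * s_inv).T
        D = (split.V_r * s_inv) @ (split.Q1.T @ CX)
    else:
        B = np.zeros((split.d, split.d))
        D = np.zeros((split.d, p))
    vc = VarianceComponents(B=(B + B.T) / 2.0, D=D, A=A, sigma2=sigma2)
    return LatentFactors(Xv), vc


def orthogonalize_latents(
    Z: CovariateMatrix | np.ndarray,
    X_raw: LatentFactors | np.ndarray,
    vc_raw: VarianceComponents,
):
    """Rewrite a model with arbitrary latent factors as an equivalent model
    whose latents are orthonormal and orthogonal to span(Z).

    Any overlap between X_raw and span(Z) is absorbed into the
    known-covariate effects (a reparameterization of B and D); the model
    covariance K is preserved exactly.  Returns (LatentFactors,
    VarianceComponents) with A diagonal.
    """
    K0 = build_K(Z, X_raw, vc_raw)
    n = K0.shape[0]
    sigma2 = vc_raw.sigma2
    M = K0 - sigma2 * np.eye(n)
    split = subspace_split(Z)
    r = split.r

    M2 = split.Q2.T @ M @ split.Q2
    w, v = scipy.linalg.eigh((M2 + M2.T) / 2.0)
    w, v = w[::-1].copy(), v[:, ::-1].copy()
    scale = max(float(np.abs(w).max(initial=0.0)), 1e-12)
    keep = w > 1e-10 * scale
    p_new = int(np.sum(keep))
    X_new = split.Q2 @ fix_signs(v[:, :p_new])
    A_new = np.diag(w[:p_new])

    if r:
        s_inv = 1.0 / split.singular_values
        M1 = split.Q1.T @ M @ split.Q1
        B_new = (split.V_r * s_inv) @ M1 @ (split.V_r * s_inv).T
        D_new = (split.V_r * s_inv) @ (split.Q1.T @ M @ X_new)
    else:
        B_new = np.zeros((split.d, split.d))
        D_new = np.zeros((split.d, p_new))
    vc_new = VarianceComponents(
        B=(B_new + B_new.T) / 2.0, D=D_new, A=A_new, sigma2=sigma2
    )
    return LatentFactors(X_new), vc_new


def _variance_ledger(
    trC: float,
    known_axis_vars: np.ndarray,
    latent_vars: np.ndarray,
    sigma2: float,
    n_excluded: int,
) -> pd.DataFrame:
    rows = []
    for i, v in enumerate(known_axis_vars, start=1):
        rows.append((f"known_axis_{i}", float(v)))
    for j, v in enumerate(latent_vars, start=1):
        rows.append((f"latent_{j}", float(v)))
    rows.append(("residual", float(sigma2 * n_excluded)))
    df = pd.DataFrame(rows, columns=["component", "variance"])
    df["fraction"] = df["variance"] / trC
    return df


def fit(
    Y: ExpressionMatrix | np.ndarray,
    Z: CovariateMatrix | np.ndarray | None = None,
    rho: float | None = None,
    p: int | None = None,
    rank_tol: float = RANK_TOL,
) -> FitResult:
    """Fit the random-effects model with known covariates Z and latent
    factors chosen by REML on the orthogonal complement of span(Z).

    Exactly one of ``rho`` (target fraction of tr(C) explained, in (0, 1);
    p is then chosen automatically and raised if the existence condition
    requires it) or ``p`` (explicit number of latent factors) must be
    given.  Y is row-centered automatically (with a warning) if it is not
    already.
    """
    if (rho is None) == (p is None):
        raise InvalidInputError("specify exactly one of rho or p")
    if not isinstance(Y, ExpressionMatrix):
        Y = ExpressionMatrix(np.asarray(Y, dtype=float))
    if Z is None:
        Z = CovariateMatrix.empty(Y.n)
    elif not isinstance(Z, CovariateMatrix):
        Z = CovariateMatrix(np.asarray(Z, dtype=float))

    if not Y.is_centered():
        warnings.warn("expression matrix was not sample-centered; centering now", stacklevel=2)
        logger.warning("expression matrix was not sample-centered; centering now")
        Y = center_samples(Y)
    if Y.m <= Y.n:
        warnings.warn(
            f"m = {Y.m} genes <= n = {Y.n} samples: the sample covariance is "
            "singular and the analytic solution is unreliable",
            stacklevel=2,
        )

    C = sample_covariance(Y)
    split = subspace_split(Z, tol=rank_tol)
    n, r = split.n, split.r
    if r < Z.d:
        logger.info("covariate matrix is rank deficient: effective rank %d < d = %d", r, Z.d)
    if r >= n:
        raise ExistenceError(
            "the known covariates span the whole sample space (r >= n): a "
            "subset of n linearly independent covariates always explains all "
            "of the variation in Y; screen the covariates first"
        )

    saturated = False
    if p is None:
        p_target = select_p(C, split, rho)
        p_final = enforce_existence(C, split, p_target)
        saturated = p_final > p_target
        if saturated:
            logger.warning(
                "existence condition raised the number of latent factors from "
                "%d to %d; total variance explained will exceed the target "
                "rho = %g (saturation)",
                p_target, p_final, rho,
            )
            warnings.warn(
                f"existence condition raised p from {p_target} to {p_final}; "
                f"variance explained will exceed the target rho = {rho}",
                stacklevel=2,
            )
    else:
        if not 0 <= p <= n - r - 1:
            raise InvalidInputError(f"need 0 <= p <= n - r - 1 = {n - r - 1}, got p={p}")
        p_final = p
        if enforce_existence(C, split, p_final) != p_final:
            raise ExistenceError(
                f"the analytic solution does not exist for p = {p_final}; "
                "increase p or re-screen the covariates"
            )

    X, spectrum2 = restricted_ppca(C, split, p_final)
    X, vc = estimate_variance_components(C, split, X)
    K_hat = build_K(Z, X, vc)

    L = log_likelihood(K_hat, C)
    # L2: PPCA log-likelihood on the orthogonal complement of span(Z)
    C2 = split.Q2.T @ C.values @ split.Q2
    K2 = split.Q2.T @ K_hat @ split.Q2
    L2 = log_likelihood(K2, C2) if n - r > 0 else 0.0
    L1 = L - L2

    Cv = C.values
    known_axis_vars = (
        np.sort(scipy.linalg.eigvalsh(split.Q1.T @ Cv @ split.Q1))[::-1] if r else np.zeros(0)
    )
    latent_vars = spectrum2[:p_final]
    ledger = _variance_ledger(
        C.trace, known_axis_vars, latent_vars, vc.sigma2, n - r - p_final
    )
    rho_achieved = float(
        (known_axis_vars.sum() + latent_vars.sum()) / C.trace
    )

    return FitResult(
        latent=X,
        components=vc,
        K_hat=K_hat,
        loglik=L,
        loglik_terms=(L1, L2),
        variance_ledger=ledger,
        p=p_final,
        rho_achieved=rho_achieved,
        effective_rank=r,
    )
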