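"""Numeric maximum-likelihood oracle and similarity diagnostics.

The quasi-Newton maximizer here exists purely as an independent
cross-check of the analytic solver on small problems: it parameterizes the
model covariance as K = F F^T + sigma^2 I with F = [Q1, X] L (L lower
triangular, X free), which spans exactly the covariances reachable by the
random-effects model with rank(Z) known covariates and p latent factors,
and maximizes the log-likelihood with analytic gradients and random
restarts.  It is never used in the production fitting path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .core import CovariateMatrix, InvalidInputError, SampleCovariance, _as_cov_array
from .reml import subspace_split


@dataclass
class OracleResult:
    K: np.ndarray
    loglik: float
    converged: bool
    n_converged: int  # restarts that reported convergence


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Normalized inner product u'v / (|u||v|), in [-1, 1]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise InvalidInputError("cosine similarity of a zero vector is undefined")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def max_abs_cosine(U: np.ndarray, V: np.ndarray) -> float:
    """Largest |cosine similarity| between any column of U and any of V."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    if U.shape[1] == 0 or V.shape[1] == 0:
        return 0.0
    Un = U / np.linalg.norm(U, axis=0, keepdims=True)
    Vn = V / np.linalg.norm(V, axis=0, keepdims=True)
    return float(np.abs(Un.T @ Vn).max())


def _unpack(theta, n, r, p):
    q = r + p
    ntri = q * (q + 1) // 2
    L = np.zeros((q, q))
    il = np.tril_indices(q)
    L[il] = theta[:ntri]
    X = theta[ntri : ntri + n * p].reshape(n, p)
    log_s2 = theta[-1]
    return L, X, log_s2, il


def _neg_loglik_and_grad(theta, Q1, Cv, n, r, p):
    L, X, log_s2, il = _unpack(theta, n, r, p)
    s2 = np.exp(np.clip(log_s2, -100.0, 100.0))
    W = np.hstack([Q1, X]) if p else Q1
    F = W @ L
    K = F @ F.T + s2 * np.eye(n)
    if not np.all(np.isfinite(K)):
        return np.inf, np.zeros_like(theta)
    try:
        cf = scipy.linalg.cho_factor(K, lower=True)
    except (scipy.linalg.LinAlgError, ValueError):
        return np.inf, np.zeros_like(theta)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Kinv = scipy.linalg.cho_solve(cf, np.eye(n))
    KinvC = Kinv @ Cv
    f = logdet + float(np.trace(KinvC))
    # gradient of f wrt K
    G = Kinv - KinvC @ Kinv
    G = (G + G.T) / 2.0
    GF2 = 2.0 * (G @ F)
    grad_L = (W.T @ GF2)[il]
    grad = np.empty_like(theta)
    ntri = len(grad_L)
    grad[:ntri] = grad_L
    if p:
        grad[ntri:-1] = (GF2 @ L[r:].T).ravel()
    grad[-1] = s2 * float(np.trace(G))
    return f, grad


def numeric_mle(
    C: SampleCovariance | np.ndarray,
    Z: CovariateMatrix | np.ndarray | None,
    p: int,
    restarts: int = 10,
    seed: int | None = None,
    gtol: float = 1e-10,
) -> OracleResult:
    """Maximize the log-likelihood numerically over the model covariance
    class with rank(Z) known covariates and p latent factors.

    Multiple random restarts of L-BFGS-B with analytic gradients; the best
    solution is kept.  ``converged`` is False if no restart reported
    convergence.  Intended for small n (tests use n <= 20).
    """
    Cv = _as_cov_array(C)
    n = Cv.shape[0]
    if Z is None:
        Z = CovariateMatrix.empty(n)
    split = subspace_split(Z)
    r = split.r
    if p + r >= n:
        raise InvalidInputError(f"need p + rank(Z) < n, got {p} + {r} >= {n}")
    rng = np.random.default_rng(seed)
    q = r + p
    ntri = q * (q + 1) // 2
    s0 = np.sqrt(max(np.trace(Cv) / n, 1e-12))

    best = None
    n_converged = 0
    for _ in range(max(restarts, 1)):
        theta0 = np.empty(ntri + n * p + 1)
        theta0[:ntri] = s0 * rng.standard_normal(ntri) / max(np.sqrt(q), 1.0)
        theta0[ntri:-1] = rng.standard_normal(n * p)
        theta0[-1] = np.log(max(np.trace(Cv) / n, 1e-12) * rng.uniform(0.2, 1.0))
        res = scipy.optimize.minimize(
            _neg_loglik_and_grad,
            theta0,
            args=(split.Q1, Cv, n, r, p),
            jac=True,
            method="L-BFGS-B",
            options={"gtol": gtol, "ftol": 1e-14, "maxiter": 5000},
        )
        n_converged += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    L, X, log_s2, _ = _unpack(best.x, n, r, p)
    W = np.hstack([split.Q1, X]) if p else split.Q1
    F = W @ L
    K = F @ F.T + np.exp(log_s2) * np.eye(n)
    return OracleResult(
        K=(K + K.T) / 2.0,
        loglik=-float(best.fun),
        converged=n_converged > 0,
        n_converged=n_converged,
    )
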