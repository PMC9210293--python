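"""Generative-model simulator for synthetic expression data.

Draws Y = Z V + X W + eps exactly from the random-effects model: per gene,
the effect vector (v_i, w_i) is jointly normal with block covariance
[[B, D], [D^T, A]] and the noise is iid N(0, sigma^2).  The simulated Y is
row-centered like real preprocessed data, so the sample covariance matches
the model covariance K only up to an O(1/m) centering correction.

All randomness flows through one seeded generator; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core import (
    CovariateMatrix,
    ExpressionMatrix,
    InvalidInputError,
    LatentFactors,
    VarianceComponents,
    center_samples,
)


@dataclass
class SimulationSpec:
    """Ground-truth parameters for one simulated dataset.

    Z_mode 'orthonormal' draws Z with orthonormal columns and X orthonormal
    in the complement of span(Z); 'correlated' gives Z columns pairwise
    correlation ``z_correlation`` (X stays orthogonal to span(Z)).
    """

    n: int
    m: int
    components: VarianceComponents
    Z_mode: str = "orthonormal"
    z_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2 or self.m < 1:
            raise InvalidInputError("need n >= 2 and m >= 1")
        if self.components.d + self.components.p >= self.n:
            raise InvalidInputError("d + p must be smaller than n")
        if self.Z_mode not in ("orthonormal", "correlated"):
            raise InvalidInputError(f"unknown Z_mode {self.Z_mode!r}")
        if not self.components.is_psd():
            raise InvalidInputError("joint effect covariance [[B, D], [D^T, A]] is not PSD")

    @property
    def d(self) -> int:
        return self.components.d

    @property
    def p(self) -> int:
        return self.components.p


def default_components(d: int, p: int, sigma2: float = 1.0) -> VarianceComponents:
    """Well-separated ground-truth covariance parameters.

    Known-covariate effect variances descend from 6, latent effect
    variances from 5 (all distinct and well above the default residual
    sigma^2 = 1, so every planted direction is recoverable); effects of
    known covariates are mildly correlated (off-diagonal 0.4) and D = 0.
    """
    B = np.zeros((d, d))
    for i in range(d):
        B[i, i] = 6.0 - 1.5 * i
    B[~np.eye(d, dtype=bool)] = 0.4
    A = np.diag([5.0 - 1.2 * j for j in range(p)])
    if d and np.min(np.diag(B)) <= 0 or p and np.min(np.diag(A)) <= 0:
        raise InvalidInputError("too many components for the default variance spacing")
    return VarianceComponents(B=B, D=np.zeros((d, p)), A=A, sigma2=sigma2)


def expression_with_covariance(C: np.ndarray, m: int, seed: int = 0) -> ExpressionMatrix:
    """Construct a row-centered expression matrix whose sample covariance
    Y Y^T / m equals the given PSD matrix exactly (requires m >= n + 1).

    Useful for tests that need a prescribed spectrum: gene directions are a
    random orthonormal frame orthogonal to the ones vector, so row means
    are exactly zero without perturbing the covariance.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if m < n + 1:
        raise InvalidInputError(f"need m >= n + 1 = {n + 1} to center exactly, got m={m}")
    rng = np.random.default_rng(seed)
    w, U = scipy.linalg.eigh((C + C.T) / 2.0)
    if w[0] < -1e-10 * max(w[-1], 1.0):
        raise InvalidInputError("target covariance is not PSD")
    w = np.clip(w, 0.0, None)
    W = rng.standard_normal((m, n))
    W -= W.mean(axis=0)  # columns orthogonal to the ones vector
    W, _ = np.linalg.qr(W)
    Y = (U * np.sqrt(m * w)) @ W.T
    return ExpressionMatrix(Y)


def _psd_sqrt(T: np.ndarray) -> np.ndarray:
    if T.size == 0:
        return T
    w, v = scipy.linalg.eigh((T + T.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return (v * np.sqrt(w)) @ v.T


def simulate(spec: SimulationSpec):
    """Draw (Y, Z, X_true) from the generative model.

    Returns a row-centered ExpressionMatrix, the CovariateMatrix Z used,
    and the true LatentFactors (orthonormal and orthogonal to span(Z)).
    Bit-reproducible for a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    n, m, d, p = spec.n, spec.m, spec.d, spec.p
    vc = spec.components

    q, _ = np.linalg.qr(rng.standard_normal((n, d + p)))
    Qz, X = q[:, :d], q[:, d : d + p]
    if spec.Z_mode == "orthonormal" or d == 0:
        Z = Qz
    else:
        c = spec.z_correlation
        R = (1.0 - c) * np.eye(d) + c * np.ones((d, d))
        if scipy.linalg.eigvalsh(R)[0] <= 0:
            raise InvalidInputError(f"z_correlation {c} gives a non-PSD column Gram matrix")
        Z = Qz @ np.linalg.cholesky(R).T  # columns unit norm, Gram = R

    T = vc.joint()
    VW = _psd_sqrt(T) @ rng.standard_normal((d + p, m))
    Y = np.sqrt(vc.sigma2) * rng.standard_normal((n, m))
    if d:
        Y += Z @ VW[:d]
    if p:
        Y += X @ VW[d:]
    Y = center_samples(ExpressionMatrix(Y))
    return Y, CovariateMatrix(Z), LatentFactors(X)
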