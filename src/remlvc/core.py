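"""Core data containers and exact evaluation of the model covariance and
log-likelihood.

The generative model is a random-effects model for an expression matrix
``Y`` (n samples x m genes)::

    Y = Z V + X W + eps

where ``Z`` (n x d) holds known sample covariates, ``X`` (n x p) holds
latent factors, the per-gene effect vectors (v_i, w_i) are jointly normal
with block covariance [[B, D], [D^T, A]], and eps is iid Gaussian noise
with variance sigma^2.  Integrating out the random effects, each gene
(column of Y) is an independent draw from N(0, K) with

    K = Z B Z^T + Z D X^T + X D^T Z^T + X A X^T + sigma^2 I

and the log-likelihood of the parameters given the sample covariance
C = Y Y^T / m is, up to constants,

    L = -log det(K) - tr(K^{-1} C).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


class InvalidInputError(ValueError):
    """Raised when an input matrix violates a precondition (non-finite
    entries, bad shapes, invalid parameter values)."""


class NotPositiveDefiniteError(ValueError):
    """Raised when a matrix required to be positive definite is not."""


class ExistenceError(RuntimeError):
    """Raised when the analytic maximum-likelihood solution does not exist.

    The analytic solution requires every retained variance direction
    (principal axis in span(Z) or retained latent eigenvalue) to explain
    strictly more variance than the residual sigma^2.
    """


# relative eigenvalue floor: C is PSD by construction, eigenvalues more
# negative than -EIG_CLIP_REL * tr(C)/n signal corrupt input
EIG_CLIP_REL = 1e-10
# positive-definiteness test: smallest eigenvalue > PD_REL * largest
PD_REL = 1e-12


def _as_labels(labels, n: int, prefix: str) -> list[str]:
    if labels is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise InvalidInputError(f"expected {n} {prefix} labels, got {len(labels)}")
    if len(set(labels)) != len(labels):
        raise InvalidInputError(f"duplicate {prefix} labels")
    return labels


def _check_finite(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        bad = np.argwhere(~np.isfinite(a))[0]
        raise InvalidInputError(
            f"{name} contains a non-finite entry at position {tuple(int(i) for i in bad)}"
        )
    return a


@dataclass
class ExpressionMatrix:
    """Expression values for n samples (rows) by m genes (columns)."""

    values: np.ndarray
    sample_ids: list[str] = None
    gene_ids: list[str] = None

    def __post_init__(self):
        self.values = _check_finite(self.values, "expression matrix")
        if self.values.ndim != 2:
            raise InvalidInputError("expression matrix must be 2-dimensional")
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise InvalidInputError(f"need n >= 2 samples and m >= 1 genes, got {n} x {m}")
        self.sample_ids = _as_labels(self.sample_ids, n, "sample")
        self.gene_ids = _as_labels(self.gene_ids, m, "gene")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def is_centered(self, tol: float = 1e-8) -> bool:
        """True if every sample (row) has mean zero within ``tol`` relative
        to the row scale."""
        scale = max(1.0, float(np.abs(self.values).max(initial=0.0)))
        return bool(np.abs(self.values.mean(axis=1)).max(initial=0.0) <= tol * scale)


@dataclass
class CovariateMatrix:
    """Known sample covariates: n samples (rows) by d covariates (columns).

    d = 0 is allowed and means "no known covariates".
    """

    values: np.ndarray
    covariate_ids: list[str] = None
    rank_tol: float = 1e-10

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise InvalidInputError("covariate matrix must be 2-dimensional")
        self.values = _check_finite(v, "covariate matrix")
        self.covariate_ids = _as_labels(self.covariate_ids, v.shape[1], "covariate")

    @classmethod
    def empty(cls, n: int) -> "CovariateMatrix":
        return cls(np.zeros((n, 0)), covariate_ids=[])

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def effective_rank(self) -> int:
        """Rank of Z at tolerance ``rank_tol`` relative to the largest
        singular value (duplicated or near-collinear covariates collapse)."""
        if self.d == 0:
            return 0
        s = scipy.linalg.svdvals(self.values)
        if s[0] <= 0:
            return 0
        return int(np.sum(s > self.rank_tol * s[0]))


@dataclass
class LatentFactors:
    """Latent factors X (n x p); columns orthonormal and, when produced by
    the REML solver, orthogonal to span(Z)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        self.values = _check_finite(v, "latent factors")

    @classmethod
    def empty(cls, n: int) -> "LatentFactors":
        return cls(np.zeros((n, 0)))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def check_orthonormal(self, tol: float = 1e-8) -> bool:
        g = self.values.T @ self.values
        return bool(np.allclose(g, np.eye(self.p), atol=tol))


@dataclass
class VarianceComponents:
    """Covariance parameters of the random effects.

    B (d x d): covariance of known-covariate effects.
    D (d x p): covariance between known and latent effects.
    A (p x p): diagonal covariance of latent effects.
    sigma2: residual variance (> 0).
    """

    B: np.ndarray
    D: np.ndarray
    A: np.ndarray
    sigma2: float

    def __post_init__(self):
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        if self.B.size == 0:
            self.B = self.B.reshape(0, 0)
        if self.A.size == 0:
            self.A = self.A.reshape(0, 0)
        d, p = self.B.shape[0], self.A.shape[0]
        self.D = np.asarray(self.D, dtype=float).reshape(d, p)
        self.sigma2 = float(self.sigma2)
        if self.sigma2 <= 0:
            raise InvalidInputError(f"sigma2 must be positive, got {self.sigma2}")

    @property
    def d(self) -> int:
        return self.B.shape[0]

    @property
    def p(self) -> int:
        return self.A.shape[0]

    def joint(self) -> np.ndarray:
        """The joint effect covariance [[B, D], [D^T, A]]."""
        return np.block([[self.B, self.D], [self.D.T, self.A]])

    def is_psd(self, tol: float = 1e-8) -> bool:
        j = self.joint()
        if j.size == 0:
            return True
        w = scipy.linalg.eigvalsh(j)
        scale = max(1.0, float(w[-1]))
        return bool(w[0] >= -tol * scale)


@dataclass
class SampleCovariance:
    """Sample covariance C = Y Y^T / m with a cached spectral decomposition.

    Eigenvalues are sorted nonincreasing; eigenvector signs follow the
    convention that the entry of largest magnitude in each column is
    positive, for reproducible output.
    """

    values: np.ndarray
    singular_warning: bool = False
    eigenvalues: np.ndarray = field(init=False)
    eigenvectors: np.ndarray = field(init=False)

    def __post_init__(self):
        c = _check_finite(self.values, "sample covariance")
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InvalidInputError("sample covariance must be square")
        if not np.allclose(c, c.T, atol=1e-10 * max(1.0, np.abs(c).max())):
            raise InvalidInputError("sample covariance must be symmetric")
        self.values = (c + c.T) / 2.0
        w, v = scipy.linalg.eigh(self.values)
        w, v = w[::-1].copy(), v[:, ::-1].copy()
        n = c.shape[0]
        floor = -EIG_CLIP_REL * max(float(np.trace(self.values)), 0.0) / n
        if np.any(w < floor):
            raise InvalidInputError(
                f"covariance matrix has eigenvalue {w.min():.3e} below the PSD "
                f"tolerance {floor:.3e}; input is likely corrupt"
            )
        self.eigenvalues = np.clip(w, 0.0, None)
        self.eigenvectors = fix_signs(v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def trace(self) -> float:
        return float(np.sum(self.eigenvalues))


@dataclass
class FitResult:
    """Everything the REML fit produces."""

    latent: LatentFactors
    components: VarianceComponents
    K_hat: np.ndarray
    loglik: float
    loglik_terms: tuple[float, float]  # (L1, L2)
    variance_ledger: "object"  # pandas.DataFrame: component, variance, fraction
    p: int
    rho_achieved: float
    effective_rank: int
    sigma2: float = None

    def __post_init__(self):
        if self.sigma2 is None:
            self.sigma2 = self.components.sigma2


def fix_signs(v: np.ndarray) -> np.ndarray:
    """Flip column signs so the entry of largest magnitude is positive."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        return v
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def center_samples(Y: ExpressionMatrix | np.ndarray) -> ExpressionMatrix:
    """Center the expression matrix so each sample (row) has mean zero.

    Removes per-sample offsets so no fixed effects on the mean are needed
    in the random-effects model.  Idempotent.
    """
    if not isinstance(Y, ExpressionMatrix):
        Y = ExpressionMatrix(np.asarray(Y, dtype=float))
    centered = Y.values - Y.values.mean(axis=1, keepdims=True)
    return ExpressionMatrix(centered, sample_ids=list(Y.sample_ids), gene_ids=list(Y.gene_ids))


def sample_covariance(Y: ExpressionMatrix | np.ndarray) -> SampleCovariance:
    """Compute C = Y Y^T / m with a cached spectral decomposition.

    If m < n, C is singular and the unconstrained optimum K = C is invalid;
    the returned object carries ``singular_warning = True``.
    """
    if not isinstance(Y, ExpressionMatrix):
        Y = ExpressionMatrix(np.asarray(Y, dtype=float))
    n, m = Y.values.shape
    C = (Y.values @ Y.values.T) / m
    return SampleCovariance(C, singular_warning=m < n)


def _as_cov_array(C) -> np.ndarray:
    return C.values if isinstance(C, SampleCovariance) else np.asarray(C, dtype=float)


def build_K(
    Z: CovariateMatrix | np.ndarray,
    X: LatentFactors | np.ndarray,
    vc: VarianceComponents,
) -> np.ndarray:
    """Assemble the model covariance K = ZBZ^T + ZDX^T + XD^TZ^T + XAX^T + sigma^2 I."""
    Zv = Z.values if isinstance(Z, CovariateMatrix) else np.asarray(Z, dtype=float)
    Xv = X.values if isinstance(X, LatentFactors) else np.asarray(X, dtype=float)
    if Zv.ndim == 1:
        Zv = Zv[:, None]
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    if Zv.shape[0] and Xv.shape[0] and Zv.shape[0] != Xv.shape[0]:
        raise InvalidInputError(
            f"Z has {Zv.shape[0]} samples but X has {Xv.shape[0]}"
        )
    n = Zv.shape[0] or Xv.shape[0]
    if n == 0:
        raise InvalidInputError("cannot infer sample count: both Z and X are empty")
    if Zv.shape[1] != vc.d or Xv.shape[1] != vc.p:
        raise InvalidInputError(
            f"dimension mismatch: Z has {Zv.shape[1]} columns vs B {vc.d}x{vc.d}; "
            f"X has {Xv.shape[1]} columns vs A {vc.p}x{vc.p}"
        )
    K = vc.sigma2 * np.eye(n)
    if vc.d:
        K += Zv @ vc.B @ Zv.T
    if vc.d and vc.p:
        cross = Zv @ vc.D @ Xv.T
        K += cross + cross.T
    if vc.p:
        K += Xv @ vc.A @ Xv.T
    return (K + K.T) / 2.0


def log_likelihood(K: np.ndarray, C: SampleCovariance | np.ndarray) -> float:
    """Evaluate L = -log det(K) - tr(K^{-1} C) through a spectral
    factorization of K (never an explicit inverse).

    Raises :class:`NotPositiveDefiniteError` naming the offending
    eigenvalue when K is not positive definite.
    """
    K = np.asarray(K, dtype=float)
    Cv = _as_cov_array(C)
    w, v = scipy.linalg.eigh((K + K.T) / 2.0)
    if w[0] <= PD_REL * max(w[-1], 0.0) or w[-1] <= 0:
        raise NotPositiveDefiniteError(
            f"K is not positive definite: smallest eigenvalue {w[0]:.6e} "
            f"(largest {w[-1]:.6e})"
        )
    logdet = float(np.sum(np.log(w)))
    # tr(K^{-1} C) = sum_i (v_i^T C v_i) / w_i
    quad = np.einsum("ij,ji->i", v.T @ Cv, v)
    return -logdet - float(np.sum(quad / w))
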