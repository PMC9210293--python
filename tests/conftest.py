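import numpy as np
import pytest

from remlvc import SampleCovariance


@pytest.fixture
def diag_cov():
    """Sample covariance diag(4, 2, 1): the canonical worked example."""
    return SampleCovariance(np.diag([4.0, 2.0, 1.0]))


@pytest.fixture
def diag_cov4():
    return SampleCovariance(np.diag([4.0, 2.0, 1.0, 1.0]))


def random_psd(n: int, rng: np.random.Generator, m: int = None) -> np.ndarray:
    """Wishart-style random PSD matrix (full rank when m >= n)."""
    m = m or 3 * n
    a = rng.standard_normal((n, m))
    return a @ a.T / m


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
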