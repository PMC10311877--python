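import numpy as np
import pytest

from qrer import CovariateMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def ladder_cov():
    """The 4-point, 1-covariate instance with a hand-computable distance."""
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    return CovariateMatrix.from_arrays(X, [1, 1, 0, 0])


@pytest.fixture
def random_cov(rng):
    """A small random instance: 12 units, 3 covariates, 5 treated."""
    X = rng.standard_normal((12, 3))
    T = np.array([1] * 5 + [0] * 7)
    return CovariateMatrix.from_arrays(X, T)
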