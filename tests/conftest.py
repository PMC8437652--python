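import numpy as np
import pytest

from decluster import DataMatrix, load_builtin


@pytest.fixture(scope="session")
def iris():
    return load_builtin("iris")


@pytest.fixture(scope="session")
def wine():
    return load_builtin("wine")


@pytest.fixture(scope="session")
def zoo():
    return load_builtin("zoo")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_clouds():
    """Two well-separated 2-d point clouds (30 points each) with membership."""
    r = np.random.default_rng(7)
    a = r.normal(0.0, 0.5, size=(30, 2))
    b = r.normal(20.0, 0.5, size=(30, 2))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 30)
    return DataMatrix(X), labels
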