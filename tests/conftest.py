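import numpy as np
import pytest

from dsadet import nn


@pytest.fixture(autouse=True)
def _seed_everything():
    nn.seed_all(0)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numerical_gradient(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar-valued fn of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = fn(x)
        x[i] = orig - eps
        fm = fn(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
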