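import numpy as np
import pytest

from slicefuse import _nn


@pytest.fixture
def f64():
    """Run the autodiff engine in float64 (for oracle/finite-difference tests)."""
    old = _nn.DTYPE
    _nn.set_default_dtype(np.float64)
    yield
    _nn.set_default_dtype(old)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def phantom_dataset():
    """Small separable phantom set shared by read-only tests."""
    from slicefuse.synthetic import SyntheticSpec, generate_dataset

    return generate_dataset(SyntheticSpec(n_per_class=6, shape=(12, 16, 16), seed=7))


def numeric_grad(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar fn at x (float64)."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = fn()
        x[idx] = orig - eps
        fm = fn()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
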