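import numpy as np
import pytest

from modseg.phantoms import PhantomSpec, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A tiny phantom family used across I/O and pipeline tests."""
    return PhantomSpec(dims=(8, 16, 16), n_modalities=2, n_classes=3,
                       lesion_radius_range=(3.0, 5.0), seed=42)


@pytest.fixture
def small_case(small_spec):
    return generate_case(small_spec, 0)


def numeric_gradient(f, arr, eps=1e-3):
    """Central finite differences of a scalar function of one array."""
    g = np.zeros(arr.shape, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g
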