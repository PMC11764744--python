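import numpy as np
import pytest

from lkmu import ArchConfig, PhantomSpec, build_model, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_arch():
    """A narrow five-stage config for fast structural tests."""
    return ArchConfig(num_classes=1, stage_channels=(8, 8, 8, 8, 8))


@pytest.fixture(scope="session")
def tiny_model(tiny_arch):
    return build_model(tiny_arch, seed=0)


@pytest.fixture(scope="session")
def small_spec():
    """64x64 single-class phantom spec scaled for test speed."""
    return PhantomSpec(height=64, width=64, n_classes=1, axis_range=(4, 14),
                       curvature_amplitude=2.0, n_layers=6)


@pytest.fixture(scope="session")
def small_sample(small_spec):
    return generate_phantom(small_spec, seed=7)


def numerical_gradient(f, x, eps=1e-3):
    """Central-difference gradient of scalar f() with respect to array x
    (mutated in place element by element)."""
    grad = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
    return grad
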