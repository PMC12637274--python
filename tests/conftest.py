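import numpy as np
import pytest

from spatioseg.network import ModelConfig, build_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest config exercising two stages, multi-head attention and the decoder."""
    return ModelConfig(
        input_size=(32, 32, 3),
        num_classes=4,
        strides=(4, 2),
        embed_dims=(8, 16),
        depths=(1, 1),
        num_heads=(1, 2),
        expansions=(4, 4),
        decoder_dim=16,
        seed=7,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return build_model(tiny_config)


def finite_difference(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar-valued f at x."""
    g = np.zeros_like(x, dtype=float)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g
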