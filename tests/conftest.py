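import numpy as np
import pytest

from hrunet import ModelConfig, PhantomParams, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_params():
    """32x32 phantom recipe for fast desk-scale tests."""
    return PhantomParams(seed=3).scaled_to(32, 32)


@pytest.fixture(scope="session")
def tiny_samples(tiny_params):
    return generate_dataset(4, tiny_params)


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(in_height=32, in_width=32, seed=1)


def random_mask(rng, shape=(9, 9), p=0.4):
    return (rng.random(shape) < p).astype(np.uint8)
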