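import numpy as np
import pytest
from hypothesis import settings

from osteoformer.config import Hyperparams, preset
from osteoformer.phantoms import generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_proposed():
    return preset("tiny_proposed")


@pytest.fixture(scope="session")
def tiny_baseline():
    return preset("tiny_baseline")


@pytest.fixture(scope="session")
def phantoms32():
    """A dozen small mixed-anatomy phantoms for fast end-to-end tests."""
    return generate_dataset(12, size=32, seed=11)


@pytest.fixture(scope="session")
def quick_hp():
    return Hyperparams(epochs=2, seed=3)


def rand(shape, seed=0):
    return np.random.default_rng(seed).standard_normal(shape)
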