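import numpy as np
import pytest
from hypothesis import settings

from chemrisk import GeneratorConfig, generate_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_dataset():
    """One full-size dataset at the default study conditions (40,000 x 63)."""
    return generate_dataset(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A 4,000-sample dataset for selection/benchmark tests."""
    return generate_dataset(GeneratorConfig(n_samples=4000, seed=3))


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 600-sample dataset for fast end-to-end checks."""
    return generate_dataset(GeneratorConfig(n_samples=600, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
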