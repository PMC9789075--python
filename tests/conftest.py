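import numpy as np
import pytest

from accelt2 import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def knee_phantom():
    """Small noisy knee phantom shared across tests."""
    return generate_phantom(PhantomConfig(grid=(32, 32, 8), seed=7))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless, lesion-free phantom: exact class T2 everywhere."""
    return generate_phantom(
        PhantomConfig(grid=(32, 32, 8), seed=3, noise_sigma=0.0,
                      lesion_count=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
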