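import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hegp import PlainDataset, SimScenario, encrypt, sample_key, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_plain() -> PlainDataset:
    """Centered 80 x 40 simulated dataset shared by invariance tests."""
    ds, _ = simulate_dataset(SimScenario(n=80, p=40, h2=0.5, qtl_prop=0.2, seed=1234))
    return ds


@pytest.fixture(scope="session")
def small_key(small_plain):
    return sample_key(small_plain.n, seed=4321)


@pytest.fixture(scope="session")
def small_cipher(small_plain, small_key):
    return encrypt(small_plain, small_key)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
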