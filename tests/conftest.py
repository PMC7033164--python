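import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import photonet as pn

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """One default factorial campaign (936 records, seed 0)."""
    return pn.generate_dataset(pn.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def noise_free_dataset():
    return pn.generate_dataset(pn.GeneratorConfig(seed=0, noise_cv=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
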