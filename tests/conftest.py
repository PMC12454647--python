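import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import convfuse as cf

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tree50():
    return cf.simulate_species_tree(50, seed=7)


@pytest.fixture(scope="session")
def tree100():
    return cf.simulate_species_tree(100, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
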