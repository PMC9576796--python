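import logging

import pytest
from hypothesis import HealthCheck, settings

import ndapo as nd

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# balance clipping warnings are expected on noisy data; keep test output clean
logging.getLogger("ndapo").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def library():
    return nd.default_library()


@pytest.fixture(scope="session")
def registry(library):
    return library.table.species


@pytest.fixture(scope="session")
def noiseless_truth():
    """Truth series from the default noiseless simulation (shared, read-only)."""
    batch = nd.simulate_batch(nd.SimulationParams(), seed=0)
    return batch
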