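import numpy as np
import pytest
from hypothesis import settings

from islandrad import SimulationParams, build_geometry, validate_params

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def default_params() -> SimulationParams:
    return validate_params(SimulationParams())


@pytest.fixture
def default_geometry():
    return build_geometry(0.0, 0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
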