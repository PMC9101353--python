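import numpy as np
import pytest

from sfmech.synthetic import GeometryConfig, default_params


@pytest.fixture(scope="session")
def params():
    """Study-condition bundle constants (slope-consistent parameter set)."""
    return default_params()


@pytest.fixture(scope="session")
def geometry():
    return GeometryConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
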