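import numpy as np
import pytest

from vesiclemc.energetics import EnergyParams
from vesiclemc.mesh import build_icosphere, icosphere_matching_edge_length


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def icosahedron():
    return build_icosphere(0, 1.0)


@pytest.fixture(scope="session")
def unit_icosphere_s2():
    """Icosphere with ~unit mean edge length (162 vertices)."""
    return icosphere_matching_edge_length(2, 1.0)


@pytest.fixture
def params():
    return EnergyParams()
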