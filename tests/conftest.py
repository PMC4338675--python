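import numpy as np
import pytest

from maskingnet.architecture import GeometryConfig, build_geometry
from maskingnet.config import fixture_network


@pytest.fixture(scope="session")
def geom1():
    """Full-size noise-mask geometry (no cells simulated)."""
    return build_geometry(GeometryConfig.model1())


@pytest.fixture(scope="session")
def geom2():
    """Full-size line-mask geometry."""
    return build_geometry(GeometryConfig.model2())


@pytest.fixture(scope="session")
def tiny1():
    """Miniature assembled noise-mask network."""
    return fixture_network("tiny_model1")


@pytest.fixture(scope="session")
def tiny2():
    """Miniature assembled line-mask network."""
    return fixture_network("tiny_model2")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
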