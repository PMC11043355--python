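import numpy as np
import pytest

from vescomp.flower import BuildSpec, build_vesicle
from vescomp.mesh import icosphere


@pytest.fixture(scope="session")
def unit_icosphere():
    return icosphere(4)


@pytest.fixture(scope="session")
def coarse_icosphere():
    return icosphere(2)


@pytest.fixture(scope="session")
def composite_mesh():
    """Reference flower vesicle: alpha=2, phi=0.14, ~642 vertices."""
    return build_vesicle(BuildSpec(alpha=2.0, phi=0.14, subdivisions=3, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
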