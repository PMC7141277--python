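import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gqipipe.gqi import GQIConfig, make_direction_set
from gqipipe.synthetic import FiberCompartment, FiberConfig, make_gradient_table

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gtab():
    """Default three-shell table: 1 null + 3 x 64 directions."""
    return make_gradient_table()


@pytest.fixture(scope="session")
def small_gtab():
    """Tiny three-shell table for brute-force loops."""
    return make_gradient_table(n_per_shell=8, seed=1)


@pytest.fixture(scope="session")
def dirs3():
    return make_direction_set(3)


@pytest.fixture(scope="session")
def gqi_cfg():
    return GQIConfig()


@pytest.fixture
def single_fiber():
    def build(direction=(0.0, 0.0, 1.0), fraction=0.8):
        return FiberConfig(
            compartments=(FiberCompartment(fraction=fraction, direction=direction),),
            isotropic_fraction=1.0 - fraction,
        )

    return build


@pytest.fixture
def isotropic_voxel():
    return FiberConfig(compartments=(), isotropic_fraction=1.0)
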