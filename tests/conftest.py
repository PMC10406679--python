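import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from remorph import shapes

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


TUBE_PROFILE = lambda z: 1.0 + 0.5 * np.sin(2 * np.pi * z / 10.0)  # noqa: E731


@pytest.fixture(scope="session")
def cube():
    return shapes.make_box()


@pytest.fixture(scope="session")
def sphere():
    return shapes.make_uv_sphere(1.0, 64, 32)


@pytest.fixture(scope="session")
def cylinder():
    return shapes.make_cylinder(1.0, 10.0, 64)


@pytest.fixture(scope="session")
def cone():
    return shapes.make_cone(1.0, 1.0, 64)


@pytest.fixture(scope="session")
def tube():
    return shapes.make_tube(TUBE_PROFILE, 10.0, 64, 64)


@pytest.fixture(scope="session")
def two_cubes():
    return shapes.make_two_component()


@pytest.fixture(scope="session")
def nanoprocess_cloud():
    return shapes.make_nanoprocess_cloud(20, 24)
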