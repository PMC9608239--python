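import numpy as np
import pytest

from loopshell import ShellModel, make_icosphere
from loopshell.locator import build_hash_grid

# hypothesis profile: derandomized so the suite is reproducible
try:
    from hypothesis import settings, HealthCheck

    settings.register_profile(
        "loopshell",
        derandomize=True,
        deadline=None,
        max_examples=25,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("loopshell")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def sphere1():
    return make_icosphere(1)


@pytest.fixture(scope="session")
def sphere2():
    return make_icosphere(2)


@pytest.fixture(scope="session")
def sphere3():
    return make_icosphere(3)


@pytest.fixture(scope="session")
def sphere4():
    return make_icosphere(4)


@pytest.fixture(scope="session")
def model2(sphere2):
    return ShellModel.for_mesh(sphere2, 3)


@pytest.fixture(scope="session")
def model3(sphere3):
    return ShellModel.for_mesh(sphere3, 3)


@pytest.fixture(scope="session")
def model4(sphere4):
    return ShellModel.for_mesh(sphere4, 3)


@pytest.fixture(scope="session")
def grid2(sphere2):
    return build_hash_grid(sphere2, 8, 8, 8)


@pytest.fixture(scope="session")
def grid3(sphere3):
    return build_hash_grid(sphere3, 12, 12, 12)


@pytest.fixture(scope="session")
def grid4(sphere4):
    return build_hash_grid(sphere4, 15, 15, 15)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
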