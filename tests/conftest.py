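import numpy as np
import pytest

from slmscat import GridSpec, scene_preset


@pytest.fixture(scope="session")
def grid512() -> GridSpec:
    return GridSpec(n=512, pixel_size=0.1)


@pytest.fixture(scope="session")
def grid256() -> GridSpec:
    return GridSpec(n=256, pixel_size=0.1)


@pytest.fixture(scope="session")
def grid64() -> GridSpec:
    return GridSpec(n=64, pixel_size=0.1)


@pytest.fixture(scope="session")
def scene40(grid512):
    """Reference 40 nm nanoparticle scene on the default background."""
    return scene_preset("aunp40", 1, grid512)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
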