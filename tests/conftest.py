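import numpy as np
import pytest

from foodpix.imageset import ClassRegistry
from foodpix.synthetic import toy_catalogue, toy_fcdb, toy_registry


@pytest.fixture(scope="session")
def registry8() -> ClassRegistry:
    """Small 8-class registry (background + 7 foods) for fast image tests."""
    return toy_registry(8)


@pytest.fixture(scope="session")
def registry56() -> ClassRegistry:
    return toy_registry(56)


@pytest.fixture(scope="session")
def cat():
    return toy_catalogue()


@pytest.fixture(scope="session")
def fcdb(cat):
    return toy_fcdb(cat)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
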