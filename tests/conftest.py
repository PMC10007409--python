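import numpy as np
import pytest

from smpcnn import data_io


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_fruit_scene():
    """The standard 3-fruit 128x128 fixture used by the end-to-end tests."""
    return data_io.generate_scene(data_io.SyntheticSceneConfig(seed=1))
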