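import numpy as np
import pytest

from topoimage import synthetic


@pytest.fixture(scope="session")
def lesion_fixture():
    """Standard lesion scene: image and ground-truth mask, fixed seed."""
    return synthetic.lesion_scene(seed=0)


@pytest.fixture(scope="session")
def digits_fixture():
    return synthetic.digits_scene(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
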