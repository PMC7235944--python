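import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_binary_16(rng):
    """Seeded random 16^3 binary volume at the reference 0.018 mm resolution."""
    from trabemorph import VoxelImage

    data = (rng.random((16, 16, 16)) < 0.4).astype(np.uint8)
    return VoxelImage(data, 0.018, is_binary=True)
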