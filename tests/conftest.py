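import numpy as np
import pytest


def rasterize_disk(shape, center, radius):
    """Boolean disk on a grid; pixel centres at integer coordinates."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disk():
    return rasterize_disk
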