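import numpy as np
import pytest

from retinagel.io import RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20211220)


@pytest.fixture
def config():
    return RunConfig()


def paint_disc(canvas, cy, cx, r, value=1.0):
    yy, xx = np.mgrid[:canvas.shape[0], :canvas.shape[1]]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    canvas[mask] = value
    return mask
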