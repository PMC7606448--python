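import numpy as np
import pytest

from histocart import TileGrid, gen_planted_slide


@pytest.fixture
def thirds_slide():
    """3x3 two-trait slide, one third of tiles per non-empty combination."""
    return gen_planted_slide(3, 3, 2, [0, 1 / 3, 1 / 3, 1 / 3], "blocks", seed=7)


@pytest.fixture
def full_grid():
    def make(rows, cols, slide_id="S1"):
        return TileGrid(slide_id=slide_id, tile_size=512, rows=rows, cols=cols)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
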