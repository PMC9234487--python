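import numpy as np
import pytest

from forestcast.raster_io import RasterGrid, StudyAreaMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid(rng):
    values = rng.integers(0, 256, (16, 16)).astype(np.uint8)
    return RasterGrid(
        values=values,
        nodata_mask=np.zeros((16, 16), bool),
        origin_x=100.0,
        origin_y=200.0,
        pixel_size=30.0,
        band_label="B3",
        crs_id="EPSG:32648",
    )


@pytest.fixture
def full_mask():
    def make(rows, cols):
        return StudyAreaMask(np.ones((rows, cols), bool))

    return make
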