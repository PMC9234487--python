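"""B432 false-color compositing and color-based vegetation segmentation.

Landsat false-color composites map near-infrared (B4) to red, red (B3) to
green and green (B2) to blue; healthy vegetation reflects strongly in the
near infrared and therefore renders red.  Vegetation is segmented by a red
dominance rule on the 8-bit composite: a pixel is vegetation when its red
channel is bright enough and sufficiently exceeds both green and blue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from forestcast.raster_io import RasterGrid

DEFAULT_R_MIN = 80
DEFAULT_DOMINANCE = 1.2


@dataclass
class FalseColorComposite:
    """8-bit RGB composite: red=B4, green=B3, blue=B2."""

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    nodata_mask: np.ndarray

    def __post_init__(self):
        shapes = {self.red.shape, self.green.shape, self.blue.shape, self.nodata_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def to_rgb(self) -> np.ndarray:
        return np.stack([self.red, self.green, self.blue], axis=-1).astype(np.uint8)


@dataclass
class VegetationMask:
    """Binary vegetation map plus the color rule that produced it."""

    values: np.ndarray
    r_min: int
    dominance: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _rescale_8bit(grid: RasterGrid) -> np.ndarray:
    """Min-max rescale valid pixels to [0, 255]; degenerate range -> 0."""
    values = np.asarray(grid.values, dtype=np.float64)
    valid = ~grid.nodata_mask
    out = np.zeros(values.shape, dtype=np.float64)
    if valid.any():
        lo, hi = values[valid].min(), values[valid].max()
        if hi > lo:
            out[valid] = (values[valid] - lo) / (hi - lo) * 255.0
    return np.rint(out).astype(np.uint8)


def stack_false_color(b4: RasterGrid, b3: RasterGrid, b2: RasterGrid) -> FalseColorComposite:
    """Stack B4/B3/B2 into an 8-bit false-color composite.

    Each band is independently min-max rescaled over its valid pixels;
    a composite pixel is nodata where any input band is nodata.
    """
    if not (b4.shape == b3.shape == b2.shape):
        raise ValueError(f"band shapes differ: {b4.shape}, {b3.shape}, {b2.shape}")
    return FalseColorComposite(
        red=_rescale_8bit(b4),
        green=_rescale_8bit(b3),
        blue=_rescale_8bit(b2),
        nodata_mask=b4.nodata_mask | b3.nodata_mask | b2.nodata_mask,
    )


def segment_vegetation(
    composite: FalseColorComposite,
    r_min: int = DEFAULT_R_MIN,
    dominance: float = DEFAULT_DOMINANCE,
) -> VegetationMask:
    """Red-dominance vegetation segmentation of a B432 composite.

    A pixel is vegetation iff red >= r_min AND red >= dominance*green AND
    red >= dominance*blue.  Nodata pixels are never vegetation.
    """
    r = composite.red.astype(np.float64)
    g = composite.green.astype(np.float64)
    b = composite.blue.astype(np.float64)
    veg = (r >= r_min) & (r >= dominance * g) & (r >= dominance * b)
    veg &= ~composite.nodata_mask
    return VegetationMask(values=veg, r_min=r_min, dominance=dominance)


def write_composite(composite: FalseColorComposite, path: str | Path) -> None:
    """Write the composite as 24-bit PNG or 3-band TIFF."""
    path = Path(path)
    rgb = composite.to_rgb()
    if path.suffix.lower() == ".png":
        Image.fromarray(rgb, mode="RGB").save(path)
    else:
        tifffile.imwrite(path, rgb, photometric="rgb")


def write_mask(mask: VegetationMask, path: str | Path) -> None:
    """Write the vegetation mask as a 0/255 PNG or 0/1 TIFF."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        Image.fromarray((mask.values * 255).astype(np.uint8), mode="L").save(path)
    else:
        tifffile.imwrite(path, mask.values.astype(np.uint8))
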