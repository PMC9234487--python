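"""Raster, mask and manifest input/output.

Rasters travel as :class:`RasterGrid` objects: a 2-D array of digital numbers
(DN) with a nodata mask and a minimal georeference (top-left origin, square
pixel size, CRS identifier).  GeoTIFF files are written with the standard
GeoTIFF tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA) plus a JSON
ImageDescription so they round-trip without an external GIS stack; plain
grayscale PNGs are accepted for pre-cut block images and carry no
georeference (origin 0,0, pixel size 1, CRS ``"pixel"``).

Pixel convention: row-major, 0-based ``(row, col)``; the map coordinate of a
pixel center is ``origin + (index + 0.5) * pixel_size`` on both axes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import tifffile
from PIL import Image
from shapely.geometry import Polygon

from forestcast.errors import (
    BandNotFoundError,
    InvalidGeometryError,
    ManifestParseError,
    RasterIOError,
)

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """A georeferenced single-band image with a nodata mask.

    ``values`` holds raw digital numbers; ``nodata_mask`` is True where the
    file declared no observation.  ``origin_x``/``origin_y`` locate the
    top-left corner in map units, with both map axes increasing with the
    pixel index.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 1.0
    band_label: str = ""
    crs_id: str = "pixel"
    nodata_value: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("values must be a non-empty 2D array")
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask must match values in shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the center of pixel (row, col)."""
        return (
            self.origin_x + (col + 0.5) * self.pixel_size,
            self.origin_y + (row + 0.5) * self.pixel_size,
        )


@dataclass
class StudyAreaMask:
    """Boolean raster aligned pixel-for-pixel with a reference grid."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def n_inside(self) -> int:
        return int(self.values.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _grid_meta(grid: RasterGrid) -> dict:
    return {
        "origin_x": grid.origin_x,
        "origin_y": grid.origin_y,
        "pixel_size": grid.pixel_size,
        "band_label": grid.band_label,
        "crs_id": grid.crs_id,
        "nodata_value": grid.nodata_value,
    }


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a RasterGrid as GeoTIFF (.tif/.tiff) or 8-bit grayscale PNG.

    GeoTIFFs carry the georeference in standard tags and round-trip
    bit-exactly for integer values.  PNG output requires 8-bit range and
    drops georeference and nodata (documented PNG defaults apply on read).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            values = grid.values
            if grid.nodata_value is not None:
                values = values.copy()
                values[grid.nodata_mask] = grid.nodata_value
            extratags = [
                (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),
                (
                    _TAG_MODEL_TIEPOINT,
                    "d",
                    6,
                    (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0),
                ),
            ]
            if grid.nodata_value is not None:
                nodata_ascii = repr(float(grid.nodata_value))
                extratags.append((_TAG_GDAL_NODATA, "s", len(nodata_ascii), nodata_ascii))
            tifffile.imwrite(
                path,
                values,
                description=json.dumps(_grid_meta(grid)),
                extratags=extratags,
            )
        elif suffix == ".png":
            values = np.asarray(grid.values)
            if values.dtype == np.uint16:
                Image.fromarray(values, mode="I;16").save(path)
            else:
                arr = np.clip(np.rint(values), 0, 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(path)
        else:
            raise RasterIOError(f"unsupported raster format: {path}")
    except OSError as exc:
        raise RasterIOError(f"cannot write raster {path}: {exc}") from exc


def read_raster(path: str | Path, band: int | str | None = None) -> RasterGrid:
    """Read a GeoTIFF or grayscale PNG into a RasterGrid.

    Multi-band GeoTIFFs (stored as a 3-D page stack or samples-per-pixel)
    are indexed by integer band position or by label recorded in the file's
    JSON description.  PNGs are single-band with pixel-space defaults.
    """
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"no such raster file: {path}")
    suffix = path.suffix.lower()
    if suffix == ".png":
        try:
            img = Image.open(path)
            values = np.asarray(img)
        except OSError as exc:
            raise RasterIOError(f"cannot read raster {path}: {exc}") from exc
        if values.ndim != 2:
            raise RasterIOError(f"PNG is not single-channel grayscale: {path}")
        return RasterGrid(values=values, nodata_mask=np.zeros(values.shape, bool))
    if suffix not in (".tif", ".tiff"):
        raise RasterIOError(f"unsupported raster format: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = tif.asarray()
            description = page.description or ""
            tags = page.tags
            pixel_size = 1.0
            origin_x = origin_y = 0.0
            if _TAG_MODEL_PIXEL_SCALE in tags:
                pixel_size = float(tags[_TAG_MODEL_PIXEL_SCALE].value[0])
            if _TAG_MODEL_TIEPOINT in tags:
                tp = tags[_TAG_MODEL_TIEPOINT].value
                origin_x, origin_y = float(tp[3]), float(tp[4])
            nodata_value = None
            if _TAG_GDAL_NODATA in tags:
                nodata_value = float(str(tags[_TAG_GDAL_NODATA].value))
    except (OSError, tifffile.TiffFileError) as exc:
        raise RasterIOError(f"cannot read raster {path}: {exc}") from exc
    meta: dict = {}
    if description:
        try:
            meta = json.loads(description)
        except json.JSONDecodeError:
            meta = {}
    band_labels: list[str] = meta.get("band_labels", [])
    if data.ndim == 3:
        # pages-first or samples-last layout
        if data.shape[0] < data.shape[2]:
            n_bands, stack = data.shape[0], data
        else:
            n_bands, stack = data.shape[2], np.moveaxis(data, 2, 0)
        if band is None:
            band = 0
        if isinstance(band, str):
            if band not in band_labels:
                raise BandNotFoundError(
                    f"band {band!r} not in {path}; available: {band_labels or list(range(n_bands))}"
                )
            idx = band_labels.index(band)
        else:
            idx = int(band)
            if not 0 <= idx < n_bands:
                raise BandNotFoundError(
                    f"band index {idx} out of range for {path}; available: 0..{n_bands - 1}"
                )
        values = stack[idx]
        label = band_labels[idx] if idx < len(band_labels) else meta.get("band_label", "")
    else:
        if isinstance(band, str) and band not in ("", meta.get("band_label")):
            raise BandNotFoundError(
                f"band {band!r} not in {path}; available: [{meta.get('band_label', '')!r}]"
            )
        if isinstance(band, int) and band not in (0,):
            raise BandNotFoundError(f"band index {band} out of range for {path}; available: 0")
        values = data
        label = meta.get("band_label", "")
    if nodata_value is None:
        nodata_value = meta.get("nodata_value")
    nodata_mask = (
        np.zeros(values.shape, bool) if nodata_value is None else values == nodata_value
    )
    return RasterGrid(
        values=values,
        nodata_mask=nodata_mask,
        origin_x=meta.get("origin_x", origin_x),
        origin_y=meta.get("origin_y", origin_y),
        pixel_size=meta.get("pixel_size", pixel_size),
        band_label=label or "",
        crs_id=meta.get("crs_id", "pixel"),
        nodata_value=nodata_value,
    )


def rasterize_boundary(
    polygon: list[tuple[float, float]] | Polygon, reference: RasterGrid
) -> StudyAreaMask:
    """Rasterize a boundary polygon onto the reference grid.

    A pixel belongs to the study area iff its *center* lies inside the
    polygon (even-odd rule); centers exactly on an edge count as inside.
    """
    if isinstance(polygon, Polygon):
        poly = polygon
        n_distinct = len(set(poly.exterior.coords[:-1]))
    else:
        vertices = [tuple(map(float, v)) for v in polygon]
        n_distinct = len(set(vertices))
        if n_distinct < 3:
            raise InvalidGeometryError(
                f"polygon needs >= 3 distinct vertices, got {n_distinct}"
            )
        poly = Polygon(vertices)
    if n_distinct < 3 or poly.is_empty:
        raise InvalidGeometryError("degenerate polygon")
    rows, cols = reference.shape
    cs = reference.origin_x + (np.arange(cols) + 0.5) * reference.pixel_size
    rs = reference.origin_y + (np.arange(rows) + 0.5) * reference.pixel_size
    xx, yy = np.meshgrid(cs, rs)
    # intersects == inside-or-on-boundary, matching the inclusive edge rule
    inside = shapely.intersects_xy(poly, xx.ravel(), yy.ravel()).reshape(rows, cols)
    return StudyAreaMask(values=inside)


# --- block-grid manifest -------------------------------------------------

_MANIFEST_HEADER = ["ordinal", "row_off", "col_off", "window", "stride"]


def write_manifest(plan, path: str | Path, band_labels: list[str] | None = None) -> None:
    """Write a BlockPlan as CSV plus a JSON sidecar with grid metadata."""
    path = Path(path)
    try:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_MANIFEST_HEADER)
            for spec in plan.blocks:
                writer.writerow(
                    [spec.ordinal, spec.row_off, spec.col_off, plan.window, plan.stride]
                )
        sidecar = {
            "source_rows": plan.source_rows,
            "source_cols": plan.source_cols,
            "window": plan.window,
            "stride": plan.stride,
            "n_blocks": len(plan.blocks),
            "band_labels": band_labels or [],
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)
    except OSError as exc:
        raise RasterIOError(f"cannot write manifest {path}: {exc}") from exc


def read_manifest(path: str | Path):
    """Read a manifest CSV (+ JSON sidecar) back into a BlockPlan."""
    from forestcast.tiling import BlockPlan, BlockSpec

    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"no such manifest: {path}")
    blocks: list[BlockSpec] = []
    window = stride = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ManifestParseError("empty manifest", line=1)
        if [h.strip() for h in header] != _MANIFEST_HEADER:
            raise ManifestParseError(f"bad header {header!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ManifestParseError(f"expected 5 fields, got {len(row)}", line=lineno)
            try:
                ordinal, row_off, col_off, window, stride = (int(x) for x in row)
            except ValueError:
                raise ManifestParseError(f"non-integer field in {row!r}", line=lineno)
            blocks.append(BlockSpec(ordinal=ordinal, row_off=row_off, col_off=col_off, window=window))
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise ManifestParseError(f"missing JSON sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    if window is None:
        window, stride = meta["window"], meta["stride"]
    return BlockPlan(
        blocks=blocks,
        window=int(window),
        stride=int(stride),
        source_rows=int(meta["source_rows"]),
        source_cols=int(meta["source_cols"]),
        validate_blocks=False,
    )
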