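"""Overlapping block grid planning, cropping and stitching.

The planner traverses the mosaic with a sliding window (phase 1), discards
windows that contain no study-area pixel (phase 2), and then hill-climbs
extra windows onto any study-area pixels the lattice missed (phase 3), so
that every pixel inside the boundary lands in at least one block.  Adjacent
blocks overlap (stride <= window) so that stitched predictions blend
smoothly; stitching averages all blocks covering a pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from forestcast.errors import EmptyStudyAreaError, InvalidParametersError
from forestcast.raster_io import RasterGrid, StudyAreaMask


@dataclass(frozen=True)
class BlockSpec:
    """One square crop window: ordinal plus top-left pixel offsets."""

    ordinal: int
    row_off: int
    col_off: int
    window: int

    def __post_init__(self):
        if self.window <= 0 or self.row_off < 0 or self.col_off < 0:
            raise ValueError(f"invalid block spec {self!r}")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row_off, self.row_off + self.window),
            slice(self.col_off, self.col_off + self.window),
        )


@dataclass
class BlockPlan:
    """The ordered block grid produced by :func:`plan_blocks`."""

    blocks: list[BlockSpec]
    window: int
    stride: int
    source_rows: int
    source_cols: int
    validate_blocks: bool = field(default=True, repr=False)

    def __post_init__(self):
        if self.stride <= 0 or self.window <= 0 or self.stride > self.window:
            raise ValueError("need 0 < stride <= window")
        if self.validate_blocks:
            ordinals = [b.ordinal for b in self.blocks]
            if ordinals != list(range(len(self.blocks))):
                raise ValueError("ordinals must be contiguous from 0")
            for b in self.blocks:
                if b.row_off + b.window > self.source_rows or b.col_off + b.window > self.source_cols:
                    raise ValueError(f"block {b} exceeds source dimensions")

    def __len__(self) -> int:
        return len(self.blocks)

    def coverage_map(self) -> np.ndarray:
        """Count, per source pixel, how many blocks cover it."""
        counts = np.zeros((self.source_rows, self.source_cols), dtype=np.int32)
        for b in self.blocks:
            counts[b.slices()] += 1
        return counts


def _clamp(v: int, lo: int, hi: int) -> int:
    return max(lo, min(v, hi))


def coverage_completion(
    mask: StudyAreaMask,
    covered: np.ndarray,
    window: int,
    step: int = 1,
) -> list[BlockSpec]:
    """Place extra windows over study-area pixels the lattice missed.

    For each 4-connected component of uncovered study pixels, a window is
    seeded at the component centroid (clamped in-bounds) and hill-climbed:
    among the 8 neighbor moves of ``step`` pixels, take the one that most
    increases the count of newly covered uncovered pixels, stopping at a
    local maximum (ties broken toward the smallest (row_off, col_off)).
    Each emitted block covers at least one uncovered pixel, so the loop
    terminates.  Emitted ordinals are provisional (-1).
    """
    covered = np.array(covered, dtype=bool)
    rows, cols = mask.shape
    out: list[BlockSpec] = []

    def gain(r: int, c: int, uncovered: np.ndarray) -> int:
        return int(uncovered[r : r + window, c : c + window].sum())

    while True:
        uncovered = mask.values & ~covered
        if not uncovered.any():
            return out
        labels, n = ndimage.label(uncovered, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        rr, cc = np.nonzero(labels == 1)
        cen_r = int(round(rr.mean() - window / 2))
        cen_c = int(round(cc.mean() - window / 2))
        r = _clamp(cen_r, 0, rows - window)
        c = _clamp(cen_c, 0, cols - window)
        best = gain(r, c, uncovered)
        while True:
            cand = []
            for dr in (-step, 0, step):
                for dc in (-step, 0, step):
                    if dr == 0 and dc == 0:
                        continue
                    nr = _clamp(r + dr, 0, rows - window)
                    nc = _clamp(c + dc, 0, cols - window)
                    cand.append((gain(nr, nc, uncovered), nr, nc))
            cand.sort(key=lambda t: (-t[0], t[1], t[2]))
            g, nr, nc = cand[0]
            if g > best:
                best, r, c = g, nr, nc
            else:
                break
        if best == 0:
            # centroid window missed the component entirely (concave shapes);
            # fall back to a window anchored on the component's first pixel
            r = _clamp(int(rr[0]) - window // 2, 0, rows - window)
            c = _clamp(int(cc[0]) - window // 2, 0, cols - window)
            if gain(r, c, uncovered) == 0:
                r = _clamp(int(rr[0]), 0, rows - window)
                c = _clamp(int(cc[0]), 0, cols - window)
        out.append(BlockSpec(ordinal=-1, row_off=r, col_off=c, window=window))
        covered[r : r + window, c : c + window] = True


def plan_blocks(mask: StudyAreaMask, window: int, stride: int) -> BlockPlan:
    """Plan the overlapping block grid over a study-area mask.

    Phase 1 enumerates lattice windows at offsets (i*stride, j*stride) kept
    fully inside the grid, row-major; phase 2 keeps only windows containing
    at least one study pixel; phase 3 appends hill-climbed windows until
    every study pixel is covered.  Ordinals are assigned after completion in
    row-major (row_off, col_off) order, so the plan is deterministic.
    """
    rows, cols = mask.shape
    if not mask.values.any():
        raise EmptyStudyAreaError("study-area mask has no pixels")
    if not (0 < stride <= window <= min(rows, cols)):
        raise InvalidParametersError(
            f"need 0 < stride <= window <= min(grid dims); got window={window}, "
            f"stride={stride}, grid={rows}x{cols}"
        )
    kept: list[tuple[int, int]] = []
    covered = np.zeros((rows, cols), dtype=bool)
    for r in range(0, rows - window + 1, stride):
        for c in range(0, cols - window + 1, stride):
            if mask.values[r : r + window, c : c + window].any():
                kept.append((r, c))
                covered[r : r + window, c : c + window] = True
    extra = coverage_completion(mask, covered, window, step=stride)
    offsets = sorted(set(kept) | {(b.row_off, b.col_off) for b in extra})
    blocks = [
        BlockSpec(ordinal=i, row_off=r, col_off=c, window=window)
        for i, (r, c) in enumerate(offsets)
    ]
    return BlockPlan(
        blocks=blocks, window=window, stride=stride, source_rows=rows, source_cols=cols
    )


def crop_block(grid: RasterGrid, spec: BlockSpec) -> np.ndarray:
    """Exact pixel copy of one block window; no resampling."""
    rows, cols = grid.shape
    if spec.row_off + spec.window > rows or spec.col_off + spec.window > cols:
        raise IndexError(f"block {spec} out of bounds for grid {rows}x{cols}")
    return grid.values[spec.slices()].copy()


def stitch(
    frames: list[tuple[BlockSpec, np.ndarray]],
    plan: BlockPlan,
    reference: RasterGrid | None = None,
) -> RasterGrid:
    """Merge block frames into a full-area image, averaging overlaps.

    Each output pixel covered by k >= 1 blocks is the arithmetic mean of
    the k block values; uncovered pixels are nodata.  Georeference is
    copied from ``reference`` when given.
    """
    acc = np.zeros((plan.source_rows, plan.source_cols), dtype=np.float64)
    counts = np.zeros_like(acc, dtype=np.int32)
    mn = np.full_like(acc, np.inf)
    mx = np.full_like(acc, -np.inf)
    for spec, frame in frames:
        frame = np.asarray(frame)
        if frame.shape != (spec.window, spec.window):
            raise ValueError(
                f"frame shape {frame.shape} does not match window {spec.window} of {spec}"
            )
        sl = spec.slices()
        acc[sl] += frame
        counts[sl] += 1
        np.minimum(mn[sl], frame, out=mn[sl])
        np.maximum(mx[sl], frame, out=mx[sl])
    nodata = counts == 0
    values = np.divide(acc, counts, out=np.zeros_like(acc), where=~nodata)
    # mean of k equal values is that value, bit-exactly
    agree = ~nodata & (mn == mx)
    values[agree] = mn[agree]
    meta = {}
    if reference is not None:
        meta = dict(
            origin_x=reference.origin_x,
            origin_y=reference.origin_y,
            pixel_size=reference.pixel_size,
            band_label=reference.band_label,
            crs_id=reference.crs_id,
        )
    return RasterGrid(values=values, nodata_mask=nodata, **meta)
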