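"""Synthetic yearly raster stacks for testing the full pipeline offline.

The generator emulates the structure of a yearly Landsat mosaic archive
without any radiometric realism: a smooth latent spatial field (a coarse
random lattice upsampled bilinearly) drifts linearly year over year,
per-band offsets give correlated bands, i.i.d. Gaussian pixel noise and
saturating elliptical cloud blobs corrupt individual frames, and an
optional abrupt block-sized change event hits the final year — the failure
modes a forecaster meets in real archives.  A random convex boundary
polygon covering 30-70%% of the extent plays the study-area boundary.

Everything is driven by one seed, so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from forestcast.forecast_model import SeriesSample, condition_width, encode_condition
from forestcast.normalization import BlockSeries, ScalingParams, apply_scaling, fit_scaling
from forestcast.raster_io import RasterGrid, StudyAreaMask, rasterize_boundary
from forestcast.tiling import BlockPlan, crop_block, plan_blocks

DEFAULT_BANDS = ["B1", "B2", "B3", "B4", "B5", "B6", "B7", "B8"]


@dataclass
class SynthConfig:
    """Knobs of the synthetic archive.

    ``trend_amplitude`` is the mean DN drift per year; ``noise_sd`` the
    i.i.d. pixel noise; ``cloud_rate`` the expected number of cloud blobs
    per frame (Poisson); ``event_rate`` the probability that one
    window-sized patch changes abruptly in the final year.
    """

    rows: int = 128
    cols: int = 128
    n_years: int = 21
    bands: list[str] = field(default_factory=lambda: list(DEFAULT_BANDS))
    trend_amplitude: float = 1.0
    noise_sd: float = 2.0
    cloud_rate: float = 0.2
    event_rate: float = 0.05
    base_level: float = 100.0
    base_range: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.rows <= 0 or self.cols <= 0 or self.n_years <= 0 or not self.bands:
            raise ValueError("sizes must be positive and bands non-empty")
        if min(self.trend_amplitude, self.noise_sd, self.cloud_rate, self.event_rate) < 0:
            raise ValueError("rates must be >= 0")


def _smooth_field(rng: np.random.Generator, rows: int, cols: int, coarse: int = 6) -> np.ndarray:
    """Band-limited random surface in [0, 1]: coarse lattice, bilinear upsample."""
    lattice = rng.random((coarse, coarse))
    zr = np.linspace(0, coarse - 1, rows)
    zc = np.linspace(0, coarse - 1, cols)
    coords = np.meshgrid(zr, zc, indexing="ij")
    return ndimage.map_coordinates(lattice, coords, order=1, mode="nearest")


def _add_clouds(frame: np.ndarray, rng: np.random.Generator, rate: float) -> None:
    """Overwrite Poisson-many elliptical blobs with saturated DN 255."""
    rows, cols = frame.shape
    for _ in range(rng.poisson(rate)):
        cr, cc = rng.integers(0, rows), rng.integers(0, cols)
        ar = rng.uniform(2, max(3, rows // 8))
        ac = rng.uniform(2, max(3, cols // 8))
        rr, cc2 = np.ogrid[:rows, :cols]
        frame[((rr - cr) / ar) ** 2 + ((cc2 - cc) / ac) ** 2 <= 1.0] = 255.0


def gen_stack(config: SynthConfig) -> tuple[dict[str, list[RasterGrid]], list[tuple[float, float]]]:
    """Generate yearly RasterGrids per band plus a boundary polygon.

    The latent field drifts by exactly ``trend_amplitude`` mean DN per
    year (a smooth trend surface normalized to unit mean); each band is an
    offset copy of the latent field, then noise, clouds and the final-year
    change event are applied per frame.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.rows, config.cols
    base = config.base_level + config.base_range * (_smooth_field(rng, rows, cols) - 0.5)
    trend_shape = _smooth_field(rng, rows, cols) + 0.5
    trend = config.trend_amplitude * trend_shape / trend_shape.mean()
    band_offsets = {b: rng.uniform(-20.0, 20.0) for b in config.bands}
    event = config.event_rate > 0 and rng.random() < config.event_rate
    if event:
        w = max(4, min(rows, cols) // 4)
        er = int(rng.integers(0, rows - w + 1))
        ec = int(rng.integers(0, cols - w + 1))
        eshift = rng.uniform(30.0, 80.0)
    stacks: dict[str, list[RasterGrid]] = {b: [] for b in config.bands}
    for year_idx in range(config.n_years):
        latent = base + year_idx * trend
        for b in config.bands:
            frame = latent + band_offsets[b]
            if config.noise_sd > 0:
                frame = frame + rng.normal(0.0, config.noise_sd, (rows, cols))
            else:
                frame = frame.copy()
            if event and year_idx == config.n_years - 1:
                frame[er : er + w, ec : ec + w] += eshift
            _add_clouds(frame, rng, config.cloud_rate)
            stacks[b].append(
                RasterGrid(
                    values=frame,
                    nodata_mask=np.zeros((rows, cols), bool),
                    band_label=b,
                    crs_id="synthetic",
                )
            )
    polygon = _convex_boundary(rng, rows, cols)
    return stacks, polygon


def _convex_boundary(
    rng: np.random.Generator, rows: int, cols: int
) -> list[tuple[float, float]]:
    """Random convex polygon covering 30-70%% of the extent (rejection sampled)."""
    from scipy.spatial import ConvexHull

    extent_area = rows * cols
    for _ in range(200):
        pts = np.column_stack(
            [rng.uniform(0, cols, 12), rng.uniform(0, rows, 12)]
        )
        hull = ConvexHull(pts)
        if 0.3 <= hull.volume / extent_area <= 0.7:
            return [tuple(pts[i]) for i in hull.vertices]
    # fall back to a centered rectangle of ~50% area
    mx, my = cols / 2, rows / 2
    hw, hh = cols * 0.3536, rows * 0.3536
    return [
        (mx - hw, my - hh),
        (mx + hw, my - hh),
        (mx + hw, my + hh),
        (mx - hw, my + hh),
    ]


def build_series(
    stacks: dict[str, list[RasterGrid]],
    plan: BlockPlan,
    years: list[int] | None = None,
) -> dict[tuple[int, str], BlockSeries]:
    """Crop every (block, band) into a BlockSeries via the real tiling path."""
    out: dict[tuple[int, str], BlockSeries] = {}
    for band, grids in stacks.items():
        ylabels = years if years is not None else list(range(len(grids)))
        for spec in plan.blocks:
            frames = [crop_block(g, spec) for g in grids]
            out[(spec.ordinal, band)] = BlockSeries(
                ordinal=spec.ordinal, band_label=band, years=list(ylabels), frames=frames
            )
    return out


def _scaled_clipped(frame: np.ndarray, params: ScalingParams) -> np.ndarray:
    return np.clip(apply_scaling(frame, params), 0.0, 1.0)


def gen_block_dataset(
    config: SynthConfig, window: int, stride: int, j: int, full_cover: bool = False
) -> tuple[BlockPlan, list[SeriesSample], dict[tuple[int, str], ScalingParams]]:
    """Run tiling + scaling on a synthetic stack; emit final-year samples.

    For each (block, band): scaling is fitted on the training years (all
    but the last), the j last training frames become the inputs and the
    final year the target, clipped to [0, 1].  Sample count is
    blocks x bands.  Returns the plan, the samples (ordered by (ordinal,
    band)), and the fitted scaling table.  ``full_cover`` replaces the
    convex boundary with an all-true mask (a regular full grid of blocks).
    """
    if config.n_years < j + 1:
        raise ValueError(f"need n_years >= j+1, got {config.n_years} < {j + 1}")
    stacks, polygon = gen_stack(config)
    reference = next(iter(stacks.values()))[0]
    if full_cover:
        mask = StudyAreaMask(np.ones((config.rows, config.cols), bool))
    else:
        mask = rasterize_boundary(polygon, reference)
    plan = plan_blocks(mask, window, stride)
    series = build_series(stacks, plan)
    width = condition_width(len(plan))
    samples: list[SeriesSample] = []
    scaling: dict[tuple[int, str], ScalingParams] = {}
    for (ordinal, band), s in sorted(series.items()):
        train_series = BlockSeries(
            ordinal=ordinal, band_label=band, years=s.years[:-1], frames=s.frames[:-1]
        )
        params = fit_scaling(train_series)
        scaling[(ordinal, band)] = params
        inputs = [_scaled_clipped(f, params) for f in s.frames[-1 - j : -1]]
        target = _scaled_clipped(s.frames[-1], params)
        samples.append(
            SeriesSample(
                condition=encode_condition(ordinal, width), inputs=inputs, target=target
            )
        )
    return plan, samples, scaling


def gen_training_windows(
    series: dict[tuple[int, str], BlockSeries],
    scaling: dict[tuple[int, str], ScalingParams],
    j: int,
    condition_bits: int,
    holdout_last: bool = True,
) -> list[SeriesSample]:
    """Sliding-window training samples with targets inside the training span.

    For each (block, band) series, every window of j consecutive frames
    whose target year is NOT the held-out final year (when ``holdout_last``)
    yields one sample, scaled with that block's fitted params.
    """
    samples: list[SeriesSample] = []
    for (ordinal, band), s in sorted(series.items()):
        params = scaling[(ordinal, band)]
        last_target = s.n - 1 if holdout_last else s.n
        for t in range(j, last_target):
            inputs = [_scaled_clipped(f, params) for f in s.frames[t - j : t]]
            target = _scaled_clipped(s.frames[t], params)
            samples.append(
                SeriesSample(
                    condition=encode_condition(ordinal, condition_bits),
                    inputs=inputs,
                    target=target,
                )
            )
    return samples
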