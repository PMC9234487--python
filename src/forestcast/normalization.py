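"""Per-block, per-band temporal statistics and max-min scaling.

Each block's yearly frames for one band form a :class:`BlockSeries`.  Before
training, pixel values are rescaled to [0, 1] with max-min scaling fitted
over the series' training span; the fitted :class:`ScalingParams` invert the
scaling exactly after prediction so that metrics are computed in raw digital
numbers.  Temporal mean/variance and the per-pixel temporal standard
deviation are reported alongside for stability analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from forestcast.errors import InsufficientFramesError

DEFAULT_EPS = 1e-8


@dataclass
class BlockSeries:
    """Ordered yearly frames of one block for one band."""

    ordinal: int
    band_label: str
    years: list[int]
    frames: list[np.ndarray]

    def __post_init__(self):
        self.frames = [np.asarray(f, dtype=np.float64) for f in self.frames]
        if len(self.frames) != len(self.years):
            raise ValueError("years and frames must have equal length")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError(f"frames differ in shape: {shapes}")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.frames)

    def stack(self) -> np.ndarray:
        return np.stack(self.frames, axis=0)


@dataclass
class ScalingParams:
    """Max-min scaling bounds for one (block, band) series."""

    lo: float
    hi: float
    eps: float = DEFAULT_EPS

    def __post_init__(self):
        if self.hi < self.lo:
            raise ValueError("hi must be >= lo")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


def temporal_stats(series: BlockSeries) -> tuple[float, float, np.ndarray]:
    """Mean, population variance, and per-pixel temporal std of a series.

    The scalar mean/variance pool every pixel of every frame (divisor
    n*pixels); ``per_pixel_std`` is the temporal standard deviation at each
    pixel position across years.  The block-level scalar std used in
    stability reports is ``sqrt(variance)``.
    """
    if series.n < 2:
        raise InsufficientFramesError(
            f"need >= 2 frames for temporal stats, got {series.n}"
        )
    stack = series.stack()
    mean = float(stack.mean())
    variance = float(stack.var())  # population (divisor N)
    per_pixel_std = stack.std(axis=0)
    return mean, variance, per_pixel_std


def fit_scaling(series: BlockSeries, eps: float = DEFAULT_EPS) -> ScalingParams:
    """Global min/max over every pixel of every frame in the series."""
    if series.n < 1:
        raise InsufficientFramesError("need >= 1 frame to fit scaling")
    stack = series.stack()
    return ScalingParams(lo=float(stack.min()), hi=float(stack.max()), eps=eps)


def apply_scaling(frame: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Map raw values to [0, 1]: (x - lo) / max(hi - lo, eps).

    A constant series (hi == lo) maps to all zeros by the eps guard.
    """
    denom = max(params.hi - params.lo, params.eps)
    return (np.asarray(frame, dtype=np.float64) - params.lo) / denom


def invert_scaling(scaled: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Exact inverse of :func:`apply_scaling` (up to float rounding)."""
    denom = max(params.hi - params.lo, params.eps)
    return np.asarray(scaled, dtype=np.float64) * denom + params.lo


# --- persistence ---------------------------------------------------------


def save_scaling_table(
    table: dict[tuple[int, str], ScalingParams], path: str | Path
) -> None:
    """Persist per-(ordinal, band) scaling params as a JSON table."""
    records = [
        {"ordinal": k[0], "band": k[1], "lo": p.lo, "hi": p.hi, "eps": p.eps}
        for k, p in sorted(table.items())
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def load_scaling_table(path: str | Path) -> dict[tuple[int, str], ScalingParams]:
    with open(path) as fh:
        records = json.load(fh)
    return {
        (int(r["ordinal"]), r["band"]): ScalingParams(lo=r["lo"], hi=r["hi"], eps=r["eps"])
        for r in records
    }
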