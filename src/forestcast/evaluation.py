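"""Prediction scoring: RMSE/NRMSE, segmentation correct rate, aggregation.

NRMSE divides the RMSE by the population standard deviation of the true
values, so 1.0 is the score of always predicting the block's mean; values
below 1 beat that baseline.  Scores are computed per (block, band) on raw
digital numbers (after inverting the training scaling), aggregated to
per-band mean/std, grouped into four equal-width score intervals, and
paired with each block's temporal standard deviation for stability
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from forestcast.errors import UndefinedMetricError
from forestcast.normalization import BlockSeries, temporal_stats


@dataclass
class BlockScore:
    """Scores of one block for one band."""

    ordinal: int
    band: str
    rmse: float
    nrmse: float
    sigma: float
    quartile: int | None = None


@dataclass
class MetricsReport:
    """Per-block scores with per-band aggregates and segmentation CR."""

    per_block: list[BlockScore]
    aggregates: dict[str, tuple[float, float]] = field(default_factory=dict)
    cr: float | None = None
    quartile_edges: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ordinal": s.ordinal,
                    "band": s.band,
                    "rmse": s.rmse,
                    "nrmse": s.nrmse,
                    "sigma": s.sigma,
                    "quartile": s.quartile,
                }
                for s in self.per_block
            ]
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error over flattened arrays."""
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    y_pred = np.asarray(y_pred, dtype=np.float64).ravel()
    if y_true.size != y_pred.size:
        raise ValueError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    if y_true.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def nrmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """RMSE normalized by the population std of the true values.

    Predicting the mean of ``y_true`` everywhere scores exactly 1.0;
    constant truth (sigma = 0) leaves the metric undefined.
    """
    y_true = np.asarray(y_true, dtype=np.float64).ravel()
    if y_true.size < 2:
        raise ValueError("need >= 2 values for NRMSE")
    sigma = float(y_true.std())  # population, divisor n
    if sigma == 0.0:
        raise UndefinedMetricError("NRMSE undefined: constant y_true (sigma = 0)")
    return rmse(y_true, y_pred) / sigma


def correct_rate(
    mask_pred: np.ndarray, mask_true: np.ndarray, scope: np.ndarray | None = None
) -> float:
    """Fraction of scope pixels where the two binary masks agree.

    num_hit counts agreeing pixels inside ``scope`` (default: everywhere),
    num_miss the disagreeing ones; CR = num_hit / (num_hit + num_miss).
    """
    mask_pred = np.asarray(mask_pred, dtype=bool)
    mask_true = np.asarray(mask_true, dtype=bool)
    if mask_pred.shape != mask_true.shape:
        raise ValueError("mask shapes differ")
    if scope is None:
        scope = np.ones(mask_pred.shape, dtype=bool)
    scope = np.asarray(scope, dtype=bool)
    if scope.shape != mask_pred.shape:
        raise ValueError("scope shape differs from masks")
    n_scope = int(scope.sum())
    if n_scope == 0:
        raise ValueError("empty scope")
    num_hit = int((mask_pred[scope] == mask_true[scope]).sum())
    return num_hit / n_scope


def aggregate_scores(per_block: list[BlockScore], band: str) -> tuple[float, float]:
    """Mean and population std of NRMSE over one band's blocks."""
    scores = np.array([s.nrmse for s in per_block if s.band == band])
    if scores.size == 0:
        raise ValueError(f"no records for band {band!r}")
    return float(scores.mean()), float(scores.std())


def quartile_groups(
    per_block: list[BlockScore], band: str, equal_count: bool = False
) -> tuple[list[BlockScore], np.ndarray]:
    """Assign each block to one of four score intervals Q1..Q4 (Q1 lowest).

    Default: the [min, max] NRMSE range is split into four equal-width
    intervals, right edge inclusive on the last; a degenerate range puts
    everything in Q1.  ``equal_count=True`` uses quartile (equal-count)
    groups instead.
    """
    records = [s for s in per_block if s.band == band]
    if len(records) < 4:
        raise ValueError(f"need >= 4 records for quartile grouping, got {len(records)}")
    scores = np.array([s.nrmse for s in records])
    if equal_count:
        edges = np.quantile(scores, [0.0, 0.25, 0.5, 0.75, 1.0])
    else:
        edges = np.linspace(scores.min(), scores.max(), 5)
    for s, x in zip(records, scores):
        if edges[0] == edges[-1]:
            q = 1
        else:
            q = int(np.searchsorted(edges[1:-1], x, side="right")) + 1
        s.quartile = min(q, 4)
    return records, edges


def stability_report(
    series_by_ordinal: dict[int, BlockSeries], per_block: list[BlockScore]
) -> list[tuple[int, float, float]]:
    """Pair each block's temporal std with its RMSE, sorted by RMSE.

    The temporal std is the scalar std of the block's full yearly stack
    (sqrt of the pooled population variance); blocks that are temporally
    stable tend to be the easiest to predict.
    """
    out = []
    for s in per_block:
        if s.ordinal not in series_by_ordinal:
            raise KeyError(f"no series for block ordinal {s.ordinal}")
        _, variance, _ = temporal_stats(series_by_ordinal[s.ordinal])
        out.append((s.ordinal, float(np.sqrt(variance)), s.rmse))
    return sorted(out, key=lambda t: t[2])


def score_blocks(
    truths: dict[tuple[int, str], np.ndarray],
    preds: dict[tuple[int, str], np.ndarray],
) -> MetricsReport:
    """Score every (ordinal, band) pair present in both dicts.

    Blocks with constant truth (sigma = 0) are excluded from the report
    (the NRMSE is undefined there) but counted in ``n_skipped``.
    """
    per_block: list[BlockScore] = []
    for (ordinal, band) in sorted(truths):
        if (ordinal, band) not in preds:
            continue
        y, yhat = truths[(ordinal, band)], preds[(ordinal, band)]
        try:
            score = nrmse(y, yhat)
        except UndefinedMetricError:
            continue
        per_block.append(
            BlockScore(
                ordinal=ordinal,
                band=band,
                rmse=rmse(y, yhat),
                nrmse=score,
                sigma=float(np.asarray(y, dtype=np.float64).std()),
            )
        )
    report = MetricsReport(per_block=per_block)
    for band in sorted({s.band for s in per_block}):
        report.aggregates[band] = aggregate_scores(per_block, band)
        if sum(s.band == band for s in per_block) >= 4:
            _, edges = quartile_groups(per_block, band)
            report.quartile_edges[band] = edges
    return report
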