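"""Completeness metrics over presence matrices.

Two reduction modes are supported:

* ``"all-levels"`` — every frame x level cell is scored; the overall
  accuracy is the fraction of agreeing indicator cells over ``N x 17``.
* ``"annotated-only"`` — crop semantics: each frame carries exactly one
  ground-truth level (its annotated vertebra) and only that cell is scored,
  so per-level counts are vertebra-image pairs.

Scan-level metrics operate on OR-aggregated per-scan presence vectors: the
per-scan completeness rate is the fraction of scans that predict every level
the ground truth marks visible, and the mean missing-vertebra frequency is
the mean fraction of visible levels a scan's prediction misses.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import LEVEL_NAMES, LEVELS, N_LEVELS, VertebralLevel, validate_presence_matrix

__all__ = [
    "MODES",
    "UndefinedMetricError",
    "LevelAccuracy",
    "CompletenessReport",
    "overall_accuracy",
    "per_level_accuracy",
    "per_scan_completeness",
    "mean_missing_frequency",
    "level_report",
    "round_half_up",
]

MODES = ("all-levels", "annotated-only")


class UndefinedMetricError(ValueError):
    """A metric has an empty denominator and no defined value."""


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, matching how report tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _check_pair(gt: pd.DataFrame, pred: pd.DataFrame) -> None:
    validate_presence_matrix(gt)
    validate_presence_matrix(pred)
    if list(gt.index) != list(pred.index):
        raise ValueError("ground-truth and predicted matrices must share frame_ids "
                         "in the same order")


def _annotated_levels(gt: pd.DataFrame) -> np.ndarray:
    """Column index (0-based ordinal - 1) of each frame's single annotated level."""
    vals = gt.to_numpy()
    counts = vals.sum(axis=1)
    bad = np.flatnonzero(counts != 1)
    if bad.size:
        raise ValueError(
            "annotated-only mode requires exactly one ground-truth level per "
            f"frame; offending frames: {list(gt.index[bad[:5]])}"
        )
    return vals.argmax(axis=1)


def overall_accuracy(gt: pd.DataFrame, pred: pd.DataFrame, mode: str = "all-levels") -> float:
    """Fraction of agreeing presence indicators between prediction and truth."""
    _check_pair(gt, pred)
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    g, p = gt.to_numpy(), pred.to_numpy()
    if g.shape[0] == 0:
        raise UndefinedMetricError("no frames to score")
    agree = g == p
    if mode == "all-levels":
        return float(agree.mean())
    cols = _annotated_levels(gt)
    return float(agree[np.arange(len(cols)), cols].mean())


def per_level_accuracy(
    gt: pd.DataFrame,
    pred: pd.DataFrame,
    level: VertebralLevel,
    mode: str = "all-levels",
) -> tuple[int, int, float]:
    """``(n_pairs, n_correct, accuracy)`` for one vertebral level.

    In all-levels mode every frame contributes a pair at every level; in
    annotated-only mode only frames annotated at ``level`` count.  An empty
    denominator raises :class:`UndefinedMetricError` rather than silently
    reporting 0 or 1.
    """
    _check_pair(gt, pred)
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    col = level.ordinal - 1
    g, p = gt.to_numpy(), pred.to_numpy()
    if mode == "all-levels":
        mask = np.ones(g.shape[0], dtype=bool)
    else:
        mask = _annotated_levels(gt) == col
    n_pairs = int(mask.sum())
    if n_pairs == 0:
        raise UndefinedMetricError(
            f"no evaluated pairs at level {level.name} in mode {mode!r}"
        )
    n_correct = int((g[mask, col] == p[mask, col]).sum())
    return n_pairs, n_correct, n_correct / n_pairs


def per_scan_completeness(
    gt_scans: pd.DataFrame, pred_scans: pd.DataFrame
) -> float:
    """Fraction of scans predicting present every level visible in the truth."""
    _check_pair(gt_scans, pred_scans)
    g, p = gt_scans.to_numpy(), pred_scans.to_numpy()
    if g.shape[0] == 0:
        raise UndefinedMetricError("no scans to score")
    complete = ((p >= g) | (g == 0)).all(axis=1)
    return float(complete.mean())


def mean_missing_frequency(
    gt_scans: pd.DataFrame, pred_scans: pd.DataFrame
) -> float:
    """Mean over scans of (visible levels missed) / (visible levels)."""
    _check_pair(gt_scans, pred_scans)
    g, p = gt_scans.to_numpy(), pred_scans.to_numpy()
    if g.shape[0] == 0:
        raise UndefinedMetricError("no scans to score")
    visible = g.sum(axis=1)
    if (visible == 0).any():
        raise UndefinedMetricError("a scan has no ground-truth-visible level")
    missed = ((g == 1) & (p == 0)).sum(axis=1)
    return float((missed / visible).mean())


@dataclass(frozen=True)
class LevelAccuracy:
    level: VertebralLevel
    n_pairs: int
    n_correct: int
    accuracy: float


@dataclass(frozen=True)
class CompletenessReport:
    """Per-level and overall completeness summary (optionally scan-level)."""

    mode: str
    overall_accuracy: float
    per_level: tuple[LevelAccuracy, ...]
    per_scan_completeness_rate: Optional[float] = None
    mean_missing_frequency: Optional[float] = None

    def level(self, level: VertebralLevel) -> LevelAccuracy:
        return self.per_level[level.ordinal - 1]

    def to_frame(self) -> pd.DataFrame:
        """Per-level table with columns level, n_pairs, n_correct, accuracy."""
        return pd.DataFrame(
            {
                "level": [r.level.name for r in self.per_level],
                "n_pairs": [r.n_pairs for r in self.per_level],
                "n_correct": [r.n_correct for r in self.per_level],
                "accuracy": [
                    round_half_up(r.accuracy, 3) if r.n_pairs else float("nan")
                    for r in self.per_level
                ],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def level_report(
    gt: pd.DataFrame,
    pred: pd.DataFrame,
    mode: str = "all-levels",
    gt_scans: Optional[pd.DataFrame] = None,
    pred_scans: Optional[pd.DataFrame] = None,
) -> CompletenessReport:
    """Assemble the full completeness report, per-level rows in T1..L5 order.

    Scan-level metrics are included when OR-aggregated per-scan matrices are
    supplied.
    """
    rows = []
    for lvl in LEVELS:
        try:
            n_pairs, n_correct, acc = per_level_accuracy(gt, pred, lvl, mode=mode)
        except UndefinedMetricError:
            # a level never evaluated stays visibly undefined (NaN), never 0/1
            n_pairs, n_correct, acc = 0, 0, float("nan")
        rows.append(LevelAccuracy(lvl, n_pairs, n_correct, acc))
    scan_rate = missing = None
    if gt_scans is not None and pred_scans is not None:
        scan_rate = per_scan_completeness(gt_scans, pred_scans)
        missing = mean_missing_frequency(gt_scans, pred_scans)
    return CompletenessReport(
        mode=mode,
        overall_accuracy=overall_accuracy(gt, pred, mode=mode),
        per_level=tuple(rows),
        per_scan_completeness_rate=scan_rate,
        mean_missing_frequency=missing,
    )
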