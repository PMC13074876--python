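"""Vertebral-level scale, detection records, and presence-matrix construction.

The thoracolumbar spine is represented as 17 ordered levels, T1..T12 followed
by L1..L5.  A frame's visibility pattern is a binary 17-vector (one indicator
per level); stacking frame vectors yields the Vertebra Presence Matrix (VPM),
the core completeness representation.  Ground-truth vectors come from the
annotation set of a frame; predicted vectors from thresholding detector
confidences, optionally gated on overlap with a same-level annotation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import BBox, iou

__all__ = [
    "VertebralLevel",
    "LEVELS",
    "LEVEL_NAMES",
    "N_LEVELS",
    "DEFAULT_TAU",
    "DEFAULT_IOU_THRESHOLD",
    "Annotation",
    "Detection",
    "FrameRecord",
    "Scan",
    "level_from_name",
    "gt_vpm",
    "predicted_vpm",
    "scan_vpm",
    "presence_matrix",
    "validate_presence_matrix",
    "build_matrices",
]

#: Confidence threshold tau converting detector scores into binary presence.
DEFAULT_TAU = 0.25
#: A detection is geometrically valid at IoU >= 0.5 with its ground-truth box.
DEFAULT_IOU_THRESHOLD = 0.5

N_LEVELS = 17


class VertebralLevel(enum.IntEnum):
    """One of the 17 thoracolumbar levels; the integer value is the ordinal."""

    T1 = 1
    T2 = 2
    T3 = 3
    T4 = 4
    T5 = 5
    T6 = 6
    T7 = 7
    T8 = 8
    T9 = 9
    T10 = 10
    T11 = 11
    T12 = 12
    L1 = 13
    L2 = 14
    L3 = 15
    L4 = 16
    L5 = 17

    @property
    def ordinal(self) -> int:
        return int(self)

    @property
    def is_thoracic(self) -> bool:
        return self <= VertebralLevel.T12

    @property
    def is_lumbar(self) -> bool:
        return self >= VertebralLevel.L1


LEVELS: tuple[VertebralLevel, ...] = tuple(VertebralLevel)
LEVEL_NAMES: tuple[str, ...] = tuple(lvl.name for lvl in LEVELS)


def level_from_name(name: str) -> VertebralLevel:
    """Look up a level by its canonical name (``T1``..``T12``, ``L1``..``L5``).

    Case-insensitive.  Names outside the T1-L5 range (cervical, sacral, or
    anything else) raise ``ValueError`` naming the offending token.
    """
    token = str(name).strip().upper()
    try:
        return VertebralLevel[token]
    except KeyError:
        raise ValueError(
            f"unknown vertebral level {name!r}: expected one of {', '.join(LEVEL_NAMES)}"
        ) from None


@dataclass(frozen=True)
class Annotation:
    """Ground-truth box for one vertebral level in one frame."""

    frame_id: str
    level: VertebralLevel
    bbox: BBox


@dataclass(frozen=True)
class Detection:
    """Detector output box with confidence; level is absent in single-class mode."""

    frame_id: str
    bbox: BBox
    confidence: float
    level: Optional[VertebralLevel] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class FrameRecord:
    """One frame's annotations and detections, the unit the pipeline consumes."""

    frame_id: str
    annotations: tuple[Annotation, ...] = field(default_factory=tuple)
    detections: tuple[Detection, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class Scan:
    """A subject's sweep: an ordered group of frames."""

    scan_id: str
    subject_id: str
    frames: tuple[FrameRecord, ...]
    split: Optional[str] = None


def _check_single_frame(records: Sequence, what: str) -> None:
    ids = {r.frame_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"{what} span multiple frames: {sorted(ids)}")


def gt_vpm(annotations: Sequence[Annotation]) -> np.ndarray:
    """Ground-truth presence vector of one frame.

    Element ``v`` is 1 iff an annotation with level ``v`` exists.  The
    annotation protocol allows at most one box per level per frame, so
    duplicate levels raise.
    """
    _check_single_frame(annotations, "annotations")
    vec = np.zeros(N_LEVELS, dtype=np.int8)
    seen: set[VertebralLevel] = set()
    for ann in annotations:
        if ann.level in seen:
            raise ValueError(
                f"duplicate annotation for level {ann.level.name} in frame "
                f"{ann.frame_id!r}"
            )
        seen.add(ann.level)
        vec[ann.level.ordinal - 1] = 1
    return vec


def predicted_vpm(
    detections: Sequence[Detection],
    tau: float = DEFAULT_TAU,
    annotations: Optional[Sequence[Annotation]] = None,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> np.ndarray:
    """Predicted presence vector: level ``v`` is 1 iff some detection for
    ``v`` has confidence >= ``tau``.

    When ``annotations`` is given (evaluation mode) a detection additionally
    has to overlap a same-level ground-truth box at IoU >= ``iou_threshold``
    to count as a valid presence; pass ``annotations=None`` for
    prediction-only use.  Duplicate detections per level are allowed (the
    presence rule is existential).
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must lie in [0, 1], got {tau}")
    _check_single_frame(detections, "detections")
    by_level: dict[VertebralLevel, list[BBox]] = {}
    if annotations is not None:
        for ann in annotations:
            by_level.setdefault(ann.level, []).append(ann.bbox)
    vec = np.zeros(N_LEVELS, dtype=np.int8)
    for det in detections:
        if det.level is None:
            raise ValueError(
                "detection carries no level label (single-class output); assign "
                "levels first via IoU matching (geometry.match_detections) or "
                "positional assignment (correction.correct_sequence)"
            )
        if det.confidence < tau:
            continue
        if annotations is not None:
            gt_boxes = by_level.get(det.level, [])
            if not any(iou(det.bbox, g) >= iou_threshold for g in gt_boxes):
                continue
        vec[det.level.ordinal - 1] = 1
    return vec


def scan_vpm(frame_vectors: Sequence[np.ndarray]) -> np.ndarray:
    """Scan-level presence: element-wise OR across a scan's frame vectors.

    A level counts as covered by the scan if it is present in at least one
    frame of the sweep.
    """
    if len(frame_vectors) == 0:
        raise ValueError("scan_vpm requires at least one frame vector")
    stacked = np.vstack([np.asarray(v, dtype=np.int8) for v in frame_vectors])
    if stacked.shape[1] != N_LEVELS:
        raise ValueError(f"presence vectors must have {N_LEVELS} elements")
    return (stacked.max(axis=0) > 0).astype(np.int8)


def presence_matrix(
    rows: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    frame_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Stack frame presence vectors into a frame x level DataFrame.

    Columns are the 17 level names in anatomical order; the index is the
    frame identifiers in the given order.
    """
    if isinstance(rows, Mapping):
        frame_ids = list(rows.keys())
        data = np.vstack([rows[f] for f in frame_ids]) if frame_ids else np.zeros((0, N_LEVELS), np.int8)
    else:
        if frame_ids is None:
            raise ValueError("frame_ids required when rows is a sequence")
        if len(frame_ids) != len(rows):
            raise ValueError("frame_ids and rows must have equal length")
        data = np.vstack(list(rows)) if len(rows) else np.zeros((0, N_LEVELS), np.int8)
    df = pd.DataFrame(data.astype(np.int8), index=list(frame_ids), columns=list(LEVEL_NAMES))
    validate_presence_matrix(df)
    return df


def validate_presence_matrix(matrix: pd.DataFrame) -> None:
    """Raise unless ``matrix`` is a binary frame x 17-level table."""
    if list(matrix.columns) != list(LEVEL_NAMES):
        raise ValueError(
            f"presence matrix columns must be {list(LEVEL_NAMES)}, got {list(matrix.columns)}"
        )
    vals = matrix.to_numpy()
    if vals.size and not np.isin(vals, (0, 1)).all():
        raise ValueError("presence matrix entries must be 0 or 1")


def build_matrices(
    frames: Iterable[FrameRecord],
    tau: float = DEFAULT_TAU,
    iou_gate: bool = True,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ground-truth and predicted presence matrices for a set of frames.

    With ``iou_gate`` (evaluation default) a detection counts only when it
    overlaps a same-level annotation at IoU >= ``iou_threshold``.
    """
    gt_rows: dict[str, np.ndarray] = {}
    pred_rows: dict[str, np.ndarray] = {}
    for fr in frames:
        if fr.frame_id in gt_rows:
            raise ValueError(f"duplicate frame_id {fr.frame_id!r}")
        gt_rows[fr.frame_id] = gt_vpm(fr.annotations)
        pred_rows[fr.frame_id] = predicted_vpm(
            fr.detections,
            tau=tau,
            annotations=fr.annotations if iou_gate else None,
            iou_threshold=iou_threshold,
        )
    return presence_matrix(gt_rows), presence_matrix(pred_rows)
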