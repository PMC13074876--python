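"""Box arithmetic, IoU matching, ROI and vertebra-centric crop geometry.

Coordinate convention: continuous pixel coordinates with the origin at the
top-left corner, ``x`` increasing rightward (lateral) and ``y`` increasing
downward (cranio-caudal).  Boxes are half-open, ``[x_min, x_max) x
[y_min, y_max)``, which makes areas and intersections exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "BBox",
    "CropSpec",
    "FrameImage",
    "CROP_SCALE_SWEEP",
    "iou",
    "subject_roi",
    "vertebra_crop",
    "match_detections",
    "standardize_frame",
    "load_frame",
]

#: Crop-scale factors used by the sensitivity sweep.
CROP_SCALE_SWEEP = (1.00, 1.25, 1.50, 2.00)

STANDARD_SIZE = 640


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in pixel coordinates, half-open on both axes."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        for v in (self.x_min, self.y_min, self.x_max, self.y_max):
            if not math.isfinite(v):
                raise ValueError(f"non-finite box coordinate: {v!r}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                "degenerate box: require x_min < x_max and y_min < y_max, got "
                f"({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def astuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes; 0.0 when disjoint, 1.0 iff equal."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def _boxes(items: Iterable) -> list[BBox]:
    out = []
    for item in items:
        out.append(item if isinstance(item, BBox) else item.bbox)
    return out


def subject_roi(annotations: Iterable) -> BBox:
    """Minimal box enclosing every annotated vertebra of one subject.

    The ROI spans from the superior-most (T1) to the inferior-most (L5)
    annotated structure and is meant to be applied unchanged to every frame
    of the subject, giving a reproducible full-spine reference window.
    Accepts ``BBox`` objects or records with a ``bbox`` attribute.
    """
    boxes = _boxes(annotations)
    if not boxes:
        raise ValueError("subject_roi requires at least one annotation")
    return BBox(
        min(b.x_min for b in boxes),
        min(b.y_min for b in boxes),
        max(b.x_max for b in boxes),
        max(b.y_max for b in boxes),
    )


@dataclass(frozen=True)
class CropSpec:
    """Padding/scale parameters for vertebra-centric crops.

    ``alpha_lateral`` is the proportional padding applied laterally to all
    levels and longitudinally to lumbar levels (symmetric lumbar padding).
    Thoracic levels receive slightly larger longitudinal padding
    (``alpha_longitudinal_thoracic``) to keep adjacent rib cues in view.
    ``scale`` composes multiplicatively with the padding (scale 1.0 is the
    plain padded crop; the sweep set is :data:`CROP_SCALE_SWEEP`).
    """

    alpha_lateral: float = 0.15
    alpha_longitudinal_thoracic: float = 0.20
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_lateral < 0 or self.alpha_longitudinal_thoracic < 0:
            raise ValueError("padding factors must be nonnegative")
        if self.scale < 1.0:
            raise ValueError(f"crop scale must be >= 1, got {self.scale}")


def vertebra_crop(
    bbox: BBox,
    level,
    spec: CropSpec,
    frame_width: float,
    frame_height: float,
) -> BBox:
    """Padded, scale-swept crop window around one vertebra's box.

    Width is scaled by ``(1 + alpha_lateral) * scale`` about the box center;
    height by ``(1 + alpha_long) * scale`` where ``alpha_long`` is the
    thoracic longitudinal padding for T1-T12 and the lateral padding for
    L1-L5.  The result is clamped to the frame extent.
    """
    alpha_long = (
        spec.alpha_longitudinal_thoracic if level.is_thoracic else spec.alpha_lateral
    )
    cx, cy = bbox.center
    half_w = bbox.width * (1.0 + spec.alpha_lateral) * spec.scale / 2.0
    half_h = bbox.height * (1.0 + alpha_long) * spec.scale / 2.0
    x0, x1 = cx - half_w, cx + half_w
    y0, y1 = cy - half_h, cy + half_h
    x0c, x1c = max(0.0, x0), min(float(frame_width), x1)
    y0c, y1c = max(0.0, y0), min(float(frame_height), y1)
    if x0c >= x1c or y0c >= y1c:
        raise ValueError("crop lies entirely outside the frame")
    return BBox(x0c, y0c, x1c, y1c)


def match_detections(
    detections: Sequence,
    annotations: Sequence,
    iou_threshold: float = 0.5,
) -> list[tuple[object, Optional[object]]]:
    """Greedy one-to-one matching of detections to ground-truth annotations.

    Detections are visited in descending confidence order; each is paired
    with the unmatched annotation of highest IoU, provided IoU reaches
    ``iou_threshold`` and, when both carry level labels, the levels agree.
    Detections that find no admissible annotation are paired with ``None``.
    Each annotation is matched at most once.
    """
    order = sorted(
        range(len(detections)),
        key=lambda i: (-detections[i].confidence, i),
    )
    taken: set[int] = set()
    matched: dict[int, Optional[object]] = {}
    for di in order:
        det = detections[di]
        best_j, best_iou = None, 0.0
        for j, ann in enumerate(annotations):
            if j in taken:
                continue
            det_level = getattr(det, "level", None)
            if det_level is not None and det_level != ann.level:
                continue
            o = iou(det.bbox, ann.bbox)
            if o >= iou_threshold and o > best_iou:
                best_j, best_iou = j, o
        if best_j is not None:
            taken.add(best_j)
            matched[di] = annotations[best_j]
        else:
            matched[di] = None
    return [(detections[i], matched[i]) for i in range(len(detections))]


@dataclass(frozen=True)
class FrameImage:
    """Standardised grayscale frame with intensities in [0, 1]."""

    pixels: np.ndarray
    height: int
    width: int

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2 or p.shape != (self.height, self.width):
            raise ValueError("pixels must be a 2-D array matching height x width")
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("intensities must lie in [0, 1]")


def standardize_frame(raw: np.ndarray, size: int = STANDARD_SIZE) -> FrameImage:
    """Standardise a raw 2-D intensity array to a ``size x size`` [0, 1] frame.

    Integer-typed inputs are divided by 255; floating inputs are assumed to
    already be in [0, 1].  Resizing uses bilinear interpolation; frames that
    already have the target shape are passed through unchanged.
    """
    arr = np.asarray(raw)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("expected a nonempty 2-D intensity array")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / 255.0
    else:
        arr = arr.astype(np.float64)
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValueError("floating-point input must already lie in [0, 1]")
    if arr.shape != (size, size):
        from skimage.transform import resize

        arr = resize(arr, (size, size), order=1, preserve_range=True,
                     anti_aliasing=False)
    arr = np.clip(arr, 0.0, 1.0)
    return FrameImage(pixels=arr, height=size, width=size)


def load_frame(path) -> np.ndarray:
    """Read a grayscale PNG (or any PIL-readable image) as a 2-D array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L"))
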