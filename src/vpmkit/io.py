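"""Readers and writers for YOLO-style label text and JSON scan manifests.

Label files carry one record per line::

    <class> <cx> <cy> <w> <h>            (annotation, 5 fields)
    <class> <cx> <cy> <w> <h> <conf>     (detection, 6 fields)

with center/size normalised to [0, 1] by the frame dimensions and the class
index mapping 0 -> T1 ... 16 -> L5.  A JSON manifest groups frames into
scans and subjects and records the train/validation split, which must be
subject-disjoint (a subject appearing in both splits is a hard error — it
would let a detector memorise subject-specific anatomy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .core import (
    Annotation,
    Detection,
    FrameRecord,
    Scan,
    VertebralLevel,
)
from .geometry import BBox

__all__ = [
    "FRAME_SIZE",
    "ParseError",
    "SplitLeakageError",
    "FrameEntry",
    "ScanEntry",
    "ScanManifest",
    "SplitReport",
    "bbox_from_yolo",
    "bbox_to_yolo",
    "parse_yolo_record",
    "format_yolo_record",
    "write_dataset",
    "read_dataset",
    "load_manifest",
    "validate_split",
    "load_config",
]

#: Standardised frame edge length in pixels.
FRAME_SIZE = 640


class ParseError(ValueError):
    """A label/detection line could not be parsed."""


class SplitLeakageError(ValueError):
    """A subject appears in more than one split."""


def bbox_from_yolo(
    cx: float, cy: float, w: float, h: float, frame_width: float, frame_height: float
) -> BBox:
    """Normalised YOLO center/size to absolute half-open pixel box."""
    return BBox(
        (cx - w / 2.0) * frame_width,
        (cy - h / 2.0) * frame_height,
        (cx + w / 2.0) * frame_width,
        (cy + h / 2.0) * frame_height,
    )


def bbox_to_yolo(
    bbox: BBox, frame_width: float, frame_height: float
) -> tuple[float, float, float, float]:
    """Absolute pixel box to normalised YOLO center/size."""
    cx = (bbox.x_min + bbox.x_max) / 2.0 / frame_width
    cy = (bbox.y_min + bbox.y_max) / 2.0 / frame_height
    return cx, cy, bbox.width / frame_width, bbox.height / frame_height


def parse_yolo_record(
    line: str,
    frame_width: float,
    frame_height: float,
    with_confidence: bool = False,
    frame_id: str = "",
    line_no: Optional[int] = None,
) -> Union[Annotation, Detection]:
    """Parse one label line into an :class:`Annotation` or :class:`Detection`.

    Annotations have 5 fields, detections 6 (confidence appended).  All
    normalised values must lie in [0, 1] and the class index in 0..16.
    """
    where = f" (line {line_no})" if line_no is not None else ""
    fields = line.split()
    expected = 6 if with_confidence else 5
    if len(fields) != expected:
        raise ParseError(
            f"expected {expected} fields, got {len(fields)}{where}: {line!r}"
        )
    try:
        cls = int(fields[0])
        values = [float(f) for f in fields[1:]]
    except ValueError as exc:
        raise ParseError(f"malformed number{where}: {line!r}") from exc
    if not (0 <= cls <= 16):
        raise ParseError(f"class index {cls} out of range 0..16{where}")
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise ParseError(f"normalised value {v} outside [0, 1]{where}")
    level = VertebralLevel(cls + 1)
    bbox = bbox_from_yolo(*values[:4], frame_width, frame_height)
    if with_confidence:
        return Detection(
            frame_id=frame_id, bbox=bbox, confidence=values[4], level=level
        )
    return Annotation(frame_id=frame_id, level=level, bbox=bbox)


def format_yolo_record(
    record: Union[Annotation, Detection], frame_width: float, frame_height: float
) -> str:
    """Serialise a record back to YOLO text (6 decimals, class index first)."""
    if record.level is None:
        raise ValueError("cannot serialise a detection without a level label")
    cx, cy, w, h = bbox_to_yolo(record.bbox, frame_width, frame_height)
    parts = [str(record.level.ordinal - 1)] + [f"{v:.6f}" for v in (cx, cy, w, h)]
    if isinstance(record, Detection):
        parts.append(f"{record.confidence:.6f}")
    return " ".join(parts)


@dataclass(frozen=True)
class FrameEntry:
    frame_id: str
    label_path: str
    detection_path: Optional[str] = None
    image_path: Optional[str] = None


@dataclass(frozen=True)
class ScanEntry:
    scan_id: str
    subject_id: str
    split: str
    frames: tuple[FrameEntry, ...]


@dataclass(frozen=True)
class ScanManifest:
    frame_width: int
    frame_height: int
    scans: tuple[ScanEntry, ...]

    def __post_init__(self) -> None:
        for scan in self.scans:
            ids = [f.frame_id for f in scan.frames]
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate frame_ids in scan {scan.scan_id!r}")


@dataclass(frozen=True)
class SplitReport:
    n_train_subjects: int
    n_val_subjects: int
    subjects_by_split: dict = field(default_factory=dict)


def validate_split(manifest: ScanManifest) -> SplitReport:
    """Confirm the split is subject-disjoint; report split sizes.

    Raises :class:`SplitLeakageError` naming every subject that appears in
    more than one split, and ``ValueError`` on an empty manifest.
    """
    if not manifest.scans:
        raise ValueError("manifest contains no scans")
    splits_of: dict[str, set[str]] = {}
    for scan in manifest.scans:
        splits_of.setdefault(scan.subject_id, set()).add(scan.split)
    leaking = sorted(s for s, splits in splits_of.items() if len(splits) > 1)
    if leaking:
        raise SplitLeakageError(
            f"subjects present in multiple splits: {', '.join(leaking)}"
        )
    by_split: dict[str, list[str]] = {}
    for subject, splits in splits_of.items():
        by_split.setdefault(next(iter(splits)), []).append(subject)
    return SplitReport(
        n_train_subjects=len(by_split.get("train", [])),
        n_val_subjects=len(by_split.get("val", [])),
        subjects_by_split={k: sorted(v) for k, v in sorted(by_split.items())},
    )


def write_dataset(scans: Sequence[Scan], out_dir) -> Path:
    """Write scans as YOLO label/detection text plus a JSON manifest.

    Layout: ``labels/<frame_id>.txt``, ``detections/<frame_id>.txt`` and
    ``manifest.json`` under ``out_dir``.  Output is deterministic: records
    are written in stored order with fixed 6-decimal formatting and the
    manifest with sorted keys.
    """
    root = Path(out_dir)
    (root / "labels").mkdir(parents=True, exist_ok=True)
    (root / "detections").mkdir(parents=True, exist_ok=True)
    entries = []
    for scan in scans:
        frame_entries = []
        for fr in scan.frames:
            label_rel = f"labels/{fr.frame_id}.txt"
            det_rel = f"detections/{fr.frame_id}.txt"
            lines = [
                format_yolo_record(a, FRAME_SIZE, FRAME_SIZE) for a in fr.annotations
            ]
            (root / label_rel).write_text("".join(l + "\n" for l in lines))
            lines = [
                format_yolo_record(d, FRAME_SIZE, FRAME_SIZE) for d in fr.detections
            ]
            (root / det_rel).write_text("".join(l + "\n" for l in lines))
            frame_entries.append(
                {"frame_id": fr.frame_id, "label_file": label_rel, "detection_file": det_rel}
            )
        entries.append(
            {
                "scan_id": scan.scan_id,
                "subject_id": scan.subject_id,
                "split": scan.split or "val",
                "frames": frame_entries,
            }
        )
    manifest = {
        "frame_width": FRAME_SIZE,
        "frame_height": FRAME_SIZE,
        "scans": entries,
    }
    (root / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return root


def load_manifest(root) -> ScanManifest:
    """Load ``manifest.json`` from a dataset directory."""
    root = Path(root)
    data = json.loads((root / "manifest.json").read_text())
    scans = tuple(
        ScanEntry(
            scan_id=s["scan_id"],
            subject_id=s["subject_id"],
            split=s.get("split", "val"),
            frames=tuple(
                FrameEntry(
                    frame_id=f["frame_id"],
                    label_path=f["label_file"],
                    detection_path=f.get("detection_file"),
                    image_path=f.get("image_file"),
                )
                for f in s["frames"]
            ),
        )
        for s in data["scans"]
    )
    return ScanManifest(
        frame_width=int(data["frame_width"]),
        frame_height=int(data["frame_height"]),
        scans=scans,
    )


def _read_records(path: Path, frame_id: str, width: int, height: int, with_confidence: bool):
    records = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        records.append(
            parse_yolo_record(
                line, width, height,
                with_confidence=with_confidence, frame_id=frame_id, line_no=i,
            )
        )
    return tuple(records)


def read_dataset(root) -> list[Scan]:
    """Read a dataset directory written by :func:`write_dataset`."""
    root = Path(root)
    manifest = load_manifest(root)
    scans: list[Scan] = []
    for entry in manifest.scans:
        frames = []
        for fe in entry.frames:
            annotations = _read_records(
                root / fe.label_path, fe.frame_id,
                manifest.frame_width, manifest.frame_height, with_confidence=False,
            )
            detections: tuple = ()
            if fe.detection_path is not None:
                detections = _read_records(
                    root / fe.detection_path, fe.frame_id,
                    manifest.frame_width, manifest.frame_height, with_confidence=True,
                )
            frames.append(
                FrameRecord(frame_id=fe.frame_id, annotations=annotations, detections=detections)
            )
        scans.append(
            Scan(
                scan_id=entry.scan_id,
                subject_id=entry.subject_id,
                frames=tuple(frames),
                split=entry.split,
            )
        )
    return scans


def load_config(path) -> dict:
    """Load a YAML configuration file as a plain mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError("configuration file must contain a mapping")
    return data
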