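"""Axis-aligned bounding boxes, IOU, and the tracker measurement parameterization.

Boxes live in image coordinates: origin at the top-left corner, x increasing
rightward, y increasing downward, continuous (sub-pixel) values. A box is the
closed rectangle ``[x_min, x_max] x [y_min, y_max]``.

The tracker does not observe box corners directly; it observes the
4-vector measurement ``(u, v, s, r)`` — horizontal center, vertical center,
area, and aspect ratio. The factorization ``s = w*h``, ``r = w/h`` makes the
corner <-> measurement conversion a bijection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Box",
    "MeasurementState",
    "Detection",
    "iou",
    "box_to_state",
    "state_to_box",
    "read_detections_csv",
    "write_detections_csv",
    "read_detections_coco",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with strictly positive width and height."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"box coordinates must be finite, got {vals}")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: need x_max > x_min and y_max > y_min, got {vals}"
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

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "Box":
        """Build from top-left corner plus width/height (MOT and COCO layout)."""
        return cls(x, y, x + w, y + h)

    def to_xywh(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.width, self.height)


@dataclass(frozen=True)
class MeasurementState:
    """The observed 4-vector (u, v, s, r): center, area, aspect ratio."""

    u: float
    v: float
    s: float
    r: float

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.r > 0):
            raise ValueError(f"area and aspect ratio must be positive, got s={self.s}, r={self.r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v, self.s, self.r], dtype=float)


@dataclass(frozen=True)
class Detection:
    """One detector output: a box in one frame with a class label and score."""

    frame_index: int
    box: Box
    class_label: str = "seedling"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 when identical."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def box_to_state(b: Box) -> MeasurementState:
    """Convert box corners to the (u, v, s, r) measurement."""
    return MeasurementState(
        u=(b.x_min + b.x_max) / 2.0,
        v=(b.y_min + b.y_max) / 2.0,
        s=b.width * b.height,
        r=b.width / b.height,
    )


def state_to_box(m: MeasurementState) -> Box:
    """Invert :func:`box_to_state`: w = sqrt(s*r), h = sqrt(s/r)."""
    w = float(np.sqrt(m.s * m.r))
    h = float(np.sqrt(m.s / m.r))
    return Box(m.u - w / 2.0, m.v - h / 2.0, m.u + w / 2.0, m.v + h / 2.0)


# ---------------------------------------------------------------------------
# Detection stream I/O
# ---------------------------------------------------------------------------

_MOT_COLUMNS = ["frame", "id", "x", "y", "w", "h", "conf", "class"]


def read_detections_csv(path: str | Path) -> list[Detection]:
    """Read a MOT-style detection CSV: frame,id,x,y,w,h,conf,class.

    ``x, y`` give the top-left corner; ``id`` is ignored (-1 for raw
    detections). Rows are returned sorted by frame index.
    """
    df = pd.read_csv(path)
    missing = set(_MOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detection CSV missing columns: {sorted(missing)}")
    df = df.sort_values("frame", kind="stable")
    return [
        Detection(
            frame_index=int(frame),
            box=Box.from_xywh(x, y, w, h),
            class_label=str(label),
            confidence=float(conf),
        )
        for frame, x, y, w, h, conf, label in zip(
            df["frame"], df["x"], df["y"], df["w"], df["h"], df["conf"], df["class"]
        )
    ]


def write_detections_csv(detections: Iterable[Detection], path: str | Path) -> None:
    rows = [
        {
            "frame": d.frame_index,
            "id": -1,
            "x": d.box.x_min,
            "y": d.box.y_min,
            "w": d.box.width,
            "h": d.box.height,
            "conf": d.confidence,
            "class": d.class_label,
        }
        for d in detections
    ]
    pd.DataFrame(rows, columns=_MOT_COLUMNS).to_csv(path, index=False)


def read_detections_coco(path: str | Path, categories: dict[int, str] | None = None) -> list[Detection]:
    """Read COCO-style result JSON: a list of {image_id, bbox, score, category_id}.

    ``bbox`` is [x, y, w, h]. ``image_id`` is used as the frame index, so
    results on video frames must number images in frame order. ``categories``
    maps category ids to class names; unmapped ids keep their numeric id as a
    string label.
    """
    with open(path) as fh:
        records = json.load(fh)
    categories = categories or {}
    dets = []
    for rec in records:
        x, y, w, h = rec["bbox"]
        cat = rec.get("category_id", 1)
        dets.append(
            Detection(
                frame_index=int(rec["image_id"]),
                box=Box.from_xywh(x, y, w, h),
                class_label=categories.get(cat, str(cat)),
                confidence=float(rec.get("score", 1.0)),
            )
        )
    dets.sort(key=lambda d: d.frame_index)
    return dets
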