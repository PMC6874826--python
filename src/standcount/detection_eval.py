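"""Detection evaluation: AP, AR100, and F1 at IOU 0.5 and IOU 0.5:0.95.

Implements the COCO-style protocol: detections are matched to ground truth
greedily in descending confidence order, each ground-truth box is consumed
at most once, average precision uses 101-point interpolation over recall,
and average recall caps detections at the 100 highest-confidence per image.
Metrics are reported per category and averaged over categories, at the
loose IOU 0.5 regime and at the strict regime averaged over the ten
thresholds 0.5, 0.55, ..., 0.95 ("IOU_all"). The F1 score combines
precision and recall as 2PR/(P+R) with P the (m)AP and R the (m)AR100 of
the matching regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import Box, Detection, iou

__all__ = [
    "GroundTruth",
    "AnnotationSet",
    "MetricsSummary",
    "IOU_ALL",
    "match_at_iou",
    "average_precision",
    "average_recall_100",
    "summarize",
    "read_coco_annotations",
]

IOU_ALL: tuple[float, ...] = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))
_RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class GroundTruth:
    """One annotated box: image id, box, class label."""

    image_id: int
    box: Box
    class_label: str


@dataclass
class AnnotationSet:
    """Ground-truth boxes for a set of images, with a declared category list."""

    ground_truths: list[GroundTruth]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = {g.class_label for g in self.ground_truths} - set(self.categories)
        if bad:
            raise ValueError(f"ground-truth labels outside declared categories: {sorted(bad)}")

    def for_class(self, label: str) -> list[GroundTruth]:
        return [g for g in self.ground_truths if g.class_label == label]


@dataclass
class MetricsSummary:
    """Per-category and overall detection metrics at the two IOU regimes."""

    per_category: dict          # label -> {"AP": ., "AR100": ., "F1": .} at IOU 0.5
    mAP_iou50: float
    mAR100_iou50: float
    f1_iou50: float
    mAP_iou_all: float
    mAR100_iou_all: float
    f1_iou_all: float
    pr_curves: dict = field(default_factory=dict)  # label -> (recall grid, precision)

    def to_dict(self) -> dict:
        return {
            "per_category": self.per_category,
            "mAP_iou50": self.mAP_iou50,
            "mAR100_iou50": self.mAR100_iou50,
            "f1_iou50": self.f1_iou50,
            "mAP_iou_all": self.mAP_iou_all,
            "mAR100_iou_all": self.mAR100_iou_all,
            "f1_iou_all": self.f1_iou_all,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2.0 * p * r / (p + r)


def match_at_iou(
    gts: Sequence[GroundTruth],
    dets: Sequence[Detection],
    threshold: float,
) -> tuple[np.ndarray, int]:
    """Greedy confidence-ordered matching of detections to ground truth.

    ``gts`` and ``dets`` must already be restricted to one class. Detections
    are visited in descending confidence; each claims the still-unmatched
    ground truth in its image with the highest IOU >= ``threshold``, or is a
    false positive. Returns a boolean TP flag per detection (in descending
    confidence order) and the count of unmatched ground truths (false
    negatives). Ties in confidence are broken by input order.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    gt_by_image: dict[int, list[int]] = {}
    for gi, g in enumerate(gts):
        gt_by_image.setdefault(g.image_id, []).append(gi)
    gt_used = np.zeros(len(gts), dtype=bool)
    tp = np.zeros(len(dets), dtype=bool)
    for rank, di in enumerate(order):
        d = dets[di]
        best_iou, best_gi = threshold, -1
        for gi in gt_by_image.get(d.frame_index, []):
            if gt_used[gi]:
                continue
            ov = iou(d.box, gts[gi].box)
            if ov >= best_iou and (ov > best_iou or best_gi < 0):
                best_iou, best_gi = ov, gi
        if best_gi >= 0:
            gt_used[best_gi] = True
            tp[rank] = True
    return tp, int((~gt_used).sum())


def average_precision(tp_flags: Sequence[bool], n_gt: int) -> float:
    """101-point interpolated average precision.

    ``tp_flags`` are per-detection true-positive flags in descending
    confidence order; ``n_gt`` is the number of ground-truth boxes of the
    class. Precision at each of the 101 evenly spaced recall points is the
    maximum precision attained at any recall >= that point; AP is their
    mean. Undefined (NaN) when ``n_gt`` is zero.
    """
    if n_gt <= 0:
        return float("nan")
    tp = np.asarray(tp_flags, dtype=float)
    if tp.size == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.arange(1, tp.size + 1)
    interp = np.array([precision[recall >= r].max() if np.any(recall >= r) else 0.0 for r in _RECALL_GRID])
    return float(interp.mean())


def _pr_curve(tp_flags: Sequence[bool], n_gt: int) -> tuple[np.ndarray, np.ndarray]:
    tp = np.asarray(tp_flags, dtype=float)
    if tp.size == 0 or n_gt <= 0:
        return _RECALL_GRID.copy(), np.zeros_like(_RECALL_GRID)
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.arange(1, tp.size + 1)
    interp = np.array([precision[recall >= r].max() if np.any(recall >= r) else 0.0 for r in _RECALL_GRID])
    return _RECALL_GRID.copy(), interp


def _top_100_per_image(dets: Sequence[Detection]) -> list[Detection]:
    by_image: dict[int, list[Detection]] = {}
    for d in dets:
        by_image.setdefault(d.frame_index, []).append(d)
    kept: list[Detection] = []
    for image_dets in by_image.values():
        image_dets.sort(key=lambda d: -d.confidence)
        kept.extend(image_dets[:100])
    return kept


def average_recall_100(
    gts: Sequence[GroundTruth],
    dets: Sequence[Detection],
    thresholds: Sequence[float] = (0.5,),
) -> float:
    """Recall with at most 100 detections per image, averaged over thresholds.

    Single-class inputs, as for :func:`match_at_iou`. NaN when there is no
    ground truth.
    """
    if len(gts) == 0:
        return float("nan")
    capped = _top_100_per_image(dets)
    recalls = []
    for t in thresholds:
        tp, _ = match_at_iou(gts, capped, t)
        recalls.append(tp.sum() / len(gts))
    return float(np.mean(recalls))


def summarize(annotations: AnnotationSet, dets: Sequence[Detection]) -> MetricsSummary:
    """Full evaluation: per-category AP/AR100/F1 at IOU 0.5, overall means
    at IOU 0.5 and IOU 0.5:0.95, and per-category PR curves.

    Categories with no ground truth are excluded from the means (their
    metrics are undefined); an entirely empty annotation set is an error.
    """
    if not annotations.ground_truths:
        raise ValueError("annotation set has no ground truth")

    per_category: dict[str, dict[str, float]] = {}
    pr_curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    ap50, ar50, ap_all, ar_all = [], [], [], []
    for label in annotations.categories:
        class_gts = annotations.for_class(label)
        if not class_gts:
            continue
        class_dets = sorted(
            (d for d in dets if d.class_label == label), key=lambda d: -d.confidence
        )
        n_gt = len(class_gts)

        tp50, _ = match_at_iou(class_gts, class_dets, 0.5)
        cat_ap = average_precision(tp50, n_gt)
        cat_ar = average_recall_100(class_gts, class_dets, (0.5,))
        per_category[label] = {"AP": cat_ap, "AR100": cat_ar, "F1": _f1(cat_ap, cat_ar)}
        pr_curves[label] = _pr_curve(tp50, n_gt)
        ap50.append(cat_ap)
        ar50.append(cat_ar)

        aps = [average_precision(match_at_iou(class_gts, class_dets, t)[0], n_gt) for t in IOU_ALL]
        ap_all.append(float(np.mean(aps)))
        ar_all.append(average_recall_100(class_gts, class_dets, IOU_ALL))

    mAP50, mAR50 = float(np.mean(ap50)), float(np.mean(ar50))
    mAPall, mARall = float(np.mean(ap_all)), float(np.mean(ar_all))
    return MetricsSummary(
        per_category=per_category,
        mAP_iou50=mAP50,
        mAR100_iou50=mAR50,
        f1_iou50=_f1(mAP50, mAR50),
        mAP_iou_all=mAPall,
        mAR100_iou_all=mARall,
        f1_iou_all=_f1(mAPall, mARall),
        pr_curves=pr_curves,
    )


def read_coco_annotations(path: str | Path) -> AnnotationSet:
    """Read a COCO-style annotation JSON into an :class:`AnnotationSet`."""
    with open(path) as fh:
        coco = json.load(fh)
    cat_names = {c["id"]: c["name"] for c in coco.get("categories", [])}
    gts = [
        GroundTruth(
            image_id=int(a["image_id"]),
            box=Box.from_xywh(*a["bbox"]),
            class_label=cat_names.get(a.get("category_id", 1), str(a.get("category_id", 1))),
        )
        for a in coco["annotations"]
    ]
    return AnnotationSet(ground_truths=gts, categories=tuple(cat_names.values()))
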