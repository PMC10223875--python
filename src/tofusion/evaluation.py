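"""Per-class average precision for detection corpora and epoch selection.

Detections are matched to ground truth greedily in order of decreasing
confidence; a detection is a true positive when its IoU with an unmatched
ground-truth box of the same class reaches the threshold (default 0.5).
AP is the area under the precision-recall curve. Two interpolation
conventions are provided: all-point (area under the precision envelope,
the PASCAL VOC 2010+/COCO style, default) and the older 11-point average.
Model selection picks the epoch with the best mean AP over the classes of
interest, earliest epoch on ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import CLASS_NAMES, BBox

__all__ = [
    "DetectionRecord",
    "EpochReport",
    "iou",
    "average_precision",
    "evaluate_classes",
    "best_epoch",
    "write_epoch_reports_csv",
    "read_epoch_reports_csv",
]


@dataclass(frozen=True)
class DetectionRecord:
    """One predicted box on one frame."""

    frame_id: str
    box: BBox

    @property
    def confidence(self) -> float:
        return self.box.confidence if self.box.confidence is not None else 1.0


@dataclass
class EpochReport:
    """AP per class at one training epoch."""

    epoch: int
    ap: dict = field(default_factory=dict)

    def mean_ap(self, classes) -> float:
        return float(np.mean([self.ap.get(c, 0.0) for c in classes]))


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes on pixel areas."""
    inter = a.intersection_area(b)
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _pr_area_all_point(recall: np.ndarray, precision: np.ndarray) -> float:
    """Area under the precision envelope (all-point interpolation)."""
    r = np.concatenate([[0.0], recall, [1.0]])
    p = np.concatenate([[0.0], precision, [0.0]])
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    steps = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[steps + 1] - r[steps]) * p[steps + 1]))


def _pr_area_11_point(recall: np.ndarray, precision: np.ndarray) -> float:
    """Mean of the interpolated precision at recalls 0, 0.1, ..., 1."""
    ap = 0.0
    for r_t in np.linspace(0.0, 1.0, 11):
        mask = recall >= r_t
        ap += precision[mask].max() if np.any(mask) else 0.0
    return float(ap / 11.0)


def average_precision(
    dets: list[DetectionRecord],
    truths: dict[str, list[BBox]],
    iou_thresh: float = 0.5,
    *,
    interpolation: str = "all_point",
) -> float:
    """AP of one class from its detections and per-frame ground truth.

    ``truths`` maps frame id -> ground-truth boxes (already filtered to the
    class being scored). Detections are sorted by descending confidence
    (stable, so equal confidences keep their input order) and matched
    greedily; each ground truth can be claimed once.
    """
    n_truth = sum(len(v) for v in truths.values())
    if n_truth == 0:
        if dets:
            warnings.warn("no ground truth for class; AP reported as 0")
        return 0.0
    if not dets:
        return 0.0
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    matched: dict[str, list[bool]] = {
        fid: [False] * len(boxes) for fid, boxes in truths.items()
    }
    tp = np.zeros(len(order))
    fp = np.zeros(len(order))
    for rank, i in enumerate(order):
        det = dets[i]
        gt = truths.get(det.frame_id, [])
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gt):
            if matched[det.frame_id][j]:
                continue
            v = iou(det.box, g)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thresh:
            matched[det.frame_id][best_j] = True
            tp[rank] = 1.0
        else:
            fp[rank] = 1.0
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(fp)
    recall = tp_cum / n_truth
    precision = tp_cum / (tp_cum + fp_cum)
    if interpolation == "all_point":
        return _pr_area_all_point(recall, precision)
    if interpolation == "11_point":
        return _pr_area_11_point(recall, precision)
    raise ValueError("interpolation must be 'all_point' or '11_point'")


def evaluate_classes(
    dets: list[DetectionRecord],
    truths: dict[str, list[BBox]],
    iou_thresh: float = 0.5,
    classes=CLASS_NAMES,
    *,
    interpolation: str = "all_point",
) -> dict:
    """Per-class AP over a corpus; cross-class matches are never allowed."""
    out = {}
    for cls in classes:
        cls_dets = [d for d in dets if d.box.label == cls]
        cls_truths = {
            fid: [b for b in boxes if b.label == cls]
            for fid, boxes in truths.items()
        }
        out[cls] = average_precision(
            cls_dets, cls_truths, iou_thresh, interpolation=interpolation
        )
    return out


def best_epoch(reports: list[EpochReport], classes=CLASS_NAMES) -> int:
    """Epoch index maximizing mean AP over ``classes``; earliest wins ties."""
    if not reports:
        raise ValueError("no epoch reports")
    best = reports[0]
    for r in reports[1:]:
        if r.mean_ap(classes) > best.mean_ap(classes):
            best = r
    return best.epoch


def write_epoch_reports_csv(reports: list[EpochReport], path,
                            classes=CLASS_NAMES) -> None:
    """Write the per-epoch AP table (one column per class) as CSV."""
    rows = [
        {"epoch": r.epoch, **{c: r.ap.get(c, float("nan")) for c in classes}}
        for r in reports
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_epoch_reports_csv(path, classes=CLASS_NAMES) -> list[EpochReport]:
    df = pd.read_csv(path)
    return [
        EpochReport(
            epoch=int(row["epoch"]),
            ap={c: float(row[c]) for c in classes if c in df.columns},
        )
        for _, row in df.iterrows()
    ]
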