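"""Object-detection quality metrics: IoU, precision/recall, AP, mAP.

Single-class evaluation of bounding-box detections against ground-truth
boxes, pooled over the frames of a dataset.  Matching is greedy in
descending confidence with one-to-one detection↔truth pairing at a
minimum IoU; average precision uses the 101-point interpolated
precision-recall area; mAP(0.5:0.95) averages AP over IoU thresholds
0.50, 0.55, …, 0.95.  With one class, mAP equals AP — both names are
reported for comparability with detector benchmarks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .detect import Detection

__all__ = [
    "EvalReport",
    "iou",
    "match_detections",
    "average_precision",
    "mean_average_precision",
    "evaluate_detections",
]

MAP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))

Box = tuple[float, float, float, float]  # (x1, y1, x2, y2)


def _as_corners(box) -> Box:
    if isinstance(box, Detection):
        return box.corners()
    x1, y1, x2, y2 = box
    return (float(x1), float(y1), float(x2), float(y2))


def iou(boxA, boxB) -> float:
    """Intersection-over-union of two axis-aligned boxes.

    Boxes are (x1, y1, x2, y2) corner tuples or :class:`Detection`
    objects; zero-area boxes are rejected.
    """
    a, b = _as_corners(boxA), _as_corners(boxB)
    for box in (a, b):
        if box[2] <= box[0] or box[3] <= box[1]:
            raise ValueError(f"zero-area box {box}")
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / union


def match_detections(
    detections: Sequence[Detection],
    ground_truth: Sequence,
    iou_threshold: float = 0.5,
) -> tuple[list[tuple[Detection, bool]], int]:
    """Label one frame's detections as TP/FP against its ground truth.

    Detections are processed in descending confidence; each claims the
    still-unmatched truth box of highest IoU provided that IoU reaches
    the threshold.  Returns the labelled detections (in processing
    order) and the number of unmatched truths (FN).
    """
    gts = [_as_corners(g) for g in ground_truth]
    taken = [False] * len(gts)
    ordered = sorted(
        detections, key=lambda d: (-d.confidence, d.x_center, d.y_center, d.width)
    )
    labelled: list[tuple[Detection, bool]] = []
    for det in ordered:
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if taken[j]:
                continue
            v = iou(det, g)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            labelled.append((det, True))
        else:
            labelled.append((det, False))
    return labelled, taken.count(False)


def average_precision(
    labelled: Sequence[tuple[float, bool]], n_ground_truth: int
) -> float:
    """101-point interpolated AP from (confidence, is_tp) labels.

    The precision-recall curve is swept over confidence; AP is the mean
    over recall grid r ∈ {0, 0.01, …, 1} of the maximum precision at
    recall ≥ r.
    """
    if n_ground_truth <= 0:
        raise ValueError("average precision is undefined without ground truths")
    if not labelled:
        return 0.0
    order = np.argsort([-c for c, _ in labelled], kind="stable")
    tp = np.array([labelled[i][1] for i in order], dtype=float)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_ground_truth
    precision = cum_tp / (cum_tp + cum_fp)
    grid = np.linspace(0.0, 1.0, 101)
    # max precision at recall >= r  (monotone envelope from the right)
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    for r in grid:
        idx = np.searchsorted(recall, r, side="left")
        ap += prec_env[idx] if idx < len(recall) else 0.0
    return float(ap / grid.size)


def _pooled_labels(
    detections: Sequence[Detection],
    ground_truth: Sequence,
    iou_threshold: float,
) -> tuple[list[tuple[float, bool]], int]:
    """Match frame by frame, pool (confidence, is_tp) labels."""
    det_by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        det_by_frame.setdefault(d.frame_index, []).append(d)
    gt_by_frame: dict[int, list] = {}
    for g in ground_truth:
        gt_by_frame.setdefault(getattr(g, "frame_index", 0), []).append(g)
    labels: list[tuple[float, bool]] = []
    n_gt = 0
    for f in sorted(set(det_by_frame) | set(gt_by_frame)):
        dets = det_by_frame.get(f, [])
        gts = gt_by_frame.get(f, [])
        n_gt += len(gts)
        labelled, _ = match_detections(dets, gts, iou_threshold)
        labels.extend((d.confidence, tp) for d, tp in labelled)
    return labels, n_gt


def mean_average_precision(
    detections: Sequence[Detection],
    ground_truth: Sequence,
    thresholds: Sequence[float] = MAP_THRESHOLDS,
) -> dict[float, float]:
    """AP at each IoU threshold (single class ⇒ mAP per threshold)."""
    out = {}
    for thr in thresholds:
        labels, n_gt = _pooled_labels(detections, ground_truth, thr)
        if n_gt == 0:
            raise ValueError("mAP is undefined without ground truths")
        out[float(thr)] = average_precision(labels, n_gt)
    return out


@dataclass
class EvalReport:
    """Detection metrics for one dataset (labels pooled across frames).

    Precision/recall are reported at the requested confidence operating
    point and additionally at the best-F1 point of the PR sweep, since
    detector benchmarks differ in which they quote.
    """

    precision: float
    recall: float
    confidence_threshold: float
    precision_best_f1: float
    recall_best_f1: float
    map_50: float
    map_50_95: float
    ap_per_threshold: dict[float, float] = field(default_factory=dict)
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "Precision": self.precision,
            "Recall": self.recall,
            "confidence_threshold": self.confidence_threshold,
            "Precision_bestF1": self.precision_best_f1,
            "Recall_bestF1": self.recall_best_f1,
            "mAP(0.5)": self.map_50,
            "mAP(0.5:0.95)": self.map_50_95,
            "AP_per_IoU": {str(k): v for k, v in self.ap_per_threshold.items()},
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
        }
        s = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(s)
        return s


def evaluate_detections(
    detections: Sequence[Detection],
    ground_truth: Sequence,
    confidence_threshold: float = 0.3,
    iou_threshold: float = 0.5,
) -> EvalReport:
    """Full single-class evaluation of a dataset."""
    labels, n_gt = _pooled_labels(detections, ground_truth, iou_threshold)
    if n_gt == 0:
        raise ValueError("evaluation is undefined without ground truths")

    kept = [(c, tp) for c, tp in labels if c >= confidence_threshold]
    tp = sum(1 for _, t in kept if t)
    fp = len(kept) - tp
    fn = n_gt - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / n_gt

    order = sorted(labels, key=lambda x: -x[0])
    cum_tp = np.cumsum([t for _, t in order]) if order else np.array([])
    best_p, best_r, best_f1 = 0.0, 0.0, -1.0
    for k in range(1, len(order) + 1):
        p = cum_tp[k - 1] / k
        r = cum_tp[k - 1] / n_gt
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best_f1:
            best_p, best_r, best_f1 = float(p), float(r), f1

    aps = mean_average_precision(detections, ground_truth)
    return EvalReport(
        precision=precision,
        recall=recall,
        confidence_threshold=confidence_threshold,
        precision_best_f1=best_p,
        recall_best_f1=best_r,
        map_50=aps[0.5],
        map_50_95=float(np.mean(list(aps.values()))),
        ap_per_threshold=aps,
        tp=tp,
        fp=fp,
        fn=fn,
    )
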