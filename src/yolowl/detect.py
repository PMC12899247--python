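"""Box decoding, non-maximum suppression, and detection metrics.

The metric engine follows the standard object-detection protocol:
detections are greedily matched to ground truth by descending score at an
IoU threshold with class-exact matching, precision/recall are accumulated
down the ranked list, AP is the area under the monotone
(ceiling-from-the-right) interpolated precision-recall curve, and mAP is
the unweighted mean over classes present in the ground truth.
mAP@0.5:0.95 additionally averages over IoU thresholds 0.50 to 0.95 in
steps of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "GroundTruthBox",
    "Detection",
    "PRCurve",
    "iou",
    "decode",
    "nms",
    "average_precision",
    "mean_ap",
    "COCO_THRESHOLDS",
]

COCO_THRESHOLDS = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class GroundTruthBox:
    """A labeled object in normalized (fraction-of-image) coordinates."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width/height must be positive")

    def corners(self, image_w: float = 1.0, image_h: float = 1.0) -> tuple:
        return ((self.cx - self.w / 2) * image_w, (self.cy - self.h / 2) * image_h,
                (self.cx + self.w / 2) * image_w, (self.cy + self.h / 2) * image_h)


@dataclass(frozen=True)
class Detection:
    """A scored predicted box in pixel corner coordinates (x1, y1, x2, y2)."""

    class_id: int
    score: float
    box: tuple

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if x2 <= x1 or y2 <= y1:
            raise ValueError("degenerate detection box")


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    ap: float


def iou(a, b) -> float:
    """Intersection-over-union of two corner boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


def decode(raw_outputs, strides=(4, 8, 16), reg_max: int = 16,
           conf_threshold: float = 0.25) -> list:
    """Decode raw head outputs of a single image into detections.

    Each cell predicts four per-side distance distributions over
    ``reg_max`` bins; the box offset is the softmax expectation of the bin
    index, scaled by the level stride and anchored at the cell center.
    Class scores pass through a sigmoid; each cell contributes its best
    class if that score clears ``conf_threshold``.
    """
    if len(raw_outputs) != len(strides):
        raise ValueError("one raw output per stride level expected")
    bins = np.arange(reg_max, dtype=np.float64)
    dets = []
    for raw, stride in zip(raw_outputs, strides):
        arr = raw.data if isinstance(raw, nn.Tensor) else np.asarray(raw)
        if arr.ndim == 4:
            if arr.shape[0] != 1:
                raise ValueError("decode expects a single image (batch 1)")
            arr = arr[0]
        c, h, w = arr.shape
        if c <= 4 * reg_max:
            raise ValueError(
                f"channel count {c} inconsistent with reg_max={reg_max}")
        box = arr[:4 * reg_max].reshape(4, reg_max, h, w).astype(np.float64)
        cls = arr[4 * reg_max:]
        ex = np.exp(box - box.max(axis=1, keepdims=True))
        probs = ex / ex.sum(axis=1, keepdims=True)
        dist = np.tensordot(bins, probs, axes=([0], [1]))      # (4, h, w)
        scores = 1.0 / (1.0 + np.exp(-cls.astype(np.float64)))
        best_cls = scores.argmax(axis=0)
        best_score = scores.max(axis=0)
        ii, jj = np.nonzero(best_score >= conf_threshold)
        for i, j in zip(ii, jj):
            cxp, cyp = (j + 0.5) * stride, (i + 0.5) * stride
            l, t, r, b = dist[:, i, j] * stride
            if l + r <= 0 or t + b <= 0:
                continue
            dets.append(Detection(int(best_cls[i, j]), float(best_score[i, j]),
                                  (cxp - l, cyp - t, cxp + r, cyp + b)))
    return dets


def nms(dets, iou_threshold: float = 0.45) -> list:
    """Greedy class-wise suppression by descending score (idempotent)."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    keep = []
    suppressed = [False] * len(dets)
    for oi, i in enumerate(order):
        if suppressed[i]:
            continue
        keep.append(dets[i])
        for j in order[oi + 1:]:
            if suppressed[j] or dets[j].class_id != dets[i].class_id:
                continue
            if iou(dets[i].box, dets[j].box) >= iou_threshold:
                suppressed[j] = True
    return keep


def _as_samples(dets, gts):
    """Normalize (dets, gts) to per-image sample lists.

    Flat inputs (Detections / ``(class, box)`` tuples) are treated as one
    image; per-image grouping uses lists of lists.
    """
    grouped = (len(dets) > 0 and isinstance(dets[0], list)) or \
              (len(gts) > 0 and isinstance(gts[0], list))
    if grouped:
        if len(dets) != len(gts):
            raise ValueError("per-image detection/ground-truth lists must align")
        return [list(d) for d in dets], [list(g) for g in gts]
    return [list(dets)], [list(gts)]


def _match_flags(dets, gts, iou_threshold, class_id=None):
    """TP flags down the ranked list plus the number of ground truths.

    ``dets``/``gts`` are aligned per-image lists; ground truths are corner
    boxes with classes (tuples ``(class_id, corners)``).
    """
    records = []      # (score, image, det index, class)
    for img, dd in enumerate(dets):
        for k, d in enumerate(dd):
            if class_id is None or d.class_id == class_id:
                records.append((d.score, img, k, d))
    records.sort(key=lambda r: (-r[0], r[1], r[2]))
    n_gt = 0
    unmatched = []
    for gg in gts:
        sel = [(c, box) for c, box in gg if class_id is None or c == class_id]
        n_gt += len(sel)
        unmatched.append([True] * len(sel))
    gts_sel = [[(c, box) for c, box in gg
                if class_id is None or c == class_id] for gg in gts]
    tp = np.zeros(len(records), dtype=bool)
    for r, (_, img, _, det) in enumerate(records):
        best, best_iou = -1, -1.0
        for g, (gcls, gbox) in enumerate(gts_sel[img]):
            if not unmatched[img][g] or gcls != det.class_id:
                continue
            v = iou(det.box, gbox)
            # highest IoU wins; equal IoU goes to the earlier ground truth
            if v >= iou_threshold and v > best_iou:
                best, best_iou = g, v
        if best >= 0:
            unmatched[img][best] = False
            tp[r] = True
    return tp, n_gt


def _ap_from_flags(tp: np.ndarray, n_gt: int) -> PRCurve:
    if n_gt == 0:
        raise ValueError("AP undefined without ground truths")
    if len(tp) == 0:
        return PRCurve(np.array([0.0]), np.array([1.0]), 0.0)
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # monotone (ceiling-from-the-right) interpolation, all points
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    ap = float(np.sum((r[1:] - r[:-1]) * p[1:]))
    return PRCurve(recall, precision, ap)


def average_precision(dets, gts, iou_threshold: float = 0.5,
                      class_id: int | None = None) -> PRCurve:
    """PR curve and AP; class-exact greedy matching, one match per GT.

    ``dets``: Detections (flat, or per-image lists); ``gts``: ``(class_id,
    corner_box)`` tuples in the same pixel frame, grouped likewise.
    """
    d, g = _as_samples(dets, gts)
    tp, n_gt = _match_flags(d, g, iou_threshold, class_id)
    return _ap_from_flags(tp, n_gt)


def mean_ap(dets, gts, thresholds=None) -> dict:
    """Per-class AP and {map50, map5095} over the classes present in GT."""
    d, g = _as_samples(dets, gts)
    classes = sorted({c for gg in g for c, _ in gg})
    if not classes:
        raise ValueError("empty ground truth set")
    ths = tuple(thresholds) if thresholds is not None else COCO_THRESHOLDS
    per_class = {}
    for c in classes:
        aps = [average_precision(d, g, t, class_id=c).ap for t in ths]
        ap50 = (aps[ths.index(0.5)] if 0.5 in ths
                else average_precision(d, g, 0.5, class_id=c).ap)
        per_class[c] = {"ap50": ap50, "ap": float(np.mean(aps))}
    return {
        "map50": float(np.mean([v["ap50"] for v in per_class.values()])),
        "map5095": float(np.mean([v["ap"] for v in per_class.values()])),
        "per_class": per_class,
    }
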