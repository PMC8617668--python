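"""Precision/recall curves, VOC 2010-2012 exact-AUC mAP, and COCO-style AP50.

Two reporting modes coexist, mirroring how detection benchmarks are scored:

* **Counts** (TP/FP/FN, precision, recall) at a fixed objectness gate
  (default 0.25): what an operator deploying the detector would see.
* **Average precision** over the full confidence sweep: detections of all
  confidences are pooled across frames into one global ranking; TP/FP flags
  accumulated down the ranking yield a precision-recall curve, which is
  integrated either exactly under its monotone envelope (VOC 2010-2012) or
  sampled at 101 evenly spaced recall points (COCO AP50).  Both use a single
  IoU threshold of 0.5 by default — for very small objects a stricter
  localisation demand would dominate the metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Detection, GroundTruthBox, match_detections


@dataclass
class PRCurve:
    """A ranked precision-recall curve: one (recall, precision) point after
    each detection in the global confidence ranking, plus the ground-truth
    count the recalls are normalised by."""

    recalls: np.ndarray
    precisions: np.ndarray
    n_gt: int

    def __post_init__(self) -> None:
        self.recalls = np.asarray(self.recalls, dtype=float)
        self.precisions = np.asarray(self.precisions, dtype=float)
        if self.recalls.shape != self.precisions.shape:
            raise ValueError("recall and precision arrays must be aligned")

    def __len__(self) -> int:
        return len(self.recalls)

    def envelope(self) -> np.ndarray:
        """Monotone precision envelope: at each point, the maximum precision
        attained at that recall or any higher recall."""
        if len(self) == 0:
            return np.empty(0)
        return np.maximum.accumulate(self.precisions[::-1])[::-1]


@dataclass
class EvalResult:
    """Counts at the fixed confidence gate plus sweep-based AP metrics."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    voc_map: float
    coco_ap50: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "voc_map": self.voc_map,
            "coco_ap50": self.coco_ap50,
        }


def pr_curve(
    dets: list[Detection],
    gts: list[GroundTruthBox],
    iou_threshold: float = 0.5,
) -> PRCurve:
    """Build the ranked precision-recall curve.

    All detections (no confidence gate) are sorted by descending confidence
    and greedily matched per frame; TP/FP are accumulated down the ranking
    and a (recall, precision) point is emitted after every detection.
    """
    if len(gts) == 0 and len(dets) > 0:
        warnings.warn(
            "PR curve requested with detections but no ground truth; "
            "recall is undefined and reported as 0",
            stacklevel=2,
        )
        n = len(dets)
        return PRCurve(np.zeros(n), np.zeros(n), 0)
    res = match_detections(dets, gts, iou_threshold, confidence_threshold=0.0)
    n = len(res.ranked_indices)
    recalls = np.zeros(n)
    precisions = np.zeros(n)
    tp = 0
    for rank, i in enumerate(res.ranked_indices):
        if res.tp_flags[i]:
            tp += 1
        recalls[rank] = tp / len(gts) if gts else 0.0
        precisions[rank] = tp / (rank + 1)
    return PRCurve(recalls, precisions, len(gts))


def voc_map(curve: PRCurve) -> float:
    """Exact area under the monotone-envelope precision-recall curve
    (single-class, so mAP coincides with AP)."""
    if len(curve) == 0 or curve.n_gt == 0:
        return 0.0
    env = curve.envelope()
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(curve.recalls, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def coco_ap50(curve: PRCurve) -> float:
    """COCO-style AP at IoU 0.5: the monotone envelope evaluated at the 101
    recall points 0.00, 0.01, ..., 1.00 and averaged."""
    if len(curve) == 0 or curve.n_gt == 0:
        return 0.0
    env = curve.envelope()
    grid = np.linspace(0.0, 1.0, 101)
    # first curve point with recall >= grid value; beyond max recall -> 0
    idx = np.searchsorted(curve.recalls, grid - 1e-12, side="left")
    vals = np.where(idx < len(curve), env[np.minimum(idx, len(curve) - 1)], 0.0)
    return float(vals.mean())


def evaluate(
    dets: list[Detection],
    gts: list[GroundTruthBox],
    iou_threshold: float = 0.5,
    confidence_threshold: float = 0.25,
) -> EvalResult:
    """One-call evaluation: gated counts plus sweep-based AP metrics.

    TP/FP/FN, precision and recall are computed with detections below
    ``confidence_threshold`` discarded; ``voc_map`` and ``coco_ap50`` sweep
    all detections regardless of the gate.
    """
    counts = match_detections(dets, gts, iou_threshold, confidence_threshold)
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    curve = pr_curve(dets, gts, iou_threshold)
    return EvalResult(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        voc_map=voc_map(curve),
        coco_ap50=coco_ap50(curve),
    )
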