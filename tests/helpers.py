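"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: IoU by
literally rasterising boxes onto a pixel grid and counting, average
precision by evaluating the precision envelope pointwise and summing
rectangles.
"""

from __future__ import annotations

import numpy as np

from skywatch.geometry import BBox


def rasterized_iou(a: BBox, b: BBox) -> float:
    """IoU by filling both boxes on a boolean pixel grid and counting."""
    w = int(max(a.x2, b.x2)) + 1
    h = int(max(a.y2, b.y2)) + 1
    ga = np.zeros((h, w), dtype=bool)
    gb = np.zeros((h, w), dtype=bool)
    ga[int(a.y) : int(a.y2), int(a.x) : int(a.x2)] = True
    gb[int(b.y) : int(b.y2), int(b.x) : int(b.x2)] = True
    inter = int((ga & gb).sum())
    union = int((ga | gb).sum())
    return inter / union


def envelope_at(recalls, precisions, r: float) -> float:
    """Max precision over curve points with recall >= r (0 past the curve)."""
    vals = [p for rr, p in zip(recalls, precisions) if rr >= r - 1e-15]
    return max(vals, default=0.0)


def envelope_rectangle_ap(recalls, precisions) -> float:
    """Exact area under the monotone precision envelope, rectangle by
    rectangle over the sorted unique recall values."""
    if len(recalls) == 0:
        return 0.0
    ap = 0.0
    prev = 0.0
    for r in sorted(set(recalls)):
        ap += (r - prev) * envelope_at(recalls, precisions, r)
        prev = r
    return ap


def hundred_one_point_ap(recalls, precisions) -> float:
    """COCO-style AP: envelope sampled at 101 evenly spaced recalls."""
    if len(recalls) == 0:
        return 0.0
    grid = [i / 100.0 for i in range(101)]
    return sum(envelope_at(recalls, precisions, r) for r in grid) / 101.0


def scene_counts(scene_pair, scene_detections, warmup: int = 15) -> dict:
    """Centre-matched TP/FP/recall per scene mode, past the warm-up frames."""
    from skywatch.geometry import match_detections_by_center

    out = {}
    for mode, (frames, gts) in scene_pair.items():
        dets = [d for d in scene_detections[mode] if d.frame_index >= warmup]
        gts_w = [g for g in gts if g.frame_index >= warmup]
        res = match_detections_by_center(dets, gts_w)
        out[mode] = {
            "tp": res.tp,
            "fp": res.fp,
            "fn": res.fn,
            "recall": res.tp / res.n_gt if res.n_gt else 0.0,
        }
    return out


def random_matching_instance(rng: np.random.Generator, max_dets=10, max_gts=5):
    """A small random detection/ground-truth instance: some detections are
    jittered copies of ground truths, some are clutter."""
    from skywatch.geometry import Detection, GroundTruthBox

    n_gt = int(rng.integers(1, max_gts + 1))
    gts = []
    for _ in range(n_gt):
        w = int(rng.integers(5, 20))
        h = int(rng.integers(5, 20))
        x = int(rng.integers(0, 80))
        y = int(rng.integers(0, 80))
        gts.append(GroundTruthBox(BBox(x, y, w, h)))
    n_det = int(rng.integers(0, max_dets + 1))
    dets = []
    for _ in range(n_det):
        if gts and rng.random() < 0.6:
            g = gts[int(rng.integers(0, len(gts)))].box
            dx, dy = rng.integers(-3, 4, size=2)
            box = BBox(g.x + int(dx), g.y + int(dy), g.w, g.h)
        else:
            box = BBox(
                int(rng.integers(0, 80)),
                int(rng.integers(0, 80)),
                int(rng.integers(5, 20)),
                int(rng.integers(5, 20)),
            )
        dets.append(Detection(box, float(rng.uniform(0.05, 1.0))))
    return dets, gts
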