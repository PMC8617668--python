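"""Axis-aligned bounding-box geometry, IoU, and detection/ground-truth matching.

Every box in this package uses a single convention: 0-based coordinates and
half-open pixel extents.  A box ``(x, y, w, h)`` covers the pixel region
``[x, x+w) x [y, y+h)``, so a box with integer fields covers exactly ``w*h``
pixel centres and intersection/union areas computed analytically agree
*exactly* with a brute-force pixel-rasterisation count.  Format readers
(Pascal-VOC XML, darknet txt) convert to this convention at the boundary.

Matching follows the Pascal-VOC convention: detections are ranked by
descending confidence, each is greedily assigned to the not-yet-matched
ground truth with which it has the highest IoU, provided that IoU clears the
threshold.  Each ground truth can satisfy at most one detection; surplus
detections on the same object are false positives.  Ties in confidence are
broken by input order, which makes the procedure fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BBox:
    """Axis-aligned pixel box: left edge ``x``, top edge ``y``, width, height.

    Covers the half-open region ``[x, x+w) x [y, y+h)``.  Width and height
    must be strictly positive; coordinates may be fractional (e.g. after
    rescaling from network resolution).
    """

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(
                f"BBox requires positive width and height, got w={self.w}, h={self.h}"
            )

    @property
    def x2(self) -> float:
        """Right edge (exclusive)."""
        return self.x + self.w

    @property
    def y2(self) -> float:
        """Bottom edge (exclusive)."""
        return self.y + self.h

    @property
    def cx(self) -> float:
        """Horizontal centre."""
        return self.x + self.w / 2.0

    @property
    def cy(self) -> float:
        """Vertical centre."""
        return self.y + self.h / 2.0

    def area(self) -> float:
        return self.w * self.h

    def contains_point(self, px: float, py: float) -> bool:
        """True if the point lies inside the half-open box region."""
        return self.x <= px < self.x2 and self.y <= py < self.y2

    def intersection_area(self, other: "BBox") -> float:
        iw = min(self.x2, other.x2) - max(self.x, other.x)
        ih = min(self.y2, other.y2) - max(self.y, other.y)
        if iw <= 0 or ih <= 0:
            return 0.0
        return iw * ih


@dataclass(frozen=True)
class Detection:
    """A detector output: a box, an objectness/confidence score in [0, 1],
    the frame it belongs to, and an identifier of the model that produced it."""

    box: BBox
    confidence: float
    frame_index: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")


@dataclass(frozen=True)
class GroundTruthBox:
    """An annotated object.  The datasets this package targets are
    single-class ("bird"), so the label defaults accordingly."""

    box: BBox
    frame_index: int = 0
    label: str = "bird"


@dataclass
class MatchResult:
    """Outcome of matching a detection list against ground truth.

    ``tp_flags`` is aligned with the *input* detection list; detections below
    the confidence threshold are neither TP nor FP (flag False, not kept).
    ``ranked_indices`` lists the indices of kept detections in the order they
    were processed (descending confidence), which is the ranking a
    precision-recall sweep needs.
    """

    tp_flags: list[bool]
    kept: list[bool]
    ranked_indices: list[int]
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)
    n_gt: int = 0

    @property
    def tp(self) -> int:
        return sum(self.tp_flags)

    @property
    def fp(self) -> int:
        return sum(self.kept) - self.tp

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes on the half-open pixel convention.

    Returns a value in [0, 1]; 0 for disjoint boxes.  For integer-coordinate
    boxes the result is exactly the rasterised pixel-count ratio.
    """
    if not isinstance(a, BBox) or not isinstance(b, BBox):
        raise TypeError("iou expects BBox arguments")
    inter = a.intersection_area(b)
    if inter == 0.0:
        return 0.0
    union = a.area() + b.area() - inter
    return inter / union


def _greedy_match(
    order: list[int],
    dets: list[Detection],
    gts: list[GroundTruthBox],
    score,
    threshold: float,
) -> tuple[dict[int, int], list[int]]:
    """Greedy one-to-one assignment core shared by IoU and centre matching.

    ``order`` gives detection indices in processing order; ``score(det, gt)``
    must be higher-is-better with ``threshold`` the acceptance cut.  A
    detection may only match a ground truth of the same frame.  Returns the
    detection->gt assignment and the list of TP detection indices.
    """
    gt_by_frame: dict[int, list[int]] = {}
    for j, g in enumerate(gts):
        gt_by_frame.setdefault(g.frame_index, []).append(j)
    gt_used = [False] * len(gts)
    assignment: dict[int, int] = {}
    for i in order:
        det = dets[i]
        best_j = -1
        best_s = -1.0
        for j in gt_by_frame.get(det.frame_index, ()):
            if gt_used[j]:
                continue
            s = score(det, gts[j])
            if s >= threshold and s > best_s:
                best_s = s
                best_j = j
        if best_j >= 0:
            gt_used[best_j] = True
            assignment[i] = best_j
    return assignment, [i for i in order if i in assignment]


def match_detections(
    dets: list[Detection],
    gts: list[GroundTruthBox],
    iou_threshold: float = 0.5,
    confidence_threshold: float = 0.25,
) -> MatchResult:
    """Classify detections as TP/FP against ground truth; count FN.

    Detections with confidence below ``confidence_threshold`` are discarded
    before matching (they count as neither TP nor FP).  The survivors are
    processed in descending confidence (ties by input order); each becomes a
    TP if it attains IoU >= ``iou_threshold`` with a same-frame, not yet
    matched ground truth (the best-IoU one), else an FP.  Ground truths left
    unmatched are FN.
    """
    for t, name in ((iou_threshold, "iou_threshold"), (confidence_threshold, "confidence_threshold")):
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    kept = [d.confidence >= confidence_threshold for d in dets]
    order = sorted(
        (i for i in range(len(dets)) if kept[i]),
        key=lambda i: -dets[i].confidence,
    )
    assignment, tps = _greedy_match(
        order, dets, gts, lambda d, g: iou(d.box, g.box), iou_threshold
    )
    tp_flags = [False] * len(dets)
    for i in tps:
        tp_flags[i] = True
    return MatchResult(
        tp_flags=tp_flags,
        kept=kept,
        ranked_indices=order,
        matched_pairs=sorted(assignment.items()),
        n_gt=len(gts),
    )


def match_detections_by_center(
    dets: list[Detection],
    gts: list[GroundTruthBox],
    confidence_threshold: float = 0.25,
) -> MatchResult:
    """Match by centre containment instead of IoU overlap.

    A detection is a TP if its box centre falls inside a same-frame,
    not-yet-matched ground-truth box (greedy, descending confidence;
    among admissible ground truths the one whose centre is nearest is
    taken).  Useful for detectors whose box extents are only coarse
    localisations of very small objects, where IoU would conflate
    "found the bird" with "drew a tight box".
    """
    kept = [d.confidence >= confidence_threshold for d in dets]
    order = sorted(
        (i for i in range(len(dets)) if kept[i]),
        key=lambda i: -dets[i].confidence,
    )

    def score(d: Detection, g: GroundTruthBox) -> float:
        if not g.box.contains_point(d.box.cx, d.box.cy):
            return -1.0
        dist = ((d.box.cx - g.box.cx) ** 2 + (d.box.cy - g.box.cy) ** 2) ** 0.5
        return 1.0 / (1.0 + dist)

    assignment, tps = _greedy_match(order, dets, gts, score, 0.0)
    tp_flags = [False] * len(dets)
    for i in tps:
        tp_flags[i] = True
    return MatchResult(
        tp_flags=tp_flags,
        kept=kept,
        ranked_indices=order,
        matched_pairs=sorted(assignment.items()),
        n_gt=len(gts),
    )
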