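"""Front-ends that adapt 4K sky video to a fixed-resolution detector.

* **Tiling** — a high-resolution frame is partitioned into an exact grid of
  non-overlapping tiles (default 2x2, i.e. 3840x2160 -> four 1920x1080
  tiles); each tile is resized to the detector's square input resolution
  (default 1024) and processed independently, and tile-local detections are
  re-projected into global frame coordinates.  Small birds survive the far
  milder per-tile downscaling.  Birds straddling a tile boundary are not
  handled specially: each tile sees only its fragment.
* **Temporal stacking** — frames t-1, t, t+1 are packed into the three
  channels of one input so frame-to-frame motion becomes a feature.  The
  first and last frames of a sequence have no complete neighbourhood and are
  excluded, so N frames yield N-2 stacks.
* **Anchor estimation** — k-means (k=9) on the (width, height) pairs of
  ground-truth boxes, the standard prior-box recipe for single-shot
  detectors.

Resizing uses a plain anisotropic stretch (independent x/y scale factors, no
letterboxing); the inverse stretch lives in one place so the convention can
be swapped if needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .geometry import BBox, Detection, GroundTruthBox, iou

NETWORK_SIZE = 1024


@dataclass(frozen=True)
class TileLayout:
    """Exact-partition tile grid over a frame.

    The grid must divide the frame exactly; tile size is derived.
    """

    frame_w: int = 3840
    frame_h: int = 2160
    grid_cols: int = 2
    grid_rows: int = 2

    def __post_init__(self) -> None:
        if self.frame_w % self.grid_cols or self.frame_h % self.grid_rows:
            raise ValueError(
                f"grid {self.grid_rows}x{self.grid_cols} does not exactly "
                f"partition a {self.frame_w}x{self.frame_h} frame"
            )

    @property
    def tile_w(self) -> int:
        return self.frame_w // self.grid_cols

    @property
    def tile_h(self) -> int:
        return self.frame_h // self.grid_rows


@dataclass
class TemporalStack:
    """Three grayscale planes (t-1, t, t+1) stacked as channels."""

    channels: np.ndarray  # (H, W, 3)
    center_index: int

    @property
    def prev(self) -> np.ndarray:
        return self.channels[..., 0]

    @property
    def cur(self) -> np.ndarray:
        return self.channels[..., 1]

    @property
    def next(self) -> np.ndarray:
        return self.channels[..., 2]


@dataclass(frozen=True)
class AnchorSet:
    """Nine (width, height) prior boxes, sorted by area ascending."""

    anchors: tuple

    def __post_init__(self) -> None:
        if any(w <= 0 or h <= 0 for w, h in self.anchors):
            raise ValueError("anchors must have positive dimensions")

    def __str__(self) -> str:
        return " ".join(f"({w},{h})" for w, h in self.anchors)


def tile_frame(frame: np.ndarray, layout: TileLayout | None = None):
    """Split a frame into its grid tiles, row-major.

    Returns a list of ``(tile, row, col)`` triples; the tiles are views into
    the frame and together cover it exactly with no overlap.
    """
    layout = layout or TileLayout()
    if frame.shape[:2] != (layout.frame_h, layout.frame_w):
        raise ValueError(
            f"frame shape {frame.shape[:2]} does not match layout "
            f"{layout.frame_h}x{layout.frame_w}"
        )
    tiles = []
    th, tw = layout.tile_h, layout.tile_w
    for r in range(layout.grid_rows):
        for c in range(layout.grid_cols):
            tiles.append((frame[r * th : (r + 1) * th, c * tw : (c + 1) * tw], r, c))
    return tiles


def resize_to_network(img: np.ndarray, network_size: int = NETWORK_SIZE) -> np.ndarray:
    """Anisotropic stretch to the square detector input resolution."""
    out = _sk_resize(
        np.asarray(img, dtype=float),
        (network_size, network_size),
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    return out


def _check_rc(row: int, col: int, layout: TileLayout) -> None:
    if not (0 <= row < layout.grid_rows and 0 <= col < layout.grid_cols):
        raise ValueError(f"tile ({row}, {col}) outside grid")


def map_detection_to_global(
    det: Detection,
    row: int,
    col: int,
    layout: TileLayout | None = None,
    network_size: int = NETWORK_SIZE,
) -> Detection:
    """Re-project a network-coordinate detection into global frame pixels.

    The box is stretched from network resolution back to tile resolution
    (independent x/y factors) and translated by the tile origin; confidence
    and frame index are untouched.
    """
    layout = layout or TileLayout()
    _check_rc(row, col, layout)
    sx = layout.tile_w / network_size
    sy = layout.tile_h / network_size
    b = det.box
    box = BBox(
        x=b.x * sx + col * layout.tile_w,
        y=b.y * sy + row * layout.tile_h,
        w=b.w * sx,
        h=b.h * sy,
    )
    return Detection(box, det.confidence, det.frame_index, det.source_id)


def translate_tile_detection(
    det: Detection,
    row: int,
    col: int,
    layout: TileLayout | None = None,
) -> Detection:
    """Translate a tile-native-resolution detection into global coordinates
    (no rescaling; for backends that work at tile resolution directly)."""
    layout = layout or TileLayout()
    _check_rc(row, col, layout)
    b = det.box
    box = BBox(b.x + col * layout.tile_w, b.y + row * layout.tile_h, b.w, b.h)
    return Detection(box, det.confidence, det.frame_index, det.source_id)


def map_detection_to_network(
    det: Detection,
    row: int,
    col: int,
    layout: TileLayout | None = None,
    network_size: int = NETWORK_SIZE,
) -> Detection:
    """Inverse of :func:`map_detection_to_global` for boxes inside one tile."""
    layout = layout or TileLayout()
    _check_rc(row, col, layout)
    sx = network_size / layout.tile_w
    sy = network_size / layout.tile_h
    b = det.box
    box = BBox(
        x=(b.x - col * layout.tile_w) * sx,
        y=(b.y - row * layout.tile_h) * sy,
        w=b.w * sx,
        h=b.h * sy,
    )
    return Detection(box, det.confidence, det.frame_index, det.source_id)


def merge_tile_detections(
    per_tile: list[list[Detection]],
    cross_tile_nms_iou: float | None = None,
) -> list[Detection]:
    """Combine already-globalised per-tile detection lists.

    By default this is plain concatenation — objects straddling a tile
    boundary may yield one fragment per tile and are left as-is.  If
    ``cross_tile_nms_iou`` is set, lower-confidence detections overlapping a
    kept one above that IoU are suppressed (greedy, descending confidence).
    """
    merged: list[Detection] = [d for tile in per_tile for d in tile]
    if cross_tile_nms_iou is None:
        return merged
    order = sorted(range(len(merged)), key=lambda i: -merged[i].confidence)
    kept: list[Detection] = []
    for i in order:
        d = merged[i]
        if any(
            k.frame_index == d.frame_index and iou(k.box, d.box) >= cross_tile_nms_iou
            for k in kept
        ):
            continue
        kept.append(d)
    return kept


def temporal_stack(prev: np.ndarray, cur: np.ndarray, nxt: np.ndarray, center_index: int = 1) -> TemporalStack:
    """Stack three consecutive frames as the channels (t-1, t, t+1)."""
    if not (prev.shape == cur.shape == nxt.shape):
        raise ValueError("all three frames must share one shape")
    return TemporalStack(np.stack([prev, cur, nxt], axis=-1), center_index)


def stack_sequence(frames) -> list[TemporalStack]:
    """Temporal stacks for every interior frame of a sequence.

    The first and last frames lack a complete (t-1, t, t+1) neighbourhood
    and are excluded, so N frames yield exactly N-2 stacks, centred on
    frames 1 .. N-2.
    """
    frames = list(frames)
    if len(frames) < 3:
        raise ValueError(f"need at least 3 frames, got {len(frames)}")
    return [
        temporal_stack(frames[t - 1], frames[t], frames[t + 1], center_index=t)
        for t in range(1, len(frames) - 1)
    ]


def estimate_anchors(
    gt_boxes: list[GroundTruthBox],
    k: int = 9,
    seed: int = 0,
    max_iter: int = 300,
) -> AnchorSet:
    """k-means prior-box estimation on ground-truth (width, height) pairs.

    Plain Euclidean k-means with seeded initialisation; the k centroids are
    rounded to integer pixels and returned sorted by area ascending.
    """
    if len(gt_boxes) < k:
        raise ValueError(f"need at least {k} boxes, got {len(gt_boxes)}")
    from sklearn.cluster import KMeans
    from sklearn.exceptions import ConvergenceWarning

    dims = np.array([[g.box.w, g.box.h] for g in gt_boxes], dtype=float)
    with warnings.catch_warnings():
        # duplicate (w, h) points can collapse clusters; accept the result
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=k, random_state=seed, n_init=10, max_iter=max_iter)
        km.fit(dims)
    cents = np.rint(km.cluster_centers_).astype(int)
    cents = np.maximum(cents, 1)
    pairs = sorted((int(w), int(h)) for w, h in cents)
    pairs.sort(key=lambda wh: wh[0] * wh[1])
    return AnchorSet(tuple(pairs))


def tile_annotations(
    gts: list[GroundTruthBox],
    layout: TileLayout | None = None,
) -> tuple[dict[tuple[int, int], list[GroundTruthBox]], int]:
    """Assign ground-truth boxes to tiles in tile-local coordinates.

    Boxes not fully contained in a single tile are dropped; the count of
    dropped boxes is returned alongside so callers can log it.
    """
    layout = layout or TileLayout()
    per_tile: dict[tuple[int, int], list[GroundTruthBox]] = {
        (r, c): [] for r in range(layout.grid_rows) for c in range(layout.grid_cols)
    }
    dropped = 0
    for g in gts:
        c = int(g.box.x // layout.tile_w)
        r = int(g.box.y // layout.tile_h)
        if not (0 <= r < layout.grid_rows and 0 <= c < layout.grid_cols):
            dropped += 1
            continue
        if g.box.x2 > (c + 1) * layout.tile_w or g.box.y2 > (r + 1) * layout.tile_h:
            dropped += 1
            continue
        local = BBox(
            g.box.x - c * layout.tile_w, g.box.y - r * layout.tile_h, g.box.w, g.box.h
        )
        per_tile[(r, c)].append(GroundTruthBox(local, g.frame_index, g.label))
    return per_tile, dropped
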