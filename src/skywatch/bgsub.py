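"""Classical background-subtraction bird detector for monochrome sky video.

The pipeline, applied per frame in this fixed order:

1. **Background subtraction** — a running-average background model ``B`` is
   maintained per pixel; the foreground map is ``D = |I - B|`` and the model
   is then relaxed towards the current frame, ``B <- (1-a) B + a I``.
2. **Gain compensation** — the morphological gradient (dilation minus
   erosion, square element) of ``D`` suppresses slow, spatially smooth
   intensity shifts caused by camera gain/exposure changes while keeping the
   sharp edges that small dark birds produce.
3. **Noise removal** — Gaussian blur with a configurable kernel (default
   size 9).
4. **Blob detection** — the blurred map is binarised and 8-connected
   components are reduced to centres and equivalent-circle radii; blobs
   whose circle area falls inside a user-defined range are emitted as
   detections.

The detector has no notion of objectness, so every detection carries
confidence 1.0 and passes any downstream confidence gate.  It assumes a
near-static background: moving clouds and illumination drift turn into
foreground energy and hence false positives, which is precisely the failure
mode the deep-learning detectors in this problem domain are meant to fix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import BBox, Detection


@dataclass
class BgSubConfig:
    """Tunables of the classical pipeline.

    ``min_area``/``max_area`` bound the equivalent-circle area (px^2) of
    blobs accepted as birds, inclusively on both ends.  ``binarize_threshold``
    is on the 0-255 intensity scale of the blurred foreground map.
    """

    blur_kernel_size: int = 9
    min_area: float = 36.0
    max_area: float = 5000.0
    binarize_threshold: float = 15.0
    morph_kernel_size: int = 3

    def __post_init__(self) -> None:
        if self.blur_kernel_size < 3 or self.blur_kernel_size % 2 == 0:
            raise ValueError("blur_kernel_size must be odd and >= 3")
        if self.morph_kernel_size < 3 or self.morph_kernel_size % 2 == 0:
            raise ValueError("morph_kernel_size must be odd and >= 3")
        if not (0 < self.min_area < self.max_area):
            raise ValueError("need 0 < min_area < max_area")


@dataclass(frozen=True)
class Blob:
    """A foreground connected component summarised as a circle."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("blob radius must be positive")

    def area(self) -> float:
        return float(np.pi * self.radius**2)


class BackgroundModel:
    """Per-pixel running-average background estimate.

    The first frame seen initialises the estimate (so the first difference
    image is identically zero); thereafter each call blends the current
    frame in with weight ``learning_rate``.  ``initialize_from`` offers a
    pixelwise-median warm start over a clip of frames, which keeps moving
    objects present at start-up from imprinting ghosts that would decay only
    over ~1/learning_rate frames.
    """

    def __init__(self, learning_rate: float = 0.05):
        if not (0.0 < learning_rate <= 1.0):
            raise ValueError("learning_rate must be in (0, 1]")
        self.learning_rate = learning_rate
        self.background: np.ndarray | None = None
        self.last_stages: dict = {}

    @property
    def initialized(self) -> bool:
        return self.background is not None

    def initialize_from(self, frames) -> None:
        """Warm-start the background as the pixelwise median of ``frames``."""
        stack = np.stack([np.asarray(f, dtype=float) for f in frames])
        self.background = np.median(stack, axis=0)

    def update_and_subtract(self, frame: np.ndarray) -> np.ndarray:
        """Return ``|I - B|`` and then update ``B`` towards ``I``."""
        img = np.asarray(frame, dtype=float)
        if img.ndim != 2:
            raise ValueError(f"expected a 2-D grayscale frame, got shape {img.shape}")
        if self.background is None:
            self.background = img.copy()
            return np.zeros_like(img)
        if self.background.shape != img.shape:
            raise ValueError(
                f"frame shape {img.shape} does not match background "
                f"shape {self.background.shape}"
            )
        diff = np.abs(img - self.background)
        a = self.learning_rate
        self.background = (1.0 - a) * self.background + a * img
        return diff


def update_and_subtract(model: BackgroundModel, frame: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`BackgroundModel.update_and_subtract`."""
    return model.update_and_subtract(frame)


def morphological_gradient(img: np.ndarray, kernel_size: int = 3) -> np.ndarray:
    """Dilation minus erosion with a square structuring element.

    Non-negative everywhere; zero on constant images.  Acts as a high-pass
    that keeps object edges while flattening smooth gain drift.
    """
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd and >= 3")
    f = np.asarray(img, dtype=float)
    size = (kernel_size, kernel_size)
    return ndimage.grey_dilation(f, size=size) - ndimage.grey_erosion(f, size=size)


def _gaussian_kernel_1d(kernel_size: int) -> np.ndarray:
    # sigma from kernel size by the OpenCV GaussianBlur convention
    sigma = 0.3 * ((kernel_size - 1) * 0.5 - 1) + 0.8
    x = np.arange(kernel_size) - (kernel_size - 1) / 2.0
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    return g / g.sum()


def gaussian_blur(img: np.ndarray, kernel_size: int = 9) -> np.ndarray:
    """Separable Gaussian smoothing with an explicit odd-sized kernel."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be odd")
    f = np.asarray(img, dtype=float)
    k = _gaussian_kernel_1d(kernel_size)
    out = ndimage.convolve1d(f, k, axis=0, mode="reflect")
    return ndimage.convolve1d(out, k, axis=1, mode="reflect")


def detect_blobs(img: np.ndarray, config: BgSubConfig) -> list[Blob]:
    """Binarise the blurred foreground map and summarise 8-connected
    components as (centre, equivalent-circle radius) blobs."""
    mask = np.asarray(img, dtype=float) >= config.binarize_threshold
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    blobs = []
    for region in measure.regionprops(labels):
        cy, cx = region.centroid
        blobs.append(
            Blob(center_x=float(cx), center_y=float(cy), radius=float(np.sqrt(region.area / np.pi)))
        )
    return blobs


def blobs_to_boxes_filtered(
    blobs: list[Blob],
    config: BgSubConfig,
    frame_shape: tuple[int, int] | None = None,
    frame_index: int = 0,
) -> list[Detection]:
    """Area-filter blobs and convert survivors to detections.

    A blob is kept if its equivalent-circle area ``pi r^2`` lies inside
    ``[min_area, max_area]`` (inclusive, with a tiny float tolerance).  The
    detection box is the tight bounding square of that circle, clipped to the
    frame when a shape is given.  Confidence is fixed at 1.0.
    """
    dets = []
    eps = 1e-9
    for blob in blobs:
        area = blob.area()
        if area < config.min_area - eps or area > config.max_area + eps:
            continue
        x = blob.center_x - blob.radius
        y = blob.center_y - blob.radius
        w = h = 2.0 * blob.radius
        if frame_shape is not None:
            fh, fw = frame_shape
            x2, y2 = min(x + w, fw), min(y + h, fh)
            x, y = max(x, 0.0), max(y, 0.0)
            w, h = x2 - x, y2 - y
            if w <= 0 or h <= 0:
                continue
        dets.append(
            Detection(BBox(x, y, w, h), confidence=1.0, frame_index=frame_index, source_id="bgsub")
        )
    return dets


def detect_frame(
    model: BackgroundModel,
    frame: np.ndarray,
    config: BgSubConfig | None = None,
    frame_index: int = 0,
) -> list[Detection]:
    """Run the full pipeline on one frame: subtract -> morphological
    gradient -> Gaussian blur -> blob detection -> area filter.

    Intermediate stage images are stashed on ``model.last_stages`` for
    inspection.
    """
    config = config or BgSubConfig()
    diff = model.update_and_subtract(frame)
    grad = morphological_gradient(diff, config.morph_kernel_size)
    blurred = gaussian_blur(grad, config.blur_kernel_size)
    blobs = detect_blobs(blurred, config)
    dets = blobs_to_boxes_filtered(
        blobs, config, frame_shape=frame.shape, frame_index=frame_index
    )
    model.last_stages = {
        "difference": diff,
        "gradient": grad,
        "blurred": blurred,
        "blobs": blobs,
    }
    return dets


def detect_sequence(
    frames,
    config: BgSubConfig | None = None,
    learning_rate: float = 0.05,
    init_frames: int = 11,
) -> list[Detection]:
    """Run the detector over a frame sequence.

    The background is warm-started as the pixelwise median of the first
    ``init_frames`` frames (pass 0 to fall back to first-frame
    initialisation), then every frame is processed in order.  Detection
    ``frame_index`` values index into ``frames``.
    """
    config = config or BgSubConfig()
    model = BackgroundModel(learning_rate=learning_rate)
    frames = list(frames)
    if init_frames > 1 and len(frames) >= init_frames:
        model.initialize_from(frames[:init_frames])
    out: list[Detection] = []
    for t, frame in enumerate(frames):
        out.extend(detect_frame(model, frame, config, frame_index=t))
    return out
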