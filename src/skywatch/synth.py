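"""Synthetic sky-surveillance video with ground truth, plus a simulated detector.

The generator emulates the statistical structure of upward-facing monochrome
sky recordings around wind farms, at a configurable (usually desk-scale)
resolution:

* **Birds** are dark axis-aligned ellipses on linear trajectories with small
  heading drift, bouncing off the frame margins so every bird is fully
  visible in every frame.  Tracks have a finite lifetime; an expiring track
  is replaced by a freshly sampled one, so the number of birds per frame is
  constant and box statistics accumulate over many independent sizes.
* **Box sizes** follow a two-piece log-uniform law calibrated so that a
  configured fraction of boxes falls below a small-object threshold
  (default: ~42% below 500 px^2, the structure of the dynamic-background
  site; the near-static site preset skews smaller, with most boxes below
  200 px^2).  Per-track areas are drawn by stratified inversion so the
  realised fraction is tight even with tens of tracks.
* **Backgrounds** are either *static* (a fixed smooth vertical sky gradient
  plus per-frame sensor noise) or *dynamic* (the same, plus a multi-octave
  cloud field advected horizontally at constant speed and a slow global
  illumination drift) — the two regimes that make or break a
  background-subtraction detector.

Ground truth is the exact integer bounding box of each rendered ellipse.
Everything is reproducible from the config seed; bird trajectories depend
only on the bird stream, so two configs differing only in background mode
produce identical ground truth.

The simulated detector (`simulate_detector`) turns ground truth into noisy
detections — independent misses, positional/size jitter, Poisson false
positives — standing in for a trained neural backend so that ensembling and
evaluation can be exercised without one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import BBox, Detection, GroundTruthBox


@dataclass
class SkySceneConfig:
    """Scene parameters.  Defaults describe a full-resolution 4K stream;
    the ``klim_preset``/``skagen_preset`` helpers give desk-scale variants."""

    frame_w: int = 3840
    frame_h: int = 2160
    n_frames: int = 100
    fps_equivalent: float = 5.0  # metadata only
    n_birds: int = 12
    bird_area_range: tuple = (36.0, 2000.0)
    small_area_threshold: float = 500.0
    small_area_fraction: float = 1000.0 / 2400.0
    bird_intensity: float = 60.0  # darker-than-sky delta
    velocity_range: tuple = (4.0, 12.0)  # px/frame
    background_mode: str = "static"
    cloud_speed: float = 3.0  # px/frame
    cloud_contrast: float = 40.0
    illumination_drift: float = 0.15  # intensity/frame, dynamic mode only
    noise_sigma: float = 2.0
    sky_level: float = 200.0
    sky_gradient: float = 15.0
    bird_lifetime: int = 50  # frames per track
    aspect_range: tuple = (0.5, 1.0)
    area_drift_sigma: float = 0.01  # per-frame sd of log-area random walk
    heading_drift_sigma: float = 0.05  # radians/frame
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bird_area_range
        if not (0 < lo < hi):
            raise ValueError("bird_area_range must be positive and increasing")
        if not (0.0 <= self.small_area_fraction <= 1.0):
            raise ValueError("small_area_fraction must be in [0, 1]")
        if self.background_mode not in ("static", "dynamic"):
            raise ValueError("background_mode must be 'static' or 'dynamic'")
        if self.n_birds < 0 or self.n_frames < 1:
            raise ValueError("need n_frames >= 1 and n_birds >= 0")
        max_dim = math.sqrt(hi / min(self.aspect_range)) + 2
        if max_dim >= min(self.frame_w, self.frame_h) / 2:
            raise ValueError("largest possible bird does not fit the frame")


def klim_preset(**overrides) -> SkySceneConfig:
    """Desk-scale dynamic-background scene: moving clouds, illumination
    drift, bird boxes 36-2000 px^2 with ~42% below 500 px^2."""
    params = dict(
        frame_w=960,
        frame_h=540,
        n_frames=200,
        n_birds=12,
        background_mode="dynamic",
    )
    params.update(overrides)
    return SkySceneConfig(**params)


def skagen_preset(**overrides) -> SkySceneConfig:
    """Desk-scale near-static scene: fixed sky, smaller birds (most boxes
    below 200 px^2)."""
    params = dict(
        frame_w=960,
        frame_h=540,
        n_frames=200,
        n_birds=12,
        background_mode="static",
        bird_area_range=(16.0, 500.0),
        small_area_threshold=200.0,
        small_area_fraction=0.7,
    )
    params.update(overrides)
    return SkySceneConfig(**params)


# ---------------------------------------------------------------------------
# bird tracks


def _area_from_u(u: float, cfg: SkySceneConfig) -> float:
    """Inverse CDF of the two-piece log-uniform box-area law."""
    lo, hi = cfg.bird_area_range
    mid = min(max(lo, cfg.small_area_threshold), hi)
    f = cfg.small_area_fraction
    if mid <= lo:
        f = 0.0
    elif mid >= hi:
        f = 1.0
    if f > 0 and u < f:
        t = u / f
        return lo * (mid / lo) ** t
    t = (u - f) / (1.0 - f) if f < 1.0 else 0.0
    return mid * (hi / mid) ** t


def _dims_from_area(area: float, aspect: float, lo: float, hi: float) -> tuple[int, int]:
    """Integer box dimensions with w*h guaranteed inside [lo, hi]."""
    w = max(2, round(math.sqrt(area / aspect)))
    h = max(2, round(math.sqrt(area * aspect)))
    while w * h < lo:
        if w <= h:
            w += 1
        else:
            h += 1
    while w * h > hi and min(w, h) > 2:
        if w >= h:
            w -= 1
        else:
            h -= 1
    return w, h


class _Track:
    __slots__ = ("x", "y", "vx", "vy", "log_area", "aspect", "frames_left")

    def __init__(self, x, y, vx, vy, log_area, aspect, frames_left):
        self.x, self.y = x, y
        self.vx, self.vy = vx, vy
        self.log_area = log_area
        self.aspect = aspect
        self.frames_left = frames_left


class _BirdSampler:
    """Spawns and advances bird tracks; all randomness from one generator.

    Track areas come from a stratified, randomly permuted uniform stream so
    the realised small-box fraction stays close to the configured one even
    for a modest number of tracks.
    """

    def __init__(self, cfg: SkySceneConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        # one stratum per expected track: every track runs a full lifetime
        # (waves are synchronised), so consuming all strata keeps the
        # realised size fraction at the configured value
        n_strata = cfg.n_birds * math.ceil(cfg.n_frames / cfg.bird_lifetime)
        if n_strata > 0:
            u = (np.arange(n_strata) + rng.random(n_strata)) / n_strata
            self._u_stream = list(rng.permutation(u))
        else:
            self._u_stream = []
        # margin keeps every possible bird fully inside the frame
        hi = cfg.bird_area_range[1]
        self.margin = math.sqrt(hi / min(cfg.aspect_range)) / 2.0 + 2.0

    def _next_u(self) -> float:
        if self._u_stream:
            return self._u_stream.pop()
        return float(self.rng.random())

    def spawn(self) -> _Track:
        cfg, rng = self.cfg, self.rng
        x = rng.uniform(self.margin, cfg.frame_w - self.margin)
        y = rng.uniform(self.margin, cfg.frame_h - self.margin)
        speed = rng.uniform(*cfg.velocity_range)
        heading = rng.uniform(0, 2 * math.pi)
        area = _area_from_u(self._next_u(), cfg)
        aspect = rng.uniform(*cfg.aspect_range)
        if rng.random() < 0.5:
            aspect = 1.0 / aspect  # tall birds as often as wide ones
        return _Track(
            x, y, speed * math.cos(heading), speed * math.sin(heading),
            math.log(area), aspect, cfg.bird_lifetime,
        )

    def advance(self, tr: _Track) -> _Track:
        """Move the track one frame; expiry is handled by the caller."""
        cfg, rng = self.cfg, self.rng
        drift = rng.normal(0.0, cfg.heading_drift_sigma)
        c, s = math.cos(drift), math.sin(drift)
        tr.vx, tr.vy = tr.vx * c - tr.vy * s, tr.vx * s + tr.vy * c
        tr.x += tr.vx
        tr.y += tr.vy
        if tr.x < self.margin:
            tr.x = 2 * self.margin - tr.x
            tr.vx = -tr.vx
        elif tr.x > cfg.frame_w - self.margin:
            tr.x = 2 * (cfg.frame_w - self.margin) - tr.x
            tr.vx = -tr.vx
        if tr.y < self.margin:
            tr.y = 2 * self.margin - tr.y
            tr.vy = -tr.vy
        elif tr.y > cfg.frame_h - self.margin:
            tr.y = 2 * (cfg.frame_h - self.margin) - tr.y
            tr.vy = -tr.vy
        lo, hi = cfg.bird_area_range
        tr.log_area = float(
            np.clip(tr.log_area + rng.normal(0.0, cfg.area_drift_sigma),
                    math.log(lo), math.log(hi))
        )
        tr.frames_left -= 1
        return tr


_ELLIPSE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _ellipse_mask(w: int, h: int) -> np.ndarray:
    """Pixel mask of the ellipse inscribed in a w x h box; the mask's tight
    bounding box is exactly w x h (pixel centres at integer offsets)."""
    key = (w, h)
    if key not in _ELLIPSE_CACHE:
        yy, xx = np.mgrid[0:h, 0:w]
        dx = (xx - (w - 1) / 2.0) / (w / 2.0)
        dy = (yy - (h - 1) / 2.0) / (h / 2.0)
        _ELLIPSE_CACHE[key] = dx**2 + dy**2 <= 1.0
    return _ELLIPSE_CACHE[key]


# ---------------------------------------------------------------------------
# backgrounds


def _cloud_texture(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Multi-octave smoothed-noise cloud field, zero mean, unit std."""
    tex = np.zeros((h, w))
    for sigma, weight in ((40.0, 1.0), (16.0, 0.5), (6.0, 0.25)):
        tex += weight * ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
    tex -= tex.mean()
    tex /= tex.std()
    return tex


def generate_sequence(
    config: SkySceneConfig,
    return_background: bool = False,
):
    """Render the scene: grayscale uint8 frames plus exact ground truth.

    Returns ``(frames, gts)`` or ``(frames, gts, backgrounds)`` where
    ``backgrounds`` are the bird-free renders (including sensor noise), so a
    caller can verify that exactly the ground-truth boxes were darkened.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    bird_rng, bg_rng, noise_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    sampler = _BirdSampler(cfg, bird_rng)
    tracks = [sampler.spawn() for _ in range(cfg.n_birds)]

    # vertical sky gradient, fixed over time
    grad = (
        cfg.sky_level
        + cfg.sky_gradient * (np.linspace(-0.5, 0.5, cfg.frame_h))[:, None]
    )
    base_sky = np.broadcast_to(grad, (cfg.frame_h, cfg.frame_w))

    cloud_tex = None
    if cfg.background_mode == "dynamic":
        total_w = cfg.frame_w + int(math.ceil(cfg.cloud_speed * cfg.n_frames)) + 2
        cloud_tex = _cloud_texture(bg_rng, cfg.frame_h, total_w)

    frames: list[np.ndarray] = []
    backgrounds: list[np.ndarray] = []
    gts: list[GroundTruthBox] = []
    for t in range(cfg.n_frames):
        bg = np.array(base_sky, dtype=float)
        if cloud_tex is not None:
            off = cfg.cloud_speed * t
            i0 = int(math.floor(off))
            frac = off - i0
            sl = (1.0 - frac) * cloud_tex[:, i0 : i0 + cfg.frame_w]
            if frac > 0:
                sl = sl + frac * cloud_tex[:, i0 + 1 : i0 + 1 + cfg.frame_w]
            bg += cfg.cloud_contrast * sl
            bg += cfg.illumination_drift * t
        if cfg.noise_sigma > 0:
            bg += noise_rng.normal(0.0, cfg.noise_sigma, bg.shape)

        frame = bg.copy()
        lo, hi = cfg.bird_area_range
        for k in range(cfg.n_birds):
            if tracks[k].frames_left <= 0:
                tracks[k] = sampler.spawn()
            tr = tracks[k]
            w, h = _dims_from_area(math.exp(tr.log_area), tr.aspect, lo, hi)
            x0 = int(round(tr.x - (w - 1) / 2.0))
            y0 = int(round(tr.y - (h - 1) / 2.0))
            x0 = min(max(x0, 0), cfg.frame_w - w)
            y0 = min(max(y0, 0), cfg.frame_h - h)
            mask = _ellipse_mask(w, h)
            patch = frame[y0 : y0 + h, x0 : x0 + w]
            patch[mask] -= cfg.bird_intensity
            gts.append(GroundTruthBox(BBox(x0, y0, w, h), frame_index=t))
            sampler.advance(tr)

        frames.append(np.clip(np.rint(frame), 0, 255).astype(np.uint8))
        if return_background:
            backgrounds.append(np.clip(np.rint(bg), 0, 255).astype(np.uint8))

    if return_background:
        return frames, gts, backgrounds
    return frames, gts


# ---------------------------------------------------------------------------
# simulated detector


@dataclass
class SimDetectorConfig:
    """Noise model of a stand-in detector driven by ground truth.

    Each ground-truth box is independently missed with ``miss_rate``;
    survivors get Gaussian positional jitter and +-10% size jitter.
    ``fp_rate`` false boxes per frame (Poisson) appear at uniform positions.
    Confidences are clipped normals with separate (mean, sd) for true and
    false detections.
    """

    miss_rate: float = 0.1
    fp_rate: float = 0.5
    jitter_sigma: float = 1.0
    tp_confidence: tuple = (0.85, 0.08)
    fp_confidence: tuple = (0.45, 0.15)
    frame_w: int = 960
    frame_h: int = 540
    fp_area_range: tuple = (36.0, 1000.0)
    seed: int = 0
    source_id: str = "sim"

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be in [0, 1]")
        if self.fp_rate < 0 or self.jitter_sigma < 0:
            raise ValueError("fp_rate and jitter_sigma must be >= 0")


def _clip_conf(rng: np.random.Generator, mean_sd: tuple) -> float:
    mean, sd = mean_sd
    return float(np.clip(rng.normal(mean, sd), 0.05, 1.0))


def simulate_detector(
    gts: list[GroundTruthBox],
    config: SimDetectorConfig,
    n_frames: int | None = None,
) -> list[Detection]:
    """Generate noisy detections from ground truth under the config's noise
    model; deterministic per seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if n_frames is None:
        n_frames = max((g.frame_index for g in gts), default=-1) + 1
    dets: list[Detection] = []
    for g in gts:
        if rng.random() < cfg.miss_rate:
            continue
        b = g.box
        x = b.x + rng.normal(0.0, cfg.jitter_sigma)
        y = b.y + rng.normal(0.0, cfg.jitter_sigma)
        w = b.w * rng.uniform(0.9, 1.1)
        h = b.h * rng.uniform(0.9, 1.1)
        dets.append(
            Detection(
                BBox(x, y, w, h),
                _clip_conf(rng, cfg.tp_confidence),
                g.frame_index,
                cfg.source_id,
            )
        )
    lo, hi = cfg.fp_area_range
    for t in range(n_frames):
        for _ in range(rng.poisson(cfg.fp_rate)):
            area = lo * (hi / lo) ** rng.random()
            aspect = rng.uniform(0.5, 1.0)
            w = math.sqrt(area / aspect)
            h = math.sqrt(area * aspect)
            x = rng.uniform(0, max(cfg.frame_w - w, 1))
            y = rng.uniform(0, max(cfg.frame_h - h, 1))
            dets.append(
                Detection(
                    BBox(x, y, w, h),
                    _clip_conf(rng, cfg.fp_confidence),
                    t,
                    cfg.source_id,
                )
            )
    return dets
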