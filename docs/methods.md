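# Methods

## Geometry and matching conventions

All boxes are 0-based with half-open pixel extents: `(x, y, w, h)` covers
`[x, x+w) × [y, y+h)`. This makes integer-box areas exact pixel counts, so
the analytic IoU can be (and is, in the tests) checked against literal
rasterisation with equality rather than a tolerance. Format readers
convert at the boundary: Pascal-VOC XML is 1-based inclusive (`xmin=1,
xmax=10` → `x=0, w=10`), darknet txt stores fractional centre format.

Detections are matched to ground truth greedily in descending confidence
(ties by input order): a detection is a true positive if it attains
IoU ≥ threshold (default 0.5) with a same-frame, not-yet-matched ground
truth, taking the best-IoU candidate; each ground truth satisfies at most
one detection. This is the standard VOC assignment; the alternative
(optimal bipartite matching) differs only in contrived configurations and
would not match how the mAP figures users compare against are computed.

A second matching rule, centre-in-box, is provided for the classical
detector: its boxes are bounding squares of equivalent circles of blurred
foreground blobs, which systematically over-cover birds a few pixels wide
and under-cover large ones, so IoU-0.5 matching would measure box
tightness rather than whether the bird was found. Centre matching asks the
operational question — is there a detection centred on the bird — and is
what the scene-comparison numbers in the README and the acceptance script
report. IoU matching remains the default everywhere else.

## Evaluation metrics

Counts (TP/FP/FN, precision, recall) are reported at a fixed objectness
gate of 0.25, the usual deployment threshold for single-shot detectors.
Average precision instead sweeps all confidences: detections from all
frames are pooled into one global ranking and TP/FP flags accumulated down
it, giving one (recall, precision) point per detection. VOC 2010–2012 mAP
is the exact area under the monotone precision envelope (max precision at
any recall ≥ r); COCO-style AP50 samples that envelope at recall = 0.00,
0.01, …, 1.00 and averages. Both use IoU 0.5 only: for objects tens of
pixels in area, demanding IoU 0.75 turns the metric into a localisation
test the boxes cannot pass. Empty-ground-truth inputs yield recall 0 with
a warning rather than NaN. With ≥ 50 objects the two metrics agree to
within 0.02 (checked in the tests); the 101-point discretisation error
shrinks as 1/n.

## The classical detector

Pipeline order is fixed: background subtraction → morphological gradient →
Gaussian blur → blob detection → area filter. Stage outputs are stashed on
the model (`last_stages`) for debugging.

* **Background model**: per-pixel running average, `B ← (1−α)B + αI` after
  each subtraction, α = 0.05 by default (time constant 20 frames = 4 s at
  5 fps, slow enough not to absorb a crossing bird, fast enough to track
  exposure drift). The model sits behind a small class so a
  mixture-of-Gaussians variant can be swapped in. `detect_sequence`
  warm-starts B as the pixelwise median of the first 11 frames; median
  initialisation ignores birds passing through the warm-up clip, which
  under first-frame initialisation would imprint ghosts that decay only
  over ~1/α frames and show up as persistent false positives.
* **Morphological gradient**: dilation − erosion with a 3×3 square
  element, applied to the difference image. It flattens spatially smooth
  intensity shifts (camera gain, exposure) while keeping the sharp edges
  small birds produce.
* **Gaussian blur**: separable, explicit kernel of odd size (default 9),
  σ derived from the kernel size by the common computer-vision convention
  σ = 0.3·((k−1)/2 − 1) + 0.8.
* **Blob detection**: binarise at 15/255 (low enough that a 6-px-wide
  blurred bird survives, high enough that σ=2 sensor noise does not),
  8-connected components, centroid + equivalent-circle radius √(area/π).
* **Area filter**: keep blobs with π·r² in [36, 5000] px², inclusive.
  36 px² is the smallest bird size category of interest; 5000 px²
  discards frame-scale disturbances. The detection box is the bounding
  square of the equivalent circle, confidence fixed at 1.0 (the method has
  no objectness concept; the constant lets its output pass the shared 0.25
  gate).

The detector assumes a near-static background. On the cloud-dynamic
synthetic scenes the background model lags the advected cloud field and the
foreground map fills with structure inside the area-filter range; false
positives exceed the static-scene count by about three orders of magnitude
at identical configuration, while recall also degrades (cloud blobs merge
with bird blobs and displace their centroids). That asymmetry — works on
quiet skies, unusable on dynamic ones — is the central qualitative finding
the test suite pins down as inequalities rather than as fixed numbers.

## Tiling, temporal stacking, anchors

Tiling is an exact partition (default 2×2; 3840×2160 → four 1920×1080
tiles): no overlap, union equals the frame, checked bit-exactly. Resizing
between tile and square network resolution (default 1024) is a plain
anisotropic stretch — no letterboxing — and its inverse lives in one
function pair, so round-trip mapping is an identity for interior boxes.
Detections from different tiles are concatenated; optional cross-tile NMS
exists but is off by default, deliberately leaving boundary-straddling
birds split, since each tile only ever sees its fragment of such a bird.
An annotation-tiling helper drops boxes not fully inside one tile and
reports the dropped count.

Temporal stacks pack raw intensities of frames t−1, t, t+1 as three
channels (no differencing, no normalisation); a sequence of N frames yields
exactly N−2 stacks because the first and last frames lack a complete
neighbourhood.

Anchors are estimated by plain Euclidean k-means (k = 9, seeded, sklearn
backend) on ground-truth (w, h) pairs, centroids rounded to integer pixels
and sorted by area. IoU-distance k-means variants exist in the literature
but raw-dimension clustering is the convention the anchor consumers here
expect. All-identical inputs are tolerated (all centroids collapse).

## Ensemble voting

Per frame, all k models' detections are pooled and clustered greedily:
highest-confidence unassigned detection seeds a group, which absorbs every
unassigned detection from a *different* model with IoU ≥ 0.5 to the seed.
The one-per-model rule prevents a model that emits two boxes on one object
from double-voting. Affirmative keeps groups with ≥ 1 vote, consensus with
a strict majority (> k/2, i.e. ≥ 4 of 6 — "more than half" read strictly,
since the even-k boundary case is otherwise ambiguous), unanimous with k
votes. The emitted detection is the highest-confidence member's box with
the mean member confidence. Outputs therefore nest (unanimous ⊆ consensus
⊆ affirmative) and recall is monotone in permissiveness; both properties
are fuzz-tested. Under the independent-noise simulated folds, affirmative
maximises recall but inherits every fold's false positives, so consensus
can edge it on mAP; with real correlated models, whose extra detections are
mostly genuine, affirmative tends to win outright.

## Synthetic scenes

The generator targets the statistical structure of the two field regimes,
not photorealism:

* **Birds**: dark ellipses (intensity delta 60 below sky, monochrome
  upward-facing cameras see birds as silhouettes), axis-aligned, aspect
  0.5–1 with random orientation of the long axis, linear motion at 4–12
  px/frame with small heading drift, specular bounce at the margins so
  every bird stays fully visible. Rendering snaps each box to the integer
  pixel grid and the ellipse inscribed in a w×h box covers exactly that
  box, so ground truth is exact by construction (verified by a
  darkened-pixel containment/tightness test).
* **Sizes**: box areas follow a two-piece log-uniform law with a
  configured fraction below a small-object threshold — 1000/2400 ≈ 42%
  below 500 px² for the dynamic-background preset, most boxes below
  200 px² for the near-static preset. Per-track areas are drawn by
  stratified inversion (one stratum per track, permuted), and tracks run
  in synchronised fixed-length waves (default 50 frames) so every track
  contributes equally many boxes; together these keep the realised
  fraction within ~1–2 points of the configured value even with only
  ~50 tracks, where iid sampling would wander by ±7 points. Areas drift
  ±1%/frame as a clipped log random walk (birds approaching/receding).
* **Backgrounds**: static mode is a fixed vertical sky gradient
  (level 200, span 15) plus per-frame Gaussian sensor noise (σ = 2);
  dynamic mode adds a three-octave smoothed-noise cloud field (σ = 40, 16,
  6, unit-normalised, contrast 40) advected horizontally at 3 px/frame,
  plus a global illumination drift of 0.15 intensity/frame. Frame-to-frame
  energy is verifiably higher in dynamic mode.
* **Scales**: presets render 960×540 at 200 frames so the full suite runs
  in tens of seconds; the config accepts 4K dimensions unchanged.
  Bird trajectories are driven by a generator stream separate from the
  background stream, so two configs differing only in background mode
  produce identical ground truth — the basis of the paired
  static-vs-dynamic comparison.

What the scenes do **not** model: wing articulation and motion blur,
birds entering/leaving at frame edges (tracks teleport on respawn),
partial occlusion, aeroplanes/insects, lens distortion, vignetting, or
compression artefacts. Passing tests therefore demonstrate the pipeline's
logic and the direction of the static/dynamic asymmetry, not field
performance on real footage.

The simulated detector drops each ground truth independently with a miss
probability, jitters survivors (Gaussian position noise, ±10% size), draws
Poisson false positives per frame at uniform positions with log-uniform
areas, and assigns clipped-normal confidences (means 0.85 for true, 0.45
for false detections). The acceptance ensemble uses miss rate 0.1 per
fold — constituent detectors of roughly 90% single-model quality, the
regime cross-validated fold ensembles are built from — and fp rate 0.5 per
frame.

## Numerical and degenerate-input choices

* IoU of disjoint boxes is exactly 0.0; invalid (non-positive) boxes are
  rejected at construction.
* Area-filter bounds compare with a 1e-9 absolute tolerance so a blob whose
  equivalent-circle area is exactly the bound is kept despite float
  round-trip through √ and π.
* The COCO recall grid uses a 1e-12 guard when locating the first curve
  point at or above each grid recall, so exact rational recalls (1/2, 1/4)
  land on the correct side.
* Confidence ties everywhere break by input order; all orderings are
  stable sorts, making every pipeline stage deterministic given inputs.
* Scene generation derives independent child generators (birds,
  background, sensor noise) from one seed via seed-sequence spawning.

## Problem sizes

Default test and acceptance runs use 960×540 scenes: 120 frames × 12 birds
for the detector comparison (1260 scored boxes past the 15-frame warm-up),
200 frames × 12 birds = 2400 boxes for size calibration and ensembling,
six simulated folds, and 100-instance fuzz loops for the oracle and
nesting properties. These sizes put every statistical assertion at least
three standard errors from its threshold while keeping the whole suite
under a minute of compute.
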