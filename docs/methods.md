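# Methods

## Pipeline model and assumptions

The analyzer assumes the acquisition geometry of a flatbed scanner: kernels
spread in a **single non-overlapping layer** on a dark sheet, imaged in
reflected mode at an unknown but fixed resolution. Touching or overlapping
kernels are out of scope: they segment as one oversized contour, which the
pipeline flags when measured length exceeds a per-rice-type sanity bound
(default 15 mm) rather than attempting to split it.

Scale is established per setup with a circular reference object of known
diameter (default 22.5 mm) placed near the left edge:
`ppm = reference width in px / known width in mm`. The detector thresholds
the image (Otsu), labels connected components whose centroid lies in the
search region (left quarter by default), keeps those with circularity
4πA/P² ≥ 0.8 and takes the most circular one; its major-axis extent is the
reference width. Centroid-based selection (instead of cropping the search
window) keeps a disk straddling the region boundary intact. A manual `ppm`
override bypasses detection for deployments that calibrate rarely.

## Segmentation and morphometry

Chain: grayscale → Gaussian smoothing (kernel 7×7; σ from the standard
auto rule 0.3·((k−1)/2−1)+0.8) → binary threshold (Otsu by default, fixed
level by config) → connected components → sub-pixel contour tracing →
minimum-area rotated rectangle → edge-midpoint distances / ppm.

Numerical choices that matter:

- **Sub-pixel boundaries.** When the smoothed grayscale is available,
  contours are traced on it at the level midway between the foreground and
  background median intensities. A blurred step edge crosses its
  half-amplitude at the true boundary, so this localises edges to a small
  fraction of a pixel; tracing the binary mask instead quantises the
  boundary to half-pixels and biases the enclosing rectangle outward by
  ~0.2–0.5 px.
- **Corner convention.** Rectangle corners are ordered cyclically starting
  from the top-left (minimum x+y) with consistent orientation, so midpoint
  pairing of opposite edges is stable at any rotation. Coordinates are
  0-based, origin top-left, x rightward, y downward.
- **Dust filter.** `min_area_px` defaults to (1 mm × ppm)²; no rice kernel
  is under 1 mm.
- **Accuracy envelope.** On default synthetic scenes (12.5 px/mm), length
  MAE is ≈0.2% and width MAE ≈1.2% of truth. Per-kernel width error is
  pixel-limited: 2% of a 1.5 mm kernel is under half a pixel at this
  resolution, so individual narrow kernels can err up to ~1 px (0.08 mm)
  while the population MAE stays within 2%.
- **Degenerate inputs.** Collinear contours and zero-extent boxes raise a
  dedicated error instead of returning 0-width geometry.

## Color scoring

Scores are per kernel (reports need per-feature grain counts), computed as
the fraction of the kernel's pixels inside an inclusive HSV box. The hue
scale is fixed at 0–179 (half-degree convention) with S/V 0–255; this is
stated prominently because configs written for degree-scaled hue would be
silently wrong otherwise. Hue wraparound ranges are rejected at validation
— yellow and chalky-white targets never need them. Defaults (yellow
(20,80,80)–(35,255,255); chalky (0,0,200)–(179,40,255); flag fraction 0.30
for both) are calibration starting points and are per-rice-type
configurable; real deployments tune them interactively per variety.

## Weight model

A 100-tree random forest maps (length, width) → grams. The split is a
seeded shuffled 80/20 holdout (no cross-validation); holdout RMSE and MAPE
are embedded in the serialized model with the seed and hyperparameters.
Forest hyperparameters beyond `n_estimators` stay at library defaults.
Downstream percent-by-weight figures are ratios of summed weights, so they
are invariant to any global rescaling of predictions.

## Damaged / paddy classification

Two independently trained binary classifiers over fixed-size RGB crops of
single kernels (crop = contour bounding box padded 10%, squared with the
scene's median background color, resized). Three interchangeable backbones
sit behind one train/evaluate/predict contract:

- `vgg19_transfer`: the VGG19 convolutional topology (sixteen 3×3 stride-1
  conv layers, five 2×2 max-pools, 224×224×3 default input) run as a
  **frozen** feature extractor with seeded He-initialised random filters,
  global average+std pooling, and a trainable standardised logistic head.
  No pretrained weights are shipped; the path exercises the
  transfer-learning structure (frozen stack depth via `frozen_layers`,
  head-only training, input-size contract) at desk scale.
- `small_cnn` (default): three frozen random conv blocks (8/16/32
  channels) + the same pooled logistic head. Random convolutional features
  with a trained linear readout are a standard lightweight classifier and
  separate the generator's classes cleanly.
- `hsv_texture_features`: HSV channel means/stds plus a Sobel edge-energy
  statistic (hull striation marker) + logistic head; dependency-light.

Training crops generated by `generate_crop_dataset` are produced through
the *same* `prepare_crop` routine the analysis pipeline uses, so trained
heads see the deployment distribution.

## Grading and report

- Broken ⇔ length strictly below the threshold; equal-to-threshold counts
  as unbroken; head rice requires length strictly above. The threshold is
  per-rice-type with no universal default; the shipped IRRI-6 preset uses
  4.8 mm (75% of the 6.4 mm nominal length) as a documented illustration,
  not a standard.
- The length histogram uses [lo, lo+1) mm bins for lo = 1…9; lengths
  outside land in a flagged overflow row. Percent-by-weight per bin uses
  predicted weights (count basis available as a diagnostic); the displayed
  column is rounded to 1 decimal per row and may sum below 100 — the
  unrounded column sums to 100 exactly and is kept alongside.
- Percent deviation between a manual and a software AGL is
  100·(manual − software)/software rounded to 2 decimals (the software
  value is the denominator; the sign is negative when the software
  over-measures).
- Feature flags are independent and non-exclusive: a kernel can be both
  yellow and broken; per-feature "weight" is the sum of *predicted*
  weights over flagged kernels and is labelled as such.
- Rounding conventions: percents 1 decimal, deviations 2 decimals, lengths
  3 decimals in serialized reports.

## Synthetic scenes: what they emulate, and what they do not

Kernels are drawn as rotated **capsules** (rectangle with semicircular
ends) so the minimum-area-rectangle extents equal the specified length and
width exactly — unambiguous morphometry ground truth (an ellipse's
enclosing box depends on discretisation). The population defaults model an
IRRI-6-like sample: lengths ~N(6.4, 0.5²) mm truncated to [3, 8], widths
~N(2.0, 0.15²) mm, background gray 15/255 with σ=3 Gaussian noise
(black-sheet scan), default scale 12.5 px/mm. True weight follows
c·L·W^α·(1+ε) with c = 8×10⁻⁴ g/mm³ and α = 2 — a volume-like proxy that
puts a nominal kernel at ≈0.02 g — with ε ~ N(0, σ²) truncated > −1
(σ = 0.05 in the noisy condition, a plausible scale-repeatability spread).
Placement is rejection sampling with a minimum capsule separation of 8 px
so smoothing never merges neighbours. All generators are deterministic
under their seed.

What the generator does **not** reproduce: real grain surface texture and
translucency, non-uniform illumination, touching kernels, dust and foreign
objects, intermediate damage severities, and natural color variation
within a class. Passing the synthetic suite therefore demonstrates the
correctness of the measurement and grading machinery under the stated
acquisition assumptions — not field accuracy on factory samples, which
requires per-deployment calibration of HSV ranges, thresholds and models.

Known interaction worth noting: very dark damage patches fall below a
global Otsu threshold, so a heavily damaged kernel can segment without its
darkest region and measure short. Damage *classification* is unaffected
(crops retain the patch), but severely damaged kernels' dimensions are
less reliable — consistent with the single-global-threshold design.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run 20 scenes × 24 kernels for
morphometry, 2,500 samples for the weight law, 40-kernel scenes for color
and report checks, and 200 crops per classification task with the
`small_cnn` backbone at 64 px input — sizes chosen so the whole
verification runs in well under a minute on one CPU while keeping
population statistics stable.
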