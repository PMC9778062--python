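# Methods

`amoxquant` reimplements, end to end and on synthetic imagery, an
image-based colorimetric assay for amoxicillin: gold nanoparticles
(AuNPs) protected by an ssDNA aptamer stay dispersed (purple-red,
absorbance peak at 520 nm) until the aptamer binds amoxicillin, after
which salt aggregates the particles (blue-purple, peak at 620 nm). The
solution color therefore encodes concentration, and a camera image of
the well, not a spectrophotometer reading, is the measurand. This note
documents the models, the parameters that matter, and the design
decisions taken where the problem left them open.

## Synthetic well images

No public image set exists for this assay, so the package generates its
own calibration imagery and treats the generator as a first-class,
tested model of the experiment.

**Dose response.** The aggregated fraction of AuNPs at concentration
*c* (µM) follows a Hill curve

    f(c) = c^n / (c^n + EC50^n),      EC50 = 0.7 µM, n = 1.2

which is zero at zero dose, strictly increasing, and saturating — the
qualitative behavior the assay shows over its 0–3.9 µM working range.
EC50 sits at the midpoint of the designed concentration ladder (0,
0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.1, 1.5, 2.3, 3.1, 3.9 µM; 100
replicates per level), so the lower half of the design spans the steep
part of the curve. An A620/A520-style aggregation index is exposed as
the affine surrogate `ratio_min + f·(ratio_max − ratio_min)`
(0.18–0.95); it is informational, not used by the pipeline.

**Color.** Solution color interpolates channel-wise between a dispersed
endpoint (178, 60, 96) and an aggregated endpoint (96, 72, 158) —
purple-red to blue-purple, falling red and rising blue. Linearity in
*f* is a modeling convenience; only monotonicity matters downstream.

**Replicate chemistry noise.** Each replicate's *effective*
concentration is `c·(1 + ε_rel) + ε_abs` with ε_rel ~ N(0, 0.12) and
ε_abs ~ N(0, 0.03 µM), clipped at zero; the image keeps the nominal
design label. This emulates pipetting/incubation variability and is the
dominant error source by design: the calibration statistics this
pipeline is meant to exhibit (prediction MSE of a few hundredths of
µM² over this design) imply a per-sample relative scatter of roughly
10–15%, and an absolute blank-level scatter of a few hundredths of a
µM. With capture nuisances alone the feature→concentration map is
nearly deterministic (the network learns to cancel a global lighting
gain exactly, and pixel noise averages out over the 2500 crop pixels),
which would make the fit unrealistically perfect.

**Rendering.** A disk of jittered center (±5 px) and radius (44 ± 4 px)
is drawn on a light background in a 128×128 frame, modulated by a
radial vignette (strength 0.06) and a per-image multiplicative lighting
gain (SD 0.008), then per-pixel Gaussian noise (SD 5 intensity units)
is added and the result quantized to 8-bit RGB. Parameters were chosen
once so that a flatbed-scanner-like capture is plausible and the well
always stays fully inside the frame under maximal jitter; they are all
overridable through `RenderParams` / the YAML config.

What the generator does **not** model: specular highlights, menisci,
bubbles, off-axis illumination color casts, chromatic aberration,
JPEG artifacts, or interfering analytes. Passing tests therefore show
that the pipeline recovers concentration from color under controlled,
well-specified nuisance variation — not that it would survive arbitrary
real-world capture conditions.

**Determinism.** Every image's seed derives from
`SeedSequence([master_seed, level_index, replicate_index])` (and a
parallel stream for the chemistry noise), so datasets regenerate
bit-identically regardless of generation order.

## Preprocessing

Three steps, in order: segmentation, filtering, cropping.

1. **Median filter** (5×5, reflect padding, per channel) to protect the
   circle detector from pixel noise.
2. **Circle Hough transform.** Grayscale (Rec. 709 luma) → median
   prefilter → Sobel gradient magnitude → Otsu threshold → per-radius
   accumulator voting over radii 0.25–0.45 of the shorter image side.
   Each edge pixel votes for every center at rasterized perimeter
   distance r; only circles fully inside the frame are admissible. The
   winner is the maximum-vote circle, ties broken by larger radius,
   then smaller (row, column) — fixed so results are exactly
   reproducible and the accumulator can be checked against an
   exhaustive brute-force search (the test suite does this on small
   fixtures). A detection must collect at least 35% of its perimeter's
   ideal votes, otherwise segmentation fails loudly with the image
   named. On the default renders the detector recovers the true circle
   to a median of ~0.4 px in center and ~0.2 px in radius.
3. **Gaussian filter** (σ = 1 px, ±3σ truncation) on the segmented
   image, then the axis-aligned square inscribed in the detected circle
   (side r·√2) is resampled to **50×50** by bilinear interpolation.
   The inscribed square guarantees that no background pixel enters the
   crop when the detection is correct; the corners of the square touch
   the rasterized disk rim, so after Gaussian smoothing a trace of
   background can graze the extreme corner samples — negligible against
   2500 pixels, and quantified in the tests.

## Features

Nine numbers per crop: for each RGB channel, the mean (M1), the
root of the central second moment (M2, a population SD), and the signed
cube root of the central third moment (M3, skewness in intensity
units) — the standard color-moment descriptor. Order is fixed
channel-major: `[R:M1,M2,M3, G:…, B:…]`. Moments are computed on raw
[0, 255] intensities; scaling is the model's concern.

## Concentration regressor

A three-layer feedforward network: 9 inputs, 18 sigmoid hidden units, 1
linear output (the regression convention for networks of this
vintage). Inputs and target are min-max scaled to [0, 1] on the
training split; the inverse target map restores µM for reporting, and
the training trace is recorded on the µM² scale so the stopping
criterion is meaningful in assay units.

Training is classic **online backpropagation**: each epoch visits every
training sample once in a freshly shuffled order (shuffle stream seeded
from the network seed — training is fully deterministic) and applies a
momentum update `v ← 0.1·v − 0.1·∇; w ← w + v` after each sample
(learning rate 0.1, momentum 0.1). The objective is the mean squared
error; gradients are exact and are verified against central finite
differences in the test suite. Training stops when the epoch's
training MSE reaches 0.07 µM², or after 1000 epochs. Online updates
rather than a single full-batch step per epoch are essential here: with
full-batch steps at this learning rate the effective step size is far
too small to reach the stopping MSE within the epoch budget (it
plateaus around 0.3 µM²), whereas the online scheme reaches it in
about ten epochs on the default dataset.

Weights initialize uniform in ±0.5 with zero biases from a mandatory
seed. Models persist as JSON (weights, scalers, config, trace) and
round-trip bit-faithfully for predictions.

## Calibration statistics

- **Split:** 3:1 train/test, stratified by concentration level (every
  level appears in both sets), seeded.
- **R²** is computed against the identity line, `1 − Σ(ŷ−y)²/Σ(y−ȳ)²` —
  prediction accuracy, the convention consistent with reporting it next
  to prediction MSE. The slope/intercept reported alongside come from
  the OLS line of predictions on truth. (R² against the OLS fit is the
  other common convention; it is deliberately not used here.)
- **LOD** = k·σ_blank/S (IUPAC), k = 3 by default (3.3 supported), with
  σ_blank the sample SD of pipeline-predicted concentrations over blank
  images and S the slope of a predicted-vs-true probe.
- **Recovery/RSD:** recovery = 100·mean(measured)/spiked;
  RSD = 100·SD(measured)/mean(measured), sample SD. The spiked-sample
  workflow runs on matrix-shifted images — a constant RGB offset
  (default (−4, −2, +3)) standing in for a sample-matrix color effect —
  since no real milk-matrix imagery exists.

## Problem sizes and numerical choices

The default calibration run renders and processes 1200 images of
128×128 px and completes in a couple of minutes on one core;
preprocessing (the Hough accumulator) dominates, the network trains in
seconds. Noise is added before 8-bit clipping (never wrap-around);
filters operate in float and preserve shape and channel order; degenerate
inputs (blank images, constant targets, even kernels, out-of-range
fractions) raise typed errors rather than propagating garbage.

## Known limitations

- The slope/intercept of the predicted-vs-true line at the stopping
  point inherit some run-to-run variability from the online update
  order; the stop-at-0.07 rule can freeze a small residual bias
  (roughly ±0.05 in slope) that further training would remove.
- The generator's nuisance model is deliberately minimal (see above);
  transfer to real captures is untested and out of scope.
- One solution region per image; multi-well plates are out of scope.
- No alternative color spaces, architectures, regularization, or
  hyperparameter search — the point is the fixed, classic pipeline.
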