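# Methods

`cugrade` implements a marker-calibrated grading pipeline for elongated
produce (cucumbers), together with a synthetic scene generator that stands
in for photographs of real harvested fruit. This note records the models,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic experiments do and do not demonstrate.

## The grading problem

A cucumber is graded by the combination of a curvature class and a size
class. Curvature: A (straightest) → B → C; size: L (longest) → M → S.
B- and C-class fruit have no L size, so the label set is
{AL, AM, AS, BM, BS, CM, CS}. The numeric cut-offs are set by each
agricultural cooperative and are not standardized; the package defaults are

| parameter | default | meaning |
|---|---|---|
| `bend_a_max_deg` | 20° | max total turning angle for class A |
| `bend_b_max_deg` | 60° | max for class B; C beyond |
| `size_l_min_cm` | 24 cm | min arc length for L |
| `size_m_min_cm` | 18 cm | min arc length for M; S below |

These defaults are a design choice (plausible magnitudes that keep every
grade cell non-empty); all are configurable via `GradeThresholds`. A bent
cucumber of L length is clamped to M because the label set has no BL/CL.

## Synthetic scenes

`synthscene` renders the capture rig: a white board with four solid blue
square markers whose centers sit exactly 40 cm apart horizontally and
30 cm vertically, and one green tube whose centerline is a circular arc
parameterized by arc length L, total turning angle φ (the "bend"), and
tube diameter t. The tube has square caps (the centerline endpoints are
not dilated), so its area is exactly L·t — an analytic oracle for the
measurement stages.

Rasterization uses half-open membership across and along the tube
([−t/2, t/2) × [−L/2, L/2) in local coordinates), so a boundary that
falls exactly on a pixel-center line is counted once. With inclusive
boundaries an axis-aligned 3 cm tube rasterizes to 16 columns at
5 px/cm but 30 at 10 px/cm — a systematic +1-pixel bias that the
half-open convention removes.

The per-grade sampler draws (φ, L) uniformly from the grade's threshold
cell, with the open-ended cells bounded at φ ≤ 110° and
12 cm ≤ L ≤ 25.5 cm and thickness uniform on [2, 3.5] cm. The upper
length bound comes from the board geometry: the 30 cm marker spacing
leaves ~28 cm of interior, and the renderer rejects any tube that
reaches the marker-eroded margin, so L-grade samples span 24–25.5 cm.
Scenes get a small placement jitter (±1 cm position, ±8° orientation)
with the long axis kept predominantly vertical, matching the portrait
training canvas.

What the generator does **not** emulate: perspective distortion, lighting
gradients and shadows, specular highlights, non-uniform cucumber color
and surface texture, warts and taper, occlusion, or multiple fruit per
scene. Passing tests therefore demonstrate the correctness of the
pipeline's logic and the value of the background encoding under
controlled conditions — not field performance on photographs.

## Vision: calibration and morphometry

Markers and fruit are found by color dominance: pixel p is marker-like if
B(p) − max(R(p), G(p)) > τ_b and fruit-like if G(p) − max(R(p), B(p)) > τ_g,
with τ_b = τ_g = 40 intensity units. On a white board with blue markers
and green produce these tests are disjoint and robust to moderate pixel
noise; they are deterministic, which makes segmentation testable
pixel-for-pixel against rendered ground truth.

Calibration divides the mean top/bottom inter-marker pixel distance by the
known 40 cm spacing (and left/right by 30 cm), giving anisotropic
px/cm scales. Because all measures are ratios to the marker spacing, the
camera distance never needs to be fixed — the distance-free sizing
property that the scale-invariance tests exercise.

Measures are defined on the largest green component restricted to the
marker quadrilateral interior (eroded by the marker half-size so marker
pixels can never contaminate the mask):

- height = bounding-box vertical extent / px_per_cm_y,
- width = bounding-box horizontal extent / px_per_cm_x,
- area = pixel count / (px_per_cm_x · px_per_cm_y).

Width is deliberately the *axis-aligned* bbox extent with no rotation
normalization: bending widens the bbox, so width doubles as a curvature
proxy. A quantization limit follows from the binary mask: extents are
integer pixels, so a measure of physical size s at resolution r carries
up to ±1/r cm of error (≈ ±0.2 cm at 5 px/cm). Height (~20 cm) and area
converge fast; width (~3–7 cm) is the quantization-limited measure, and
at 5 px/cm a curved edge can shift it by ~0.2 cm (a few percent). The
scale-invariance checks use representative geometries where the spread
stays within 2%; sub-pixel agreement at arbitrary geometry is not
claimed.

## Canvas and the RGB background encoding

Training images are 100 × 340 (portrait) canvases. The segmented crop is
resampled to a fixed 10 px/cm physical scale (bilinear for pixels,
nearest for the mask) and pasted centered, by mask, so every non-object
pixel equals the background color exactly. A fixed physical scale on a
fixed canvas preserves absolute size through any later resizing — the
reason the canvas exists at all.

The encoding writes the normalized measures into the background color:

    B = round(255·h/34), G = round(255·w/10), R = round(255·a/170)

with h, w in cm, a in cm², each ratio clipped to [0, 1]. The
normalization denominators are the canvas's physical extent at 10 px/cm
(34 cm tall, 10 cm wide) and a generous area bound (170 cm²), chosen as
fixed physical constants rather than dataset min/max so that the encoding
is stable across datasets; they are configurable via `NormRanges`.
Quantization is round-half-up to 8 bits, so a decode recovers each value
to within 1/255. The baseline "black background" canvas is exactly the
encoding of (0, 0, 0); both flavors share one code path, so comparisons
isolate the encoding itself.

## The classifier

Both flavors share one shallow CNN (NHWC, float32):

    conv 8×(7×7) → batch-norm → ReLU → max-pool 2×2 →
    conv 16×(7×7) → batch-norm → ReLU → max-pool 2×2 →
    flatten → dense 64 → ReLU → dense 32 → ReLU → dense 7 → softmax

with valid (no-padding) convolutions at stride 1 and input resized to
72 (tall) × 24 (wide). The two flavors differ only in how size reaches
the network:

- **without_rgb** (baseline): the normalized (h, w, a) triplet is
  concatenated to the flattened features before the dense block; no
  dropout.
- **with_rgb**: no side channel (the background carries the sizes); four
  dropout layers — after each pooling stage and after the 64- and
  32-unit dense layers — regularize training, default drop rate 0.1 in
  both blocks (the conv-block rate is sweepable separately).

Training: softmax cross-entropy, Adam at learning rate 0.001, batch size
100 drawn with replacement (so step counts smaller than an epoch are well
defined), for exactly `max_steps` optimizer updates ("training cycles").
All randomness — initialization, batch order, dropout masks — flows from
one seeded generator, so a run is reproducible bit-for-bit on the same
platform.

Design points that were genuinely open: batch-norm is applied before the
ReLU; the dense layers use ReLU activations (without a nonlinearity three
stacked dense layers would collapse to one); dropout placement covers
both the convolutional and dense blocks, matching the two separately
tunable drop rates; the baseline is built without dropout; the scalar
side channel feeds the normalized triplet rather than raw centimeters for
optimization stability (callers may pass raw values if they prefer).
72 × 24 is read as height × width to match the portrait canvas.

The network is implemented directly in NumPy. Convolutions run as one
BLAS matmul per pass against a width-banded weight matrix built from the
kernel (tile width chosen so the GEMM stays wide enough to run near
peak); batch statistics, pooling, and dropout are vectorized; the first
layer skips its input gradient. On one CPU core a training step at batch
100 takes on the order of tens of milliseconds, which sets the problem
sizes used in the experiments below.

## Evaluation protocol

`EvalReport` computes the confusion matrix (rows true, columns predicted,
canonical grade order) and four metrics: accuracy, macro recall, macro
precision, macro F-measure (mean of per-class F1). Zero-denominator
per-class precision/F contribute 0 and are logged. On a balanced test set
macro recall equals accuracy algebraically; the implementation divides
last in that case so the identity also holds bit-for-bit.

The replicate experiment trains fresh models per (method, cycle count,
replicate) with replicate seeds `base_seed + r`, evaluates each on a
balanced held-out test set, and reports metric means over replicates.
Summary tables are means over replicates, not pooled confusions. The
experiments run at a desk scale chosen to keep a full grid re-runnable
in minutes on one core: 70 training and 10 test scenes per grade
(490 + 70 images), cycle counts {10, 1000}, 3 replicates. The `image_only`
ablation trains the with_rgb architecture on black-background canvases
with no side channel, so neither the encoding nor the scalars carry size:
whatever accuracy it reaches comes from the object pixels that survive
the 72 × 24 resize. At that resolution 1 cm ≈ 2 vertical pixels, so
neighboring size classes blur near the thresholds — the gap between the
ablation and the encoded model measures how much of the size signal the
background carries.

## Known limitations

- Synthetic-only validation; no claim transfers to real photographs
  without recalibrating thresholds, colors, and normalization ranges.
- No perspective rectification: an oblique camera would bias the
  anisotropic calibration.
- Bounding-box measures conflate bend and width by construction; medial
  axis statistics would separate them but are out of scope.
- Binary-mask quantization limits sub-centimeter width accuracy at low
  resolution (see above).
- Dropout mask draws interleave with batch draws in one generator
  stream, so adding/removing layers changes the whole stream; seeds are
  contracts within a configuration, not across configurations.
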