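# Methods

This note records the model, the numerical choices, and what the synthetic
data does and does not establish. It is written for a maintainer deciding
whether a behavior is intentional.

## Model

Both iris boundaries are modeled as circles `(x, y, r)` in pixel units
(x = column, y = row, 0-based, pixel centers on integer coordinates). The
detector is anchor-free: each boundary is a center point on a stride-1
heatmap, plus dense radius and sub-pixel offset regressions. Assumptions
inherited from the problem domain:

* exactly one eye per image (single-instance decode by global argmax);
* both circle centers lie inside the pupil disk, nearly concentric, with at
  most a small shift between them;
* boundaries are circular — ellipses and strong perspective are out of scope.

### Target encoding

The Gaussian width per circle is `σ = g/3`, where `g` is the largest corner
displacement of the circumscribing square (side `2r`) that keeps IoU ≥
`min_overlap` (default 0.7) in the worst of the three displacement cases;
the corrected quadratic-root form is used and is unit-tested against an
exhaustive search. Both channel Gaussians are truncated to the inner-circle
disk — this keeps the positive-sample region compact and balanced. With the
concentric strategy on, the overlap region (in practice the whole truncated
support, since a Gaussian is positive everywhere on its disk) receives the
shared value `min(0.5, ½(α_in·Y_in + α_out·Y_out))` in both channels, and
the per-channel center pixel / four axis-neighbors are then forced to 1.0 /
0.8, so those printed values survive clipping. `α_in = α_out = 1` by
default; the clip ceiling 0.5 and neighbor value 0.8 are part of the
encoding contract, not tunables.

With the strategy off, each channel is its plain truncated Gaussian (peak
forced to 1); no 0.8 neighbors are written in that mode.

Radius supervision covers every pixel with positive heat (the whole Gaussian
region "is responsible" for its circle's radius); offsets are supervised only
at the floored center pixels. The two offset channels are shared between
categories. When both floored centers fall in the same pixel, the stored
offset is the mean of the two fractional parts: one pixel can carry only one
value, and the mean bounds each circle's decoding error strictly below half
a pixel — this is what makes the encode→decode round trip meet its
half-pixel guarantee in all cases.

### Network

A simplified encoder–decoder: a stem conv block, then `depth−1` levels of
stride-2 downsampling (channels double per level) each followed by a
residual conv block; a stack of `bottleneck_blocks` residual conv blocks at
the deepest level; then a decoder that mirrors the encoder with bilinear ×2
upsampling, one conv block per level, and additive skips; a final block
projects to the 32-channel full-resolution feature map. The default depth is
5. The decoder conv uses stride 1: a stride-2 conv after upsampling would
cancel the upsample and contradict the full-resolution output this design
requires.

The bottleneck stack exists for receptive-field reasons: the circle centers
sit in the featureless pupil, so the evidence for the outer radius lies a
full radius away, and shallow presets would otherwise never see it (at depth
3 on 96 px images the field is ~39 px against an outer diameter of up to
58 px; three extra blocks at 1/4 resolution raise it past 60 px at ~3% step
cost).

Heads: classification (3 convs + sigmoid, 2 channels), two radius branches
with disjoint parameters (1 channel each), one shared offset head
(2 channels). Each head is two 3×3 conv+ReLU layers at `head_hidden`
channels plus a 1×1 projection. At run time the four heads are evaluated as
three fused convolutions with block-diagonal weights — an implementation
detail that shares the full-resolution patch matrices (the dominant memory
cost on CPU); a test verifies the fused path equals per-head evaluation.

Initialization: He-normal weights; the heatmap projection bias starts at
−2.19 (sigmoid ≈ 0.1, mostly-background prior); the radius projection biases
start at 12 px. The radius prior matters: with Adam at lr 10⁻³ an output
bias moves about `lr` per step, so starting at zero would leave a transient
of thousands of steps before predictions even reach the target range —
acceptable in a 20k-step full-scale schedule, not in a desk-scale one.

The mask head crops a square RoI of side `crop_scale·r̂` (default 2.0;
`crop_scale = 1` reproduces the literal radius-sized crop) around the outer
center on the feature map — ground-truth circle during training, predicted
circle at inference — and applies three stride-2 conv blocks plus a 1×1
projection and sigmoid, giving a stride-8 native map. The training loss is
evaluated at native resolution against the nearest-resized ground-truth
crop; for assembly the native map is bilinearly resized back to the RoI and
thresholded at 0.5 (ties positive). RoI sides below 8 px are clamped to 8.

### Losses

Penalty-reduced focal loss (exponents 2 and 4, normalized by the count of
exactly-1 pixels, jointly over both channels); L1 radius loss combined as
`½ Σ_k` with per-channel means over the positive region by default (the
literal two-peak form is retained as `mode="peaks"`); L1 offset loss
normalized by 2 centers × 2 components; mean binary cross-entropy for the
mask. Defaults `w_loc = w_reg = w_mask = 1`, `λ_size = 1`, `λ_off = 0.1`.
Predictions are clamped to `[1e−6, 1−1e−6]` before logarithms. All gradients
are finite-difference-checked on toy maps.

### Training loop

Adam (lr 0.001, weight decay 0.0004), batch 6, default 120 epochs. The
automatic learning-rate adjustment is a linear warmup over the first 100
steps followed by halving after 10 epochs without improvement of the
monitored loss (validation loss when a split exists). Gradients are clipped
to a global norm of 5. Both stabilizers matter at desk scale: the focal loss
is enormous at initialization (hundreds of thousands of penalized background
pixels per image), and without warmup/clipping the first steps poison Adam's
moment estimates, making short runs strongly init-sensitive. A 90/10 split
of the provided samples selects the best checkpoint by validation mean box
IoU. A NaN loss aborts with the offending batch indices. Runs are
deterministic given the seed (numpy RNG; single-threaded BLAS).

Which encoding to train with depends on the data regime: on eye-only frames
the plain truncated Gaussians localize better (a sharp unique argmax
target), while the concentric strategy is aimed at frames where the eye is a
minor region among face-like distractors. This mirrors the strategy's
published ablation behavior and is why the package's evaluation examples use
`use_cgr=False` on the default eye-only generator regime.

## Numerical choices

* Heatmap decode: global argmax, ties to the smallest row-major index;
  decoded radii are clamped to ≥ 1 px so an untrained model still produces a
  valid RoI.
* Rubber-sheet normalization (`R×A` grid, default 64×360): per angle, sample
  points interpolate linearly between the inner and outer boundary points;
  bilinear interpolation, out-of-image reads 0. The boundary rays are inset
  half a pixel at each end, so row 0 samples the first ring of iris pixel
  centers rather than the rasterized boundary itself; on a hard-rasterized
  annulus every sampled value then exceeds 0.5 (ties positive), making
  "ground-truth annulus unwraps to all ones" exact. `inset=0` restores
  literal endpoint sampling.
* Masks rasterize with the pixel-center-in-circle rule (boundary inclusive);
  images render with 1-px anti-aliased edges. Ground truth is therefore
  integer-exact while images look plausible.
* "Box IoU" uses the circumscribing squares; the analytic circle-area IoU
  (two-segment lens formula) is computed alongside and checked against a
  pixel-counting oracle. Hausdorff normalization divides x by W and y by H.
  E1 aggregates as an unweighted mean over images. The normalized-mask error
  unwraps each mask with its *own* circles (prediction with predicted, truth
  with annotated); degenerate circle pairs score the worst case 1.0.
* Input sizes must be multiples of 32; the preprocessing step centrally
  crops/pads per axis (e.g. 400×300 → 448×320) and translates annotations.

## Synthetic data

The generator emulates the degradations this detector is meant to survive:
a textured annular iris (radial+angular sinusoids plus grain) around a dark
pupil whose center may be shifted up to `center_jitter_px` (default 2) from
the iris center; bright skin/sclera background; optional elliptical eyelid
occluders clipped from the top, specular highlight disks, and Gaussian blur,
each removing/masking pixels with its own probability (defaults 0.3 / 0.5 /
0.3). The distractor regime adds dark face-like blobs far from the eye and
keeps the eye under 40% of the frame — the situation where a plain Gaussian
encoding can lock onto the wrong dark region and the concentric strategy
concentrates supervision.

Default geometry: outer radius 0.18–0.30 of the short image side, pupil
0.25–0.45 of the outer radius. Default image size 96×96 — the desk-scale
training problem (300 images, 30 epochs, batch 6) fits in roughly 12 minutes
on one CPU with the numpy engine.

What passing on this data does **not** show: robustness to real sensor
noise, gaze deviation, glasses, elliptical boundaries, or domain shift
between capture devices — real benchmarks are orders of magnitude harder
(full-scale visible-light corpora, 120-epoch schedules, 320×448 inputs).
The synthetic results validate the machinery (encoding → optimization →
decoding → metrics), not field performance.

## Known limitations

* Single instance only; no multi-eye decoding.
* The inner/outer radii are regressed independently (no pairing constraint),
  so nothing prevents a decoded inner radius from approaching the outer one
  on hard images.
* Shared offset channels mean coincident floored centers share one sub-pixel
  correction (bounded error, see above).
* The serial localize-then-segment design means segmentation quality is
  capped by localization: a missed outer center yields a misplaced RoI.
* The numpy engine is CPU-only and single-threaded; it is sized for the
  desk-scale problems above, not for full-resolution corpora.
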