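# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic experiments do and do not show.

## Directional noise reduction filter (DNRF)

The filter separates *detection* from *filtering* so that clean pixels are
never altered. For the pixel at (r, c):

1. an 11×11 window is centred on the pixel (borders mirror-padded,
   reflect-101, so no intensities are invented);
2. the four direction-placed lines through the center — middle row, middle
   column, both diagonals, 11 pixels each — are extracted;
3. each line is sorted ascending after removing the center *by position*
   (duplicated intensities elsewhere in the line survive), and the smallest
   and largest values are dropped, leaving N = 8 trimmed values;
4. the direction with the lowest population standard deviation of its
   trimmed values is selected; ties go to the fixed priority
   horizontal > vertical > main diagonal > anti diagonal;
5. the heuristic metric is the mean absolute deviation of the center from
   the selected trimmed values, HM = (1/N)·Σ |P_c − P_i|; the pixel is
   noisy iff HM > T (strict);
6. a noisy pixel is replaced by the arithmetic mean of its 3×3
   neighbourhood *excluding itself* (so an impulse never contaminates its
   own replacement), rounded to the nearest integer; the detection pass and
   all replacements read the original image, never earlier replacements.

The homogeneous-direction logic is what makes the detector texture-aware:
in an oriented texture, the iso-intensity direction has near-zero spread,
so genuine texture pixels score a low HM while isolated impulses — removed
from every direction's trimmed set only if extreme in *that* line — score
high.

**Parameters.** `threshold` T = 20 on the 0–255 scale (≈8% of range),
chosen so smooth gradients (local slope ≪ 20/pixel) pass while salt/pepper
impulses (deviation ≥ 100 in typical mid-gray surroundings) fail by a wide
margin; `window` = 11; `avg_window` = 3; `hm_mode` selects the HM form
(`"mad"` above, or `"mean_diff"` = |P_c − mean(P_i)| as an alternative).
The population (divide-by-N) standard deviation is used.

An independent step-by-step reimplementation of this procedure lives in
the test suite and the vectorized implementation is asserted equal to it
bit for bit on noisy images.

## Gabor sweep and fusion (GMT)

The complex Gabor kernel is

    g(x, y) = exp(−(x′² + γ² y′²) / (2σ²)) · exp(i(2π x′/λ + ψ)),
    x′ = x cos θ + y sin θ,  y′ = −x sin θ + y cos θ,

with x along columns and y along rows (downward). Defaults: λ = 8 px,
σ = 4 px, γ = 0.5, ψ = 0, ksize = 31, scale s = 1 (s multiplies both σ and
λ). Kernels are DC-adjusted by subtracting an envelope-weighted mean so a
constant region responds exactly zero; brightness therefore cannot
masquerade as texture (switchable via `zero_mean=False`).

The sweep covers the 180 integer orientations −90° … +89°; +90° is omitted
because its response magnitude duplicates −90°. Responses are computed as
the magnitude of the complex correlation with mirror-padded borders (FFT
implementation, kernel spectra cached across images of equal size). Fusion
is the per-pixel maximum across the 180 layers, with the winning
orientation retained as provenance; the fused map dominates every layer
pointwise and is invariant to layer permutation.

For downstream stages the fused map is rescaled to *equivalent grating
amplitude*: division by half the kernel-envelope mass maps a matched
sinusoid of amplitude A to ≈A, putting the texture-energy map back onto
the 0–255 intensity scale with an input-independent gain. It is carried as
float32 so that a float-TIFF disk round-trip is exact and stage-by-stage
CLI runs reproduce the in-memory pipeline bit for bit.

## Texture features and the feature matrix

All features are computed on the texture-energy map (GCI), not the raw
image — the classifier sees texture evidence only.

* **LBP** uses the inverted comparison rule this pipeline is specified
  with: neighbour > center → bit 0, neighbour ≤ center → bit 1 (constant
  patches code to 255). Bit order: clockwise from the top-left neighbour,
  first bit most significant. The textbook rule is available as
  `rule="standard"`.
* **LTP** with tolerance t = 5 (on the 0–255 scale): +1 / 0 / −1 per
  neighbour, split into upper (+1 pattern) and lower (−1 pattern) 8-bit
  maps with the same bit order. At t = 0 the upper map is the exact bit
  complement of the LBP map, which the tests assert.
* **GLCM** at the 45° offset (−1, +1) (up-right), 32 uniform quantization
  bins over the image's own intensity range, symmetric accumulation,
  normalized to sum 1 (counting delegated to scikit-image). Statistics:
  energy Σp², entropy −Σ p log₂ p, homogeneity Σ p/(1+|i−j|), and the
  standard marginal-index correlation, defined as 0 for a zero-variance
  (single-valued) image.
* **NSCT** is realized as an undecimated two-stage scheme: per stage, a
  circular (FFT) B3-spline lowpass — upsampled à trous (holes) at stage
  2 — splits the signal into lowpass and highpass, and the highpass is
  fanned into directional bands by a *triangular angular partition of
  unity* over frequency-plane orientation mod π (4 bands at stage 1, 2 at
  stage 2). Because the windows sum to one, lowpass + all bands reconstruct
  the input exactly (asserted to 1e−6), and circular filtering makes every
  band exactly shift-equivariant. True NSCT filter banks admit many
  realizations; this one favours exact invertibility and shift invariance,
  the two properties the pipeline relies on.

**Assembly.** Each 2-D map (LBP, LTP upper, LTP lower, 7 contourlet bands)
is block-averaged onto a 16×16 grid and stacked vertically; signed
contourlet bands are mapped to [0, 1] around 0.5 with a fixed ±255 range,
unsigned maps are divided by 255. One final broadcast row carries the four
GLCM scalars in equal column segments (correlation mapped from [−1, 1],
entropy normalized by its 2·log₂(levels) maximum). The result is a fixed
(161, 16) matrix in [0, 1] for any input image size — the precondition for
a fixed classifier. The per-channel grid of 16 keeps the classifier's
convolution cost desk-scale while leaving each channel enough resolution
to localize a lesion occupying ≥10% of the frame; the layout is recorded
in the matrix object and round-trips exactly.

## CervixNet

Both branches consume the feature matrix as one single-channel plane.
Defaults: ILL-1 filters (16, 24, 32, 48) with 5×5 kernels; ILL-2 filters
(4, 6, 8, 12) with 7×7 kernels (low count, large window); a configuration
where ILL-2 is not strictly below ILL-1 elementwise is rejected. Each
branch: conv–ReLU ×2, pool, conv–ReLU ×2, pool (2×2, stride 2). The
concatenated branches (48 + 12 = 60 channels) pass through Maxpool23,
flatten, and dense layers of sizes (256, 64, 1) — ReLU after the first
two, sigmoid on the single output. *No layer has a bias term*: a zero
input provably produces a zero pre-activation everywhere, which the tests
assert. Decision: cancer iff score ≥ 0.5 (configurable).

Training: binary cross-entropy on logits, Adam (lr 1e−3, β = 0.9/0.999),
batch 16, 30 epochs, He-normal initialization. Everything is numpy float32
with im2col convolutions; gradients were verified against central
differences in float64. Weight init and shuffling derive from explicit
seeds, so identical seeds give bit-identical trained checkpoints; the
checkpoint stores the configuration and all weights and reloads to an
exactly identical forward pass. With these sizes (≈0.7M parameters,
dominated by the first dense layer) the packaged 200-image training run
takes a few minutes on one CPU; filter counts are config-exposed for
larger budgets.

## Segmentation

Cancer-classified images are segmented from the texture-energy map (the
stage's immediate upstream product; `source="raw"` switches to the
denoised image). The map is Otsu-thresholded (strictly-above =
foreground; a constant map yields an empty mask with a warning). The
lesion *boundary* is the morphological gradient, dilation minus erosion,
with a disk of radius 3 (dilation pads with background, erosion with
foreground, so a full-frame mask has an empty gradient); the *region* is
the hole-filled mask. Erosion ⊆ mask ⊆ dilation holds by construction and
growing the element never shrinks the band.

## Metrics

HCDI and CCDI are the percentages of correctly classified healthy and
cancer images; DI is their unweighted mean. Indices are reported
*truncated* to one decimal (98.367 → 98.3) — the convention under which
the published cohort tallies reproduce exactly — and DI is the mean of
the truncated indices. Pixel metrics are standard sensitivity/specificity/
accuracy over TP/TN/FP/FN mask tallies, with table averages reported to
two decimals. Degenerate inputs (an empty truth class) raise an error
naming the undefined metric rather than returning a silent 0.

## Synthetic phantoms

The generator emulates exactly the properties the method exploits:

* healthy images: a smooth intensity plane (base ≈95–125, slopes up to
  ±40 across the frame) plus one low-frequency diagonal ripple — no
  texture;
* cancer images: the same background plus an oriented sinusoid (wavelength
  8 px = the Gabor default, amplitude 50–70, uniform random orientation)
  confined to an ellipse (semi-axes ≈18–35 px on a 128×128 frame, uniform
  pose) that is the ground-truth mask;
* salt-and-pepper noise applied last, each pixel forced to 0 or 255 with
  probability p/2 each (default p = 0.05).

Defaults were fixed once as a realistic desk-scale stand-in: lesions
occupy ≈10–20% of the frame, texture contrast is strong but not
saturating, and the noise level matches the denoising experiments. All
draws flow from one seed; identical specs render bit-identical images.

What passing the synthetic experiments shows: the implemented stages
compose correctly — impulses are detected and removed without touching
clean pixels, oriented texture is isolated with the planted orientation
recovered within ±2°, the two classes are separable by the pipeline's own
features (held-out accuracy ≥95% with 100 training phantoms per class),
and lesion regions are recovered with IoU well above 0.70. What it does
*not* show: performance on clinical cervigrams, whose texture statistics,
illumination, specular reflections and anatomy are far richer than the
phantoms; the published clinical-cohort figures are therefore reproduced
here only at the level of their printed arithmetic, not re-measured.

## Known limitations

* The NSCT realization uses circular boundary handling; bands near the
  border mix content from opposite edges (irrelevant at the 16×16
  block-average resolution used downstream, but visible in raw bands).
* The GLCM quantizes over each image's own min–max range, making its
  statistics contrast-invariant but not comparable across images in
  absolute intensity terms.
* Training is single-threaded numpy; it is reproducible bit-for-bit for a
  fixed platform/BLAS but not guaranteed identical across different BLAS
  builds.
* The Otsu-based segmentation assumes one dominant textured lesion; faint
  multi-focal lesions would need a different binarization policy.
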