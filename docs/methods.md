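# Methods

This note documents the models, parameters, numerical choices and known
limitations of `mammoseg`. It is written for someone who wants to know
exactly what the package computes and why the defaults are what they are.

## Synthetic phantoms

`phantom.generate_phantom` renders a grayscale image in [0, 1] with:

* a **breast-shaped foreground**: a half-ellipse anchored to the left image
  edge (semi-axes 0.46·side vertically, 0.78·side horizontally) over a dark
  (0.02) background;
* **parenchymal texture**: three octaves of Gaussian-smoothed white noise
  (correlation lengths `texture_scale`, /4, /16; default 32 px) normalized
  to a combined standard deviation of 0.05, added to the mean foreground
  intensity (`background_level`, default 0.35);
* **lesions**: star-shaped blobs whose angular radius profile is
  `r(θ) = r0·(1 + Σ_k a_k cos((k+2)θ + φ_k))` with four harmonics of
  amplitude 0.04–0.12. `r0` is solved in closed form from the requested
  pixel area (area = ½∮r² dθ), so the rasterized mask lands within a few
  percent of the target (±15% is the contract). Intensity is added as a
  smoothed radial profile scaled by `lesion_contrast`, slightly feathered
  past the mask boundary so edges are low contrast; the binary mask records
  exactly the rasterized blob support.

Cohorts (`generate_cohort`) draw one lesion per image, with pixel areas
sampled uniformly per size category — small [60, 499], medium [500, 1500],
large [1501, 4500] — apportioned across categories by largest remainder so
realized counts match the requested mix exactly. When `reference_side` is
given, areas and categories are defined on that grid (typically the 224
model grid) and scaled by `(image_side/reference_side)²` for rendering, so
category bounds stated at model resolution drive a higher-resolution
phantom. Default per-category contrasts are 0.10/0.16/0.22 (small/medium/
large) against the 0.05 texture SD: subtle early lesions are both small and
faint in screening practice, and this coupling is what lets a trained model
reproduce a size-dependent detection gradient.

What the phantoms deliberately do **not** model: X-ray physics, pectoral
muscle, calcification clusters, multi-view geometry, annotation ambiguity.
Passing tests on phantoms therefore demonstrate that the *pipeline
machinery* behaves as specified — not that any particular accuracy carries
over to clinical mammograms.

## Preprocessing

Images are min–max normalized to [0, 1], then CLAHE is applied via
scikit-image with an 8×8 tile grid and clip limit 2.0 expressed in
multiples of the uniform histogram height (mapped to scikit-image's
normalized parameter as `2.0/256` with 256 bins; scikit-image quantizes
internally to 16 bits, so quantization error is ≤ 2⁻¹⁶). A constant image
maps to zeros with a warning rather than dividing by a zero range.

Masks are binarized with a **strict >** at threshold 0.5, which keeps
interpolation-induced exact-0.5 halos out of the lesion. Downsampling to
the 224×224 model input uses bilinear interpolation (area averaging is a
config option); masks are interpolated bilinearly and re-binarized at 0.5,
and the native-resolution lesion area is carried alongside the resized one.

Augmentation applies, each with independent probability 0.5: horizontal
flip; rotation of magnitude U[0, 10]° with random sign; zoom of magnitude
U[0, 12%] (in or out); elastic deformation (α=30, σ=6 at the 224 scale,
scaled proportionally at other resolutions); a lesion-preserving 90% crop
whose window is chosen to contain the lesion bounding box; and a randomized
re-application of CLAHE with clip limit U[1.0, 3.0] — the contrast-
enhancement augmentation distinct from the deterministic preprocessing
CLAHE. Image and mask receive identical geometric transforms; if a draw
nevertheless empties a non-empty mask, the draw is repeated (up to 8
times, then the input is returned unchanged), so lesion-preserving
augmentation never silently loses the lesion.

## Patch sampling

Positive patches are 224×224 crops centered on the lesion centroid plus
uniform jitter of ±25% of the patch side per axis, clamped to the image;
the jitter magnitude is a package choice ("small positional variance"), and
if extreme jitter pushes a tiny lesion out of the window the patch is
recentered exactly. Negatives are rejection-sampled (budget 100 attempts
each, 2 per positive) under two constraints: mask coverage strictly below
5%, and — by default — at least 50% of the window on the breast foreground
(intensity > 0.1), because all-black background windows are uninformative.
The patch dataset splits 80/20 **by source image** to prevent leakage.

The Stage-2 hybrid generator substitutes, independently per sample with
probability 0.35, a positive lesion patch for a full image. Patches are
extracted from preprocessed native-resolution images, so a 224×224 crop
already matches the model input and enters the batch directly.

## Network and training

The U-Net uses two 3×3 conv → batch-norm → ReLU layers per block (the
classic double-conv; the block conv count is a package choice), 2×2
max-pooling, dropout after each encoder pooling stage and after the
bottleneck (rate 0.3; bottleneck dropout is symmetric-by-choice and
configurable), transpose-convolution upsampling with skip concatenation,
and a 1×1 sigmoid head. Weights are He-uniform initialized from a config
seed; probabilities are clipped to [1e-6, 1−1e-6]. Encoder transfer copies
every encoder-block and bottleneck parameter (including batch-norm running
statistics) and leaves the decoder at its fresh initialization.

Forward and backward passes are exact analytic implementations in float32
NumPy; 3×3 convolutions run through numba-compiled direct kernels (with an
im2col fallback). Training uses Adam (default learning rate 1e-4), early
stopping (patience 10), learning-rate decay (×0.5 after 5 stale epochs) and
best-checkpoint selection, all monitored on validation Dice computed at
threshold 0.5 in inference mode (dropout off, batch-norm running
statistics). A minimum improvement of 1e-4 counts as progress. Batch size
defaults to 8. Tversky loss is computed per sample and averaged across the
batch; focal loss is a mean over all pixels.

The 60/20/20 cohort split accepts either fractions (largest-remainder
rounding) or explicit counts, because the published 159/55/55 partition of
269 cases does not follow any standard rounding of 60/20/20 and must be
reproducible as given.

## Evaluation

Detection is strict: IoU > 0.10. Category bounds assign 500 and 1500 px to
"medium" (small < 500 ≤ medium ≤ 1500 < large). Hausdorff distance is the
symmetric max of directed nearest-neighbor maxima between positive-pixel
coordinate sets (Euclidean, in pixels at the evaluation resolution) and is
*undefined* — excluded from aggregation, never zero — when either mask is
empty. Dice and IoU of two empty masks are defined as 1.0 (perfect
agreement on absence); this does not arise in abnormal-only cohorts but
makes the metrics total. Records carry the native-resolution mask area by
default (configurable to model-resolution).

Kruskal–Wallis uses the rank-sum H with tie correction and a χ² reference
with k−1 degrees of freedom; all-identical input returns (H=0, p=1) rather
than dividing by a zero tie term. The missed-vs-detected size comparison
uses a two-sided Mann–Whitney U (tie-corrected normal approximation with
continuity correction), with Welch's t reported as a secondary line; the
size–quality correlation is Pearson by default with Spearman as an option.
Detection rates are rounded to one decimal only at the reporting layer.

## Desk-scale pipeline

`pipeline.run_pipeline` reproduces the protocol end-to-end at desk scale:
64 phantoms at 512 px (40/16/8 small/medium/large with areas defined on the
224 grid), category-stratified 60/20/20 split (so each size category is
represented in every split, as in the published test cohort), reduced
U-Net (8/16/32 encoder filters, 64-filter bottleneck — full-scale topology,
~121k parameters), up to 30 epochs per stage (early stopping active) with
learning rates 3e-3 (Stage 1) and 1e-3 (Stage 2). The larger-than-default
learning rates are the appropriate setting for a network and dataset this
small; 1e-4 remains the full-scale default. These problem sizes keep a
complete run around ten minutes on one CPU.

Stage-2 batches are re-augmented every epoch with the *geometric-only*
subset (flips, rotation, zoom). The destructive transforms — elastic
deformation, contrast jitter, cropping — measurably hurt at this scale:
after downsampling, small-category lesions span only a few pixels, and
elastic warping plus mask re-binarization can erase them from the target
outright, teaching the network to ignore exactly the lesions the hybrid
sampler is trying to preserve. The full augmentation list remains available
(`AugmentConfig`, and `augment: full` in the CLI).

## Known limitations

* Phantom realism is intentionally limited (see above); absolute metric
  values on phantoms say nothing about clinical performance.
* The NumPy/numba engine is single-threaded and CPU-bound; it is meant for
  desk-scale experiments and testing, not full-resolution training.
* Hybrid substitution draws only positive patches; negative patches are
  used in Stage 1 only.
* Only one lesion per image is generated by default; multi-lesion images
  are supported by the generator but per-lesion matching in evaluation is
  not implemented (records are per-image).
* The focal/Tversky parameters and their unit mixing weights are standard
  defaults, exposed in `LossConfig`; no claim is made that they are optimal.
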