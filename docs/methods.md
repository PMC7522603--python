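# Methods

## Problem and model

`virtualstain` performs paired image-to-image regression for microscopy: given
one or more co-registered grayscale channels `I` (phase contrast or
fluorescence), predict a target fluorescence channel `Φ`.  The same machinery
covers autofocusing, where the input is a defocused fluorescence plane and the
target is the in-focus plane of the same z-stack.

The regressor is a conditional GAN.  The generator G is a U-Net-style
encoder–decoder: an initial stride-2 convolution (kernel 3), encoder blocks
`LeakyReLU → Conv(s2) → BatchNorm`, decoder blocks
`ReLU → ConvTranspose(s2) → BatchNorm` with skip connections between
same-resolution encoder/decoder levels, and a final Tanh so outputs live in
[−1, 1].  The discriminator D scores a candidate image concatenated with G's
conditioning input: a stride-2 convolution (kernel 5) plus BatchNorm, three
`Conv(s2) → BatchNorm → LeakyReLU` blocks, one fully connected layer and a
sigmoid.  G minimizes

    l = λ1·l_MAE + λ2·l_G + λ3·‖θ_G‖₁

with `l_MAE` the per-pixel mean absolute difference between `Φ` and `G(I)`
(the L1 norm of the residual divided by the W×H patch area),
`l_G = −log D(I, G(I))`, and the L1 norm of all generator parameters as the
regularizer; default weights (0.99, 0.01, 0.001).  D minimizes binary
cross-entropy with real = 1 and predicted = 0 on the conditional pair.  Both
networks use the adaptive-momentum (Adam) optimizer, default learning rate
2×10⁻⁴, and training alternates one D step with one G step per mini-batch.
Images are preprocessed by a linear map of the dtype full scale
`[0, 2^bit_depth − 1]` to [−1, 1]; predictions are inversely mapped and
rounded back to integer levels.  The dtype scale (not the per-image maximum)
is used so intensities stay comparable across fields of view.

Because no GPU deep-learning framework is part of this package's dependency
set, the layers (strided convolution, its exact adjoint as the transposed
convolution, batch normalization, dense, activations) and Adam are
implemented in numpy with explicit backpropagation (`nn.py`).  Gradients of
every layer are verified against finite differences in the test suite, and
the transposed convolution is verified to be the exact adjoint of the
convolution (`⟨conv(x), z⟩ = ⟨x, convᵀ(z)⟩`).  Everything is seeded and
CPU-deterministic: two runs with the same configuration produce bit-identical
loss histories.

## Tolerance-level error index

Fluorescence intensities are only semi-quantitative (photobleaching,
illumination, camera settings), so small intensity mismatches rarely change
biological interpretation, while signal predicted where there is none (or
missing where there is) does.  The absolute error map is therefore scanned
over thresholds `i` = 0..99 % of the bit-depth range and split into

* `IE(i)` — mean |pred − truth| over the pixels whose error ≤ the threshold,
  normalized by the full scale (0 if no pixel qualifies), and
* `SE(i)` — the area fraction of pixels whose error > the threshold.

The tolerance level is `TL = min_i [β1·IE(i) + β2·SE(i)]`, with equal default
weights β1 = β2 = 0.5 so TL ∈ [0, 1]; ties break toward the smallest
threshold (the stricter tolerance).  `IE` averages only over sub-threshold
pixels by default — the literal reading of "MAE below the threshold level";
a `clipped_variant` flag instead averages the threshold-clipped error over
all pixels, which is monotone in the threshold and comparable across
thresholds.  SE is non-increasing in the threshold by construction, giving
`0 ≤ TL ≤ β1 + β2`.  MAE, PSNR (`20·log₁₀(full/RMSE)`, +∞ for identical
images) and SSIM (11-px Gaussian window, σ = 1.5, K1 = 0.01, K2 = 0.03;
delegated to scikit-image and cross-checked in the tests against a direct
windowed-formula implementation) complete the metric set.

## Dataset construction

Training samples are square patches (128 or 256 px for production-scale
images; 32 px in the scaled studies below) cropped at random offsets drawn
uniformly over all positions where the patch fits; input and target are cut
at identical coordinates.  Augmentation applies one dihedral transform
(rot90/180/270, horizontal/vertical flip) identically to all channels.  The
validation split (default 20 %) is made at the whole-image level so
overlapping patches never leak between train and validation; the best
checkpoint is the parameter snapshot at the minimal validation loss.

Autofocus pairs come from z-stacks with uniform slice spacing: every slice
with `min_abs_z < |z − z_focus| ≤ max_abs_z` becomes an input paired with the
repeated in-focus slice.  The band is lower-exclusive/upper-inclusive, so a
[2, 10] µm band on a 2-µm stack yields the offsets {±4, ±6, ±8, ±10} — eight
defocused planes per stack, matching the geometry of a 32-slice, 2-µm
acquisition.

Full fields of view are predicted by overlapped tiling: origins advance by
`tile − overlap`, the last tile snaps to the border, and per-tile alpha
weights ramp linearly from (near) zero at the tile edge to one at half the
overlap, renormalized pixelwise so the weights form an exact partition of
unity.  Stitching tiles cut from an image without a model reconstructs it to
floating-point rounding.

## Synthetic scenes

The fixture generator renders four co-registered channels per scene —
`nuclei` (soft-edged filled ellipses), `fibers` (anti-aliased line segments
radiating from each cell, ending in a brighter Gaussian plaque tip, emulating
the actin-density maxima at focal adhesions), `puncta` (2-D Gaussian spots,
σ = 1.6 px), and `membrane` (elliptical rings) — plus additive Gaussian
noise clipped to the bit range and a constant background.  The key control is
`puncta_coupling ∈ [0, 1]`: each fiber contributes one punctum, placed
exactly at that fiber's terminus with probability `puncta_coupling` and
uniformly at random otherwise.  At coupling 1 the puncta channel is a
deterministic local function of the fibers channel (the paired-channel
regime where virtual staining is expected to work); at coupling 0 the two
channels share no spatial information beyond their marginals.  Scene
generation is a pure function of its parameters including the seed.
Defocus is modeled as an isotropic Gaussian PSF with σ =
`psf_sigma_per_micron · |z|` (default 0.25 px/µm) and reflective boundaries;
z = 0 returns the input unchanged and interior photon counts are conserved
to integer rounding.

What the generator does not emulate: diffraction-limited or vectorial PSFs,
Poisson shot noise, photobleaching, illumination gradients, or the
morphological diversity of real cells.  Tests passing on these scenes
demonstrate that the pipeline's mechanics (losses, optimization, tiling,
metrics) behave as specified and that learnability tracks structural
coupling; they do not certify prediction quality on any real dataset.

## Scaled study conditions

The package's self-contained studies (test suite and `scripts/acceptance.py`)
run on 1 CPU in minutes, so they use deliberately small problem sizes:
ten 96×96 scenes (eight train, two validation), 12 patches of 32×32 per
scene, a depth-3 generator with base width 16 (bottleneck 4×4), a
discriminator with base width 8, batch size 8, and ≈480 optimizer steps.  At
this step budget the Adam step size is set to 5×10⁻³; the 2×10⁻⁴ default is
retained for production-scale training runs.  Under these conditions the
coupled fiber→puncta model beats the best constant-image predictor (the
pixel median of the held-out targets, the MAE-optimal constant) by ≈60 %
relative MAE, while the uncoupled control does not beat it at all — the
structural-correlation contrast the method predicts.  The autofocus variant
trained on the ±10 µm band (excluding ±2 µm) sharpens essentially all
held-out defocused patches, measured by variance of the Laplacian.

## Numerical choices and edge cases

* Convolutions use SAME padding with output size ⌈n/s⌉; the transposed
  convolution is the exact adjoint, so stride 2 doubles the spatial size and
  requires patch sizes divisible by 2^depth.
* BatchNorm keeps running statistics (momentum 0.9) and uses them at
  inference, so single-image prediction is deterministic.
* Discriminator outputs are clipped to (1e−7, 1 − 1e−7) before logs.
* Non-finite training or validation losses abort with a
  `TrainingDivergedError` carrying the history recorded so far.
* Histogram equalization (optional contrast step for low-contrast datasets)
  is the classic integer-CDF remap, applied before normalization; constant
  images are returned unchanged, and the remap never inverts the rank order
  of distinct values.
* PSNR of identical images returns +∞ rather than raising, since
  self-comparison occurs legitimately in calibration runs.
* Tolerance-level ties break to the smallest threshold; the scan grid is
  integer percents 0–99 by default and fully configurable.

## Known limitations

The CPU backbone is not performance-competitive with GPU frameworks and is
intended for method development, testing, and small studies.  The
discriminator's fully connected head fixes the patch size at build time.
Only grayscale 8/16-bit TIFF and 8-bit PNG are supported; channels must
already be co-registered.  The defocus model is a Gaussian blur, which
ignores the sign of z (no asymmetric aberrations), so the autofocus variant
cannot distinguish above-focus from below-focus inputs.
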