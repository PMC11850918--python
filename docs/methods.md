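# Methods

This note documents the models, algorithms and numerical choices behind
`uitrans`: a volumetric restoration network for light-sheet fluorescence
microscopy (LSFM), the synthetic degradation model used to exercise it,
and the surrounding preprocessing, evaluation and 4D-reconstruction
machinery.

## The restoration problem

In vivo LSFM of a beating zebrafish heart forces acquisitions down to
milliseconds of exposure at ~0.1 mW, producing volumes that are
photon-starved (SNR in the mid-single digits, dB) and contaminated by a
long-range scattering haze that more light cannot remove. Line-confocal
LSFM (synchronizing a scanned excitation line with the camera's rolling
shutter) rejects much of the scattered light and, at a ~3000x higher
light dose, yields clean volumes — but only on fixed, optically cleared
samples. The restoration network learns the mapping from economical
conventional-LSFM volumes to line-confocal-quality volumes and is then
applied to live acquisitions.

## Network

The network (`uitrans.model.UITransNet`) is a hierarchical
encoder-decoder that maps a single-channel volume to a restored volume
of the same size.

**Dual-branch encoder.** Each of the (default 3) stages runs two
parallel branches on the same input and concatenates their outputs along
channels after stride-2 downsampling: a *convolutional branch* (two
3x3x3 convolutions + LeakyReLU) for local detail, and a *transformer
branch* for global context. The stage output width is `base_channels *
2**(i+1)`; each branch contributes half (the full width if the other
branch is disabled for ablation), so the decoder is ablation-agnostic.
The concatenated per-stage map is both the skip connection and the next
stage's input; a double convolution on the last stage output forms the
bottleneck (8^3 for a 64^3 input at 3 stages).

**Transformer block.** Two parallel multi-headed self-attention (MSA)
modules whose outputs are concatenated (doubling channels to match the
conv branch). Each MSA tokenizes the volume by *interval extraction*:
stride-`s` interleaved sub-sampling (space-to-channel rearrangement,
`s = token_stride` per axis) followed by a linear projection, so every
token samples the entire field of view rather than a local patch. The
token sequence passes through LayerNorm -> multi-head attention ->
LayerNorm -> MLP with two residual connections, is projected back and
re-interleaved to the input spatial size. No positional encoding is used
by default (a learned embedding is available behind a config flag).
Because full attention is quadratic in token count, keys/values are
average-pooled onto a coarser token grid when the grid exceeds
`max_tokens_per_axis` (default 8) per axis; queries stay at full
resolution, so the output remains per-token and attention rows still sum
to one. The two MSAs are identical twins with independent parameters.

**Decoder.** U-type: trilinear 2x upsampling + convolution,
concatenation with the corresponding encoder skip, double convolution;
finished by a 1x1x1 convolution to one channel (optional clamp to [0,1]
at inference). Strided convolutions downsample and interpolation +
convolution upsample — the factor-2 is fixed, the operators avoid
pooling aliasing and checkerboard artifacts respectively.

**Initialization.** Kaiming-uniform for convolutions, truncated normal
(sigma 0.02) for attention/MLP weights, all drawn from one seeded
generator, so a (config, seed) pair reproduces parameters bit-for-bit.

**Width defaults.** The published description fixes the topology but not
the widths. Defaults: `base_channels=16`, `embed_dim=32`, `n_heads=4`,
`mlp_ratio=2`, `token_stride=2`. The desk-scale preset used by the test
and benchmark suites (`UITransConfig.small()`): `base_channels=8`,
`embed_dim=16`, `token_stride=4` (~0.7 M parameters), sized so the full
acceptance pipeline trains in minutes on one CPU core.

## Numerical stack

No GPU framework is assumed: the package ships a compact reverse-mode
autodiff engine on numpy (`uitrans.nn.autograd`) with exactly the
operators the network needs — broadcast arithmetic, batched matmul, 3D
convolution via im2col (JIT-compiled patch extraction/accumulation with
numba when available, pure numpy otherwise), trilinear upsampling,
softmax, LayerNorm and GELU/LeakyReLU — plus an ADAM optimizer. Every
primitive's gradient is verified against central finite differences in
the test suite, and the JIT and numpy convolution paths are checked
against each other. All tensors are float32; metric computations are
float64.

## Training objective

The loss is a weighted sum of a voxelwise term and a structural term:

    L_total = L_MAE + lambda * L_perc,    lambda = 0.01

`L_MAE` is the mean absolute voxel error over the volume. `L_perc` cuts
the volumes into 2D z-slices (the imaging planes), feeds each slice —
replicated to three channels — through a frozen VGG-style 2D
convolutional pyramid, and averages the mean-squared feature distance at
three taps over slices and taps. The extractor is a *fixed, seeded,
randomly initialized* pyramid by default: random frozen convolutional
features preserve the structural-similarity role of a perceptual loss
while keeping the package deterministic and free of downloaded weights;
a hook accepts externally supplied pretrained weights. Which layers and
which distance to use are configurable since no canonical choice exists.

Training uses ADAM (beta1 0.9, beta2 0.999). Learning rate, batch size
and epoch count are engineering choices: defaults `1e-4`, the desk-scale
schedule (`TrainConfig.desk_scale()`) uses a constant `2e-3`, batch 2,
8 epochs. Datasets are split 9:1 into train/validation with a seeded
permutation; the checkpoint with the best validation loss is kept.
Intensities are normalized per volume by percentile scaling (0.1th -> 0,
99.9th -> 1, clipped), which is robust to the haze-offset difference
between the two acquisition modes; the normalization is recorded in the
checkpoint. No data augmentation is applied by default.

## Synthetic data generator

Real paired acquisitions are not distributable with the package, so all
tests run on a parametric simulator that emulates the acquisition:

* **Phantom** — two overlapping ellipsoidal Gaussian shells ("ventricle"
  and "atrium", wall width 0.08 in normalized radius, peak intensity
  0.85) with multiplicative band-limited speckle (Gaussian-filtered
  seeded noise, sigma 1.5 voxels, 35% contrast) emulating cell-scale
  texture on the thin myocardial wall. Default sampling 0.325 um/voxel.
* **PSF** — separable anisotropic Gaussian blur; lateral/axial FWHM
  0.98/4 um converted to sigma via sigma = FWHM/2.355.
* **Scattering haze** — `v + confocal_rejection * haze_strength *
  (v * K) + offset`, with K a wide normalized Gaussian (sigma 10 um >>
  PSF): additive, long-range and signal-correlated.
  `confocal_rejection` is 1 for conventional LSFM and ~0.05 for the
  line-confocal ground-truth mode. No depth-dependent haze scaling is
  applied. The haze model is a stand-in — the scattering of real tissue
  is not quantitatively calibrated here.
* **Noise** — Poisson photon noise at `photon_gain` expected photons per
  unit intensity, plus Gaussian read noise (the standard sCMOS
  photon-limited model).
* **Boundaries** — all simulator convolutions use reflect padding to
  avoid dark edges in small volumes.

The default *economy input* mode (gain 20 photons, read sigma 0.025,
full haze, offset 0.05) and *quality ground-truth* mode (gain 60000 —
the 3000x dose ratio of the two acquisition settings — rejection 0.05,
read sigma 0.005) produce pairs with input SNR ~6 dB and ground-truth
SNR ~16 dB under the package's SNR definition, matching the acquisition
regimes the method targets.

**Beating sequences** re-evaluate the phantom geometry at a
phase-dependent radial scale `1 + A * w(2*pi*p/P)`, where `w` is a
normalized two-harmonic pulse `sin(theta) + 0.5*sin(2*theta)`. The
second harmonic is essential: a pure sinusoid makes the motion
mirror-symmetric in phase (frames at p and P/2 - p are identical), so no
synchronization algorithm could identify the phase. Default amplitude
0.1 (peak radial dilation 10%), enough to move the wall 1-2 voxels on
the desk-scale grids. Frames are exactly periodic by construction.

**What the simulator does not capture:** refractive-index
inhomogeneity, depth- and direction-dependent scattering, motion blur
within a frame, fixed-pattern camera noise, photobleaching and true
anatomical variability. Passing the synthetic suites therefore
demonstrates that the implementation is correct and the pipeline
recovers what it degrades — not that restored intensities from real
tissue are quantitatively faithful; the network is in any case not meant
for intensity-based quantification.

## Preprocessing

Paired acquisitions are registered by exhaustive integer-translation
search (all shifts up to `max_shift` in all three directions jointly)
maximizing the Pearson correlation on the overlap only — no sub-voxel
interpolation, matching pixel-level alignment of same-stage
acquisitions. Ties break toward the smallest shift magnitude, then
lexicographically. Above `max_shift = 8` a coarse-to-fine search
(2x-downsampled prescan, local +-2 refinement) is used purely for speed.
An axis-by-axis search is not used; the joint search is exact.

## Evaluation metrics

NRMSE (RMSE normalized by the *reference range*), Pearson correlation,
PSNR (data range 1.0 after normalization; capped at 200 dB for identical
volumes, flagged), SSIM (per z-slice, Gaussian window sigma 1.5,
K1=0.01, K2=0.03, averaged over slices). SNR and contrast lack one
canonical formula in the literature, so the package fixes:

    SNR [dB] = 10 log10((mu_fg - mu_bg)^2 / sigma_bg^2)
    contrast = (mu_fg - mu_bg) / (mu_fg + mu_bg)          (Michelson)
    contrast enhancement = contrast(test) / contrast(input)

with foreground/background masks from Otsu thresholding of the
ground-truth volume (user-supplied masks accepted), so input, restored
and GT are scored over identical regions. Acquisition-economy ratios
multiply laser power x exposure x planes (dose) and exposure x planes
(time).

## Tiled inference

Volumes of arbitrary size are restored by mosaicking overlapping tiles
(tile dims divisible by `2**n_stages`; reflect padding when the volume
is smaller than a tile). Tiles are blended with a separable
tapered-cosine window — flat in the interior, cosine ramps across the
overlap — and the accumulated weights are normalized per voxel, so the
effective blending weights sum to exactly one everywhere.

## 4D synchronization

Per-slice movies (one long time series per z-plane) are phase-aligned
post hoc. The heartbeat period is the dominant non-zero-lag peak of the
autocorrelation of the mean-intensity trace within an automatically
selected high-variance region, refined by parabolic interpolation and
rounded; a peak must exceed `max(0.1, 4/sqrt(T))` (the white-noise
envelope) or the signal is declared aperiodic. Phase offsets are chained
between adjacent slices: each movie is folded into a per-pixel average
cycle, and the neighbor's offset is the circular shift maximizing the
image correlation of the folded cycles — images, not scalar traces,
because a scalar intensity trace can frequency-double under symmetric
wall motion, making offsets ambiguous modulo half a period. Chaining
starts at the slice with the strongest beating signal and proceeds
outward, so near-empty edge slices cannot corrupt downstream links;
links with correlation below 0.2 propagate the previous offset with a
warning. Phase binning is nearest-frame (no temporal interpolation).
Offsets are defined up to a global gauge — adding a constant to all
offsets cyclically rotates the reconstructed phase volumes and nothing
else. Restoration is applied per reconstructed volume after
synchronization, not per 2D frame.

## Desk-scale study conditions

All quantitative suites run on one CPU core within minutes, using: 40
synthetic pairs at 32^3 (split 36/4), the `small()` network preset, the
desk-scale schedule (8 epochs, 144 steps); the single-pair overfit run
uses at most 500 steps; shift recovery uses 50 phantoms at 24^3 with
|shift| <= 4; synchronization uses 20 slices of a 20x32x32 beating
phantom, period 20, 60 frames, plus a 1000-frame trace for period
estimation. Under these conditions the pipeline typically takes the
median validation SNR from ~6 dB to ~15 dB, reduces median NRMSE to
~0.3x the input's, improves Pearson correlation on every validation
volume, recovers all injected shifts exactly, and recovers the period
and >= 95% of phase offsets within one frame (see
`scripts/acceptance.py`, which recomputes all of these from scratch).

## Known limitations

* The paper-scale regime (400 pairs at 256^3, pretrained-VGG perceptual
  loss) is supported by the same code paths but is not exercised by the
  test suite; quantitative parity with results measured on real
  zebrafish acquisitions is not claimed and not verifiable without the
  original data.
* The haze model is analytically convenient rather than tissue-calibrated.
* Attention uses pooled keys/values above the token-grid cap; exact
  full attention at large volumes is configurable but quadratic.
* The synchronization realization (intensity-cycle chaining) is one
  reasonable implementation of post-acquisition phase alignment; other
  realizations may differ in detail.
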