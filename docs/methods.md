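# Methods

This note records the models, conventions and design choices behind the
package, in the order data flows through the pipeline.

## Synthetic phantom

The generator (`esdm.phantom`) emulates an N-repetition oral-OCT B-frame
stack over a two-layer tissue:

* **Geometry.** Per frame, the air–epithelium surface and the
  epithelium–stroma boundary are smooth curves: unit-variance Gaussian
  noise low-pass filtered along the transverse axis with correlation
  length `boundary_smoothness` (default 40 px), scaled by
  `boundary_amplitude` (default 6 px) around `surface_depth_mean` (40 px)
  and `epithelium_thickness_mean` (45 px). Curves share a common
  component across frames plus a slow per-frame drift (`frame_drift`,
  default 0.2 of the amplitude, smoothed over frames), so consecutive
  frames look like consecutive B-scans of one volume. Boundaries are
  rounded half-up to integer rows; masks (0 background, 1 epithelium,
  2 stroma) and the stored boundary curves are exactly consistent.
* **Reflectivity.** Noise-free intensity is per-class mean backscatter —
  0.35 (epithelium) and 0.55 (stroma), epithelium darker than stroma as
  in oral OCT — times exponential decay with the cumulative attenuation
  along the A-line (0.002/px in epithelium, 0.004/px in stroma), plus a
  0.03 noise floor. The default epithelium thickness of 45 px corresponds
  to ~280 µm at the 6.27 µm/px tissue pitch, a typical healthy value.
* **Speckle.** Each repetition multiplies the noise-free image by an
  independent, per-pixel, unit-mean gamma field with shape k
  (`speckle_shape`, default 4, i.e. speckle contrast 0.5 — partially
  developed/processed speckle; k = 1 would be fully developed intensity
  speckle, `inf` disables noise). Unit mean makes the repetition average
  unbiased, and the variance of the NR-mean is `I²/(k·NR)`: the 1/NR
  averaging law the denoising target relies on, verified by Monte Carlo
  in the tests. Values are clipped to [0, 1]; tests of the variance law
  use dim phantoms so clipping is negligible.

What the phantom does **not** model: coherent point-spread functions and
spatially correlated speckle grain, refraction, shadowing, motion
artifacts, and the intensity statistics of any particular scanner
(no public data exists to calibrate them). Passing tests therefore
demonstrate that the pipeline's machinery is correct and learnable-from,
not that clinical performance is reproduced.

## Pair construction

The denoising target is the arithmetic per-frame mean over repetitions;
the input is repetition 1. Crop boxes are 256 × 256, half-open 0-based
transverse windows at {0, 144} for 400-px (intraoral-lens) frames and
{0, 256, 344} for 600-px (LSM03) frames, anchored at the image top
axially. The first frame of each volume carries the manual mask; later
frames carry teacher pseudo-labels. Since no pre-trained teacher ships
with the package, the default teacher is a *corrupting oracle*: it
displaces both boundary curves by smooth seeded noise of scale `jitter`
(default 2 px), rebuilds the mask, and resamples each pixel's label
uniformly with probability `flip_rate` (default 1 %). An
`external-model` mode delegates to any callable and validates its
output. Masks are encoded as soft labels: 0.95 on the annotated class,
the remaining 0.05 spread uniformly — the loss is then tolerant of
pseudo-label error. Train/validation/test splits are by volume, seeded.

## Network

Defaults: filter sizes {32, 64, 128, 256, 256}, SCT counts {1, 2, 2},
heads {4, 8, 8}, input 256 × 256 × 1, three classes.

* **Encoder.** Stages 1–2 are convolution blocks (3×3 stride-2 conv +
  norm + GeLU, then a 3×3 refining conv + norm + GeLU). Stages 3–5 are a
  strided 3×3 downsampling conv (+ norm + GeLU) followed by the stage's
  SCT blocks. Stem and downsampling convolutions use **instance
  normalisation** (per-channel spatial statistics, affine): at stem
  widths of 8–32 channels, normalising across channels per pixel would
  discard absolute-intensity information that both tasks need, whereas
  instance norm preserves each channel's spatial contrast.
* **SCT block.** Pre-norm residuals (channel-wise layer norm):
  `x + Attn(LN(x))` then `x + FFN(LN(x))`. Attention sequences come from
  1×1 conv + 3×3 depthwise conv per Q/K/V; heads split the channel axis
  (the standard multi-head contract), scaling by √(C/heads); the output
  projection is a C-unit linear layer. The FFN is
  `PW(4C) → DW 3×3 → GeLU → PW(C)`.
* **Denoising decoder.** Five stride-2 3×3 deconvolutions back to full
  resolution (channel path 256→256→128→64→32), each followed by GeLU and
  refining 3×3 convs — one at the three deep stages, two at the two
  shallow stages, mirroring the two-conv stems. Encoder skips from
  stages 1–4 are fused after upsampling: SE gate (reduction 8) →
  depthwise 3×3 → 1×1 projection to the decoder width → addition. The
  decoder is normalisation-free (restoration-decoder practice). Output
  head: 3×3 conv block then a 3×3 conv to one channel; outputs are
  clipped to [0, 1] at inference only.
* **Segmentation decoder.** Channel-LN on the bottleneck, a linear
  projection to the stage-3 width (128), then four ×2 bilinear
  upsamplings each followed by a linear decoder block
  `LP(C/2) → LN → GeLU → LP(C)`. Encoder features of stages 3, 2 and 1
  are added into the cascade at their native resolutions, entirely
  parameter-free — stage 3 matches the working width; narrower stages
  are zero-padded along channels (the classic parameter-free shortcut).
  The 3-class 3×3 head predicts at half resolution and the logits are
  bilinearly upsampled ×2; interpolating decisions rather than features
  suppresses per-pixel speckle flicker in the masks.
* **Upsampling grid.** All bilinear upsamplings use the `src = j/2`
  mapping, whose even outputs coincide with input samples. Stride-2
  convolutions sample at even pixel coordinates, so this convention
  keeps fused skip features registered with the cascade across scales;
  the usual cell-centred convention would accumulate a half-cell offset
  per scale.
* **Initialisation.** He-normal for convolutions, Glorot for linear
  projections, zero biases, and *identity initialisation* of everything
  additive: the residual-branch output layers (attention out-projection,
  FFN's second pointwise conv), the skip-fusion projections and both
  task heads start at zero weights. The network therefore begins as a
  near-identity map whose branches switch on smoothly — at desk-scale
  step budgets this roughly halved the loss reached in ten epochs, and
  it is free: parameter counts are untouched.

Ablation switches (`enable_denoise_decoder`, `enable_seg_decoder`,
`use_skip`, `use_se`) and filter-size scaling reproduce the reference
complexity table's seven variants from configuration alone; the
architecture above was fixed by reconciling exact parameter counts
against those printed figures (worst deviation 0.31 %), with the
component additivity `params(multi) = params(reconstruction-only) +
params(segmentation decoder)` holding exactly. FLOPs are reported
analytically from convolution/matmul multiply-accumulates under the
documented convention 1 MAC = 2 FLOPs.

## Losses and training

`L_D = α·Σ(I−Î)² + β·Σ(φ(I)−φ(Î))²` with α = 1, β = 0.01, sums (not
means) over pixels and feature elements per sample, batch-averaged —
keeping the calibrated α/β balance. The feature extractor φ is
pluggable: callers may supply pretrained perceptual weights; the default
is a fixed-seed two-layer random convolutional surrogate (deterministic,
no download, still measures feature-space discrepancy); `off`/β = 0
gives plain MSE. `L_seg` is soft-label cross-entropy, mean over pixels,
logs clamped at 1e−12, probabilities from a softmax over the K-logit
head (normalisation is the loss's responsibility). `L_c = L_D + L_seg`
with no extra weights.

Training uses Adam (lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-7 — the
TensorFlow-style default), batch 16, 200 epochs by default; after each
epoch the validation combined loss is computed and the best-so-far
weights are kept (checkpoint selection). Runs are bit-reproducible from
the manifest: data order, initialisation and the loss surrogate all
derive from recorded seeds. All computation is float32; scalar
constants use NumPy's weak-promotion path so graphs never silently
upcast.

## Metrics

PSNR uses `i_max = 1` on normalised images (MSE = 0 reported as +inf and
excluded from aggregation). SSIM defaults to the conventional windowed
form — 11 × 11 Gaussian window (σ = 1.5, truncate 3.5), k₁ = 0.01,
k₂ = 0.03, border of one window radius cropped — with the whole-image
("global") single-statistic form also exposed; both are tested against
a direct sliding-window oracle. mDice and mIoU average per-class scores
over the K classes; a class absent from both masks contributes 1
(perfect-agreement convention), keeping toy cases defined. Dataset
aggregation is mean ± sample standard deviation (ddof 1; a single image
reports std 0).

## Thickness

Per A-line the epithelium pixel count is the **longest contiguous run**
of label 1 — robust to isolated flipped pixels in predicted or pseudo
masks; runs shorter than `min_run` (default 1, i.e. no filtering) are
marked missing and excluded from frame statistics. Thickness is
`N_pixel × axial_coeff_air / refractive_index` (defaults 8.74 µm/px and
1.395 → ≈ 6.27 µm/px). Frame-level comparison takes the absolute
difference of frame-mean thicknesses, aggregated mean ± std across
frames — the desk-scale analogue of per-region clinical reporting.

## Desk-scale problem sizes

The packaged experiments are sized for a single CPU: phantoms of
64 × 64 (geometry scaled accordingly: surface 12 px, epithelium 14 px,
amplitude 3 px, smoothness 10 px), ~200 training pairs drawn as 100
volumes × 2 frames (volume diversity, not step count, limits
generalisation at this scale), a reduced model (filters
{8, 16, 32, 64, 64}, one SCT block and two heads per stage), ten
epochs. Monte-Carlo checks of the speckle law use ≥ 10⁴ stroma pixels.

## Known limitations

* Per-pixel independent speckle is statistically milder than correlated
  speckle grain; real-scanner performance cannot be inferred from
  phantom scores.
* The corrupting-oracle teacher has zero-mean boundary error; a real
  pre-trained teacher may be biased, which frame-1 manual labels only
  partly correct.
* The FLOPs report covers convolution/linear/attention
  multiply-accumulates only (norms, activations and elementwise ops are
  excluded), and conventions differ across published counters.
* Training is single-device float32 without mixed precision; wall-clock
  performance is bounded by NumPy's single-threaded convolution lowering.
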