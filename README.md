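# esdm-oct

Multi-task deep learning for **oral optical coherence tomography (OCT)**:
a single encoder–decoder network that simultaneously **denoises**
single-repetition B-frames and **segments** the oral epithelium and stroma,
plus the full surrounding pipeline — frame-averaged denoising targets,
pseudo-label semi-supervision, combined loss, image-quality and
segmentation metrics, and epithelium-thickness quantification.

OCT can assess oral mucosa non-invasively, but speckle noise degrades
single-scan images, and averaging repeated scans (the usual remedy)
multiplies acquisition time and motion artifacts. The model here — an
Efficient Segmentation-Denoising Model (ESDM) — learns to map one noisy
repetition to the quality of a multi-repetition average while also
delineating the epithelium/stroma boundary, whose depth (epithelium
thickness) is a clinical marker for lesion assessment.

Because clinical oral-OCT volumes are not publicly available, the package
ships a first-class **synthetic phantom generator**: two-layer tissue with
smooth seeded boundaries, per-layer exponential depth attenuation, and
independent unit-mean gamma speckle per repetition. Every stage of the
pipeline is tested end-to-end against these phantoms.

## The model

* **Shared encoder**, five stages: two strided convolution blocks, then
  three separable-convolutional-transformer (SCT) stages. An SCT layer
  builds the attention sequences by pointwise + depthwise convolution,

  `Q, K, V = flatten(DW₃ₓ₃(Conv₁ₓ₁(x)))`,

  applies multi-head self-attention `Softmax(QKᵀ/√d)V` with channel-split
  heads, and each SCT block pairs that with a depthwise feed-forward
  network `PW₂(GeLU(DW(PW₁(·))))` (4× expansion) under pre-norm residuals.
* **Denoising decoder**: five stride-2 deconvolution stages with
  squeeze-and-excitation-gated encoder skips fused through a
  depthwise-separable projection; normalisation-free, as is common in
  image-restoration decoders.
* **Segmentation decoder**: a lightweight cascade of bilinear upsamplings
  and per-pixel linear decoder blocks `LP₂(GeLU(LN(LP₁(x))))`, with
  parameter-free multi-scale fusion of encoder features.
* **Loss**: `L_c = L_D + L_seg` with
  `L_D = α·Σ(I−Î)² + β·Σ(φ(I)−φ(Î))²` (α=1, β=0.01; φ a pluggable feature
  extractor) and soft-label cross-entropy for segmentation (confidence
  0.95 on the annotated class).
* **Thickness**: per A-line, `thickness = N_pixel × (8.74 µm / 1.395)`
  — the axial pixel pitch in air divided by the tissue refractive index,
  ≈ 6.27 µm/pixel.

The network, its reverse-mode differentiation and the Adam optimiser are
implemented in NumPy (`esdm._autodiff`, `esdm.nn`) — a compact,
fully-tested engine purpose-built for this model family, with gradients
validated against finite differences.

## Worked example

Build the default multi-task model and inspect its complexity:

```python
from esdm import ModelConfig, build_model, count_parameters

report = count_parameters(build_model(ModelConfig()))
print(report.parameters_m, report.breakdown)
```

```
7.701 {'encoder': 4463712, 'denoise_decoder': 3133437, 'seg_decoder': 103683}
```

7.701 M trainable parameters for the default configuration (filter sizes
{32, 64, 128, 256, 256}, SCT counts {1, 2, 2}, heads {4, 8, 8}); the
segmentation decoder adds only 0.104 M on top of the reconstruction-only
model.

Train a reduced model on synthetic phantoms at desk scale (this is the
packaged smoke experiment; ~90 s on one CPU):

```python
import numpy as np
from esdm.esdm_net import ModelConfig, SMOKE_FILTERS
from esdm.phantom import PhantomConfig, generate_phantom
from esdm.preprocess import CropSpec, TeacherOracle, make_dataset
from esdm.pipeline import TrainConfig, train
from esdm.metrics import psnr, confusion, mdice

def phantom(seed):
    return generate_phantom(PhantomConfig(
        width=64, depth=64, n_frames=2, n_repetitions=4,
        surface_depth_mean=12, epithelium_thickness_mean=14,
        boundary_amplitude=3, boundary_smoothness=10, seed=seed))

spec = CropSpec(64, 64, (0,))
vols = [(f"v{i}", *phantom(i)) for i in range(100)]
ds = make_dataset(vols, spec, TeacherOracle(jitter=2.0, flip_rate=0.01,
                                            seed=99),
                  split=(0.88, 0.12, 0.0), seed=0)
cfg = ModelConfig(filter_sizes=SMOKE_FILTERS, sct_counts=(1, 1, 1),
                  heads=(2, 2, 2), input_shape=(64, 64, 1), seed=0)
model, manifest = train(ds["train"], ds["val"], cfg,
                        TrainConfig(epochs=10, batch_size=16, seed=0))
```

Evaluating on five held-out phantoms (exact ground-truth masks) prints

```
PSNR noisy 15.31  denoised 18.28  gain 2.97 dB
mDice 0.9168
```

i.e. the one-repetition input gains ~3 dB towards the 4-repetition
average, and the predicted epithelium/stroma masks overlap the ground
truth at mDice ≈ 0.92 after ten epochs.

A CLI mirrors the library:

```bash
esdm simulate --seed 3 --out data/v0          # phantom volume + masks
esdm preprocess --volumes data/v0 --out pre   # training pairs
esdm train --data data --epochs 10 --out run  # fit, checkpoint best epoch
esdm infer --checkpoint run/checkpoint.npz --volume data/v0 --out out
esdm eval --checkpoint run/checkpoint.npz --data data
esdm thickness --masks data/v0/masks          # µm per frame
esdm complexity                               # parameters + FLOPs
```

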