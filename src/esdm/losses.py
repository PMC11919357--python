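"""Multi-task training objective.

Denoising is trained with a weighted sum of pixel MSE and a feature-space
content loss, both written as sums over elements (not means), so the
default weights alpha = 1 and beta = 0.01 keep their calibrated balance;
batch aggregation averages the per-sample sums. Segmentation is trained
with soft-label cross-entropy: the annotated class carries confidence 0.95
and the remaining 0.05 is spread over the other classes, which makes the
loss tolerant to pseudo-label error. The combined objective is their
unweighted sum.

The content-loss feature extractor is pluggable. Pretrained perceptual
weights can be supplied by the caller; the default is a fixed-seed
random-weight convolutional surrogate, which is deterministic, needs no
download, and still measures feature-space (rather than pixel-space)
discrepancy. ``mode="off"`` (or beta = 0) reduces the denoising loss to
pure MSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .nn import Conv2d, Module

__all__ = ["FeatureExtractor", "LossConfig", "denoise_loss", "seg_loss",
           "combined_loss"]

_LOG_CLAMP = 1e-12


class _SurrogateNet(Module):
    """Two fixed random conv layers with GeLU; weights frozen."""

    def __init__(self, seed: int, channels: tuple = (16, 32)):
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(1, channels[0], 3, rng)
        self.conv2 = Conv2d(channels[0], channels[1], 3, rng)
        for p in self.parameters():
            p.requires_grad = False

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv2(ad.gelu(self.conv1(x)))


@dataclass
class FeatureExtractor:
    """Maps an image batch to a feature map, deterministically.

    mode: ``fixed-random-surrogate`` (default), ``pretrained-perceptual``
    (requires ``network``, e.g. a perceptual backbone adapted to this
    interface), or ``off``.
    """

    mode: str = "fixed-random-surrogate"
    seed: int = 0
    network: object = None

    def __post_init__(self):
        if self.mode == "fixed-random-surrogate":
            self.network = _SurrogateNet(self.seed)
        elif self.mode == "pretrained-perceptual":
            if self.network is None:
                raise ValueError(
                    "pretrained-perceptual mode requires a caller-supplied "
                    "feature network (no weights ship with this package)")
        elif self.mode != "off":
            raise ValueError(f"unknown feature extractor mode {self.mode!r}")

    def __call__(self, x: Tensor) -> Tensor:
        if self.mode == "off":
            raise RuntimeError("feature extractor is disabled")
        return self.network(x)


@dataclass
class LossConfig:
    alpha: float = 1.0      # MSE weight
    beta: float = 0.01      # content-loss weight
    confidence: float = 0.95
    feature_extractor: FeatureExtractor = field(
        default_factory=FeatureExtractor)

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be non-negative")
        if not 0.0 < self.confidence <= 1.0:
            raise ValueError("confidence must lie in (0, 1]")


def _as4d(t: Tensor) -> Tensor:
    if t.ndim == 2:
        return ad.reshape(t, (1, 1) + t.shape)
    if t.ndim == 3:
        return ad.reshape(t, (t.shape[0], 1) + t.shape[1:])
    return t


def denoise_loss(target: Tensor | np.ndarray, output: Tensor,
                 cfg: LossConfig) -> Tensor:
    """alpha * sum((I - Ihat)^2) + beta * sum((phi(I) - phi(Ihat))^2).

    Sums run over all pixels / feature elements of each sample; the batch
    dimension is averaged.
    """
    target = target if isinstance(target, Tensor) else Tensor(
        np.asarray(target, dtype=np.float32))
    if target.shape != output.shape:
        raise ValueError(f"shape mismatch: {target.shape} vs {output.shape}")
    t4, o4 = _as4d(target), _as4d(output)
    n = t4.shape[0]
    diff = t4 - o4
    loss = ad.mul(ad.sum_(ad.mul(diff, diff)), cfg.alpha / n)
    use_content = (cfg.beta > 0
                   and cfg.feature_extractor.mode != "off")
    if use_content:
        fdiff = cfg.feature_extractor(t4) - cfg.feature_extractor(o4)
        loss = ad.add(loss,
                      ad.mul(ad.sum_(ad.mul(fdiff, fdiff)), cfg.beta / n))
    return loss


def seg_loss(probabilities: Tensor, soft_labels: np.ndarray) -> Tensor:
    """Soft-label cross-entropy, mean over pixels.

    ``probabilities``: (N, K, H, W) per-pixel class probabilities (rows sum
    to 1); ``soft_labels``: matching array. Logs are clamped at 1e-12.
    """
    y = np.asarray(soft_labels, dtype=probabilities.data.dtype)
    if y.shape != probabilities.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs "
                         f"{probabilities.shape}")
    if probabilities.data.min() < -1e-9:
        raise ValueError("negative probabilities")
    n_pixels = probabilities.shape[0] * probabilities.shape[2] \
        * probabilities.shape[3]
    logp = ad.log(probabilities, eps=_LOG_CLAMP)
    return ad.mul(ad.sum_(ad.mul(logp, y)), -1.0 / n_pixels)


def seg_loss_from_logits(logits: Tensor, soft_labels: np.ndarray) -> Tensor:
    """Convenience: softmax over the class axis, then soft-label CE."""
    return seg_loss(ad.softmax(logits, axis=1), soft_labels)


def combined_loss(denoise_term: Tensor | None,
                  seg_term: Tensor | None) -> Tensor:
    """L_c = L_D + L_seg, no extra weights; a disabled task contributes 0."""
    if denoise_term is None and seg_term is None:
        raise ValueError("at least one task term is required")
    if denoise_term is None:
        return seg_term
    if seg_term is None:
        return denoise_term
    return ad.add(denoise_term, seg_term)
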