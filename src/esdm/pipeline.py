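"""Orchestration: training loop, checkpointing, inference and evaluation.

Training minimises the combined loss with Adam at a fixed learning rate,
keeping the weights with the lowest validation combined loss (checkpoint
selection). Everything is seeded: data order, weight initialisation and the
loss surrogate, so a run manifest plus a seed reproduces a run bit for bit
on the same build.
"""

from __future__ import annotations

import copy
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .esdm_net import EsdmModel, ModelConfig, build_model, count_parameters
from .losses import LossConfig, combined_loss, denoise_loss, seg_loss_from_logits
from .metrics import evaluate_dataset
from .nn import Adam
from .phantom import OctVolume
from .preprocess import CropSpec, DataPair, extract_patches, stitch_patches
from .thickness import ThicknessConfig, measure_thickness, thickness_mae

__all__ = ["TrainConfig", "RunManifest", "train", "infer", "evaluate",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 16
    epochs: int = 200
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-7

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training hyperparameters")


@dataclass
class RunManifest:
    model_config: dict
    train_config: dict
    loss_config: dict
    train_losses: list = field(default_factory=list)
    val_losses: list = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("nan")
    complexity: dict = field(default_factory=dict)
    wall_seconds: float = 0.0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _batch_arrays(pairs: list[DataPair]):
    noisy = np.stack([p.noisy for p in pairs])[:, None].astype(np.float32)
    target = np.stack([p.target for p in pairs])[:, None].astype(np.float32)
    soft = np.stack([p.soft_label for p in pairs]).transpose(0, 3, 1, 2)
    soft = np.ascontiguousarray(soft, dtype=np.float32)
    return noisy, target, soft


def _losses_for_batch(model: EsdmModel, noisy, target, soft,
                      loss_cfg: LossConfig):
    den, logits = model(Tensor(noisy))
    d_term = denoise_loss(target, den, loss_cfg) if den is not None else None
    s_term = (seg_loss_from_logits(logits, soft)
              if logits is not None else None)
    return combined_loss(d_term, s_term)


def _validation_loss(model: EsdmModel, pairs: list[DataPair],
                     loss_cfg: LossConfig, batch_size: int) -> float:
    total, n = 0.0, 0
    with ad.no_grad():
        for i in range(0, len(pairs), batch_size):
            chunk = pairs[i:i + batch_size]
            noisy, target, soft = _batch_arrays(chunk)
            loss = _losses_for_batch(model, noisy, target, soft, loss_cfg)
            total += loss.item() * len(chunk)
            n += len(chunk)
    return total / n


def train(train_pairs: list[DataPair], val_pairs: list[DataPair],
          model_cfg: ModelConfig, train_cfg: TrainConfig | None = None,
          loss_cfg: LossConfig | None = None,
          verbose: bool = False) -> tuple[EsdmModel, RunManifest]:
    """Fit the model; returns the best-validation-loss weights and the run
    manifest (per-epoch loss trajectories, selected epoch, complexity)."""
    if not train_pairs or not val_pairs:
        raise ValueError("need non-empty train and validation splits")
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    t0 = time.time()
    model = build_model(model_cfg)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate,
               beta1=train_cfg.adam_beta1, beta2=train_cfg.adam_beta2,
               eps=train_cfg.adam_eps)
    rng = np.random.default_rng(train_cfg.seed)
    manifest = RunManifest(model_config=model_cfg.to_dict(),
                           train_config=asdict(train_cfg),
                           loss_config={"alpha": loss_cfg.alpha,
                                        "beta": loss_cfg.beta,
                                        "confidence": loss_cfg.confidence,
                                        "extractor":
                                        loss_cfg.feature_extractor.mode},
                           complexity=count_parameters(model).to_dict())
    best_state = copy.deepcopy(model.state_dict())
    best_val = float("inf")
    best_epoch = -1
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(train_pairs))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), train_cfg.batch_size):
            chunk = [train_pairs[j] for j in order[i:i + train_cfg.batch_size]]
            noisy, target, soft = _batch_arrays(chunk)
            opt.zero_grad()
            loss = _losses_for_batch(model, noisy, target, soft, loss_cfg)
            val = loss.item()
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={val}")
            loss.backward()
            opt.step()
            epoch_loss += val * len(chunk)
            seen += len(chunk)
        val_loss = _validation_loss(model, val_pairs, loss_cfg,
                                    train_cfg.batch_size)
        manifest.train_losses.append(epoch_loss / seen)
        manifest.val_losses.append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = copy.deepcopy(model.state_dict())
        if verbose:
            print(f"epoch {epoch}: train {epoch_loss / seen:.4f} "
                  f"val {val_loss:.4f}")
    model.load_state_dict(best_state)
    manifest.best_epoch = best_epoch
    manifest.best_val_loss = best_val if np.isfinite(best_val) else \
        float("nan")
    manifest.wall_seconds = time.time() - t0
    return model, manifest


def save_checkpoint(model: EsdmModel, manifest: RunManifest,
                    path: str | Path) -> None:
    """Weights as .npz plus a JSON architecture manifest alongside."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    manifest.to_json(path.with_suffix(".json"))


def load_checkpoint(path: str | Path, model_cfg: ModelConfig) -> EsdmModel:
    model = build_model(model_cfg)
    with np.load(Path(path), allow_pickle=False) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def infer(model: EsdmModel, volume: OctVolume, spec: CropSpec):
    """Denoise + segment every frame using repetition 1 only.

    Patches are forward-passed per crop window and stitched back at their
    windows; overlapping columns are averaged (denoised image and softmax
    probabilities alike), then the mask is the per-pixel argmax with ties
    broken toward the lowest class index.
    """
    f_total, _, depth, width = volume.data.shape
    spec.validate(depth, width)
    denoised = np.zeros((f_total, spec.patch_height, width), dtype=np.float32)
    masks = np.zeros((f_total, spec.patch_height, width), dtype=np.uint8)
    for f in range(f_total):
        patches = extract_patches(volume.data[f, 0], spec)
        batch = np.stack(patches)[:, None].astype(np.float32)
        den, logits = model.predict(batch)
        den_list = [den[i, 0] for i in range(len(patches))] \
            if den is not None else None
        if den_list is not None:
            denoised[f] = stitch_patches(den_list, spec, spec.patch_height,
                                         width)
        if logits is not None:
            z = logits - logits.max(axis=1, keepdims=True)
            probs = np.exp(z)
            probs /= probs.sum(axis=1, keepdims=True)
            k = probs.shape[1]
            prob_maps = [probs[i].transpose(1, 2, 0)
                         for i in range(len(patches))]
            stitched = np.stack(
                [stitch_patches([pm[:, :, c] for pm in prob_maps], spec,
                                spec.patch_height, width)
                 for c in range(k)], axis=-1)
            masks[f] = np.argmax(stitched, axis=-1).astype(np.uint8)
    return denoised, masks


def evaluate(model: EsdmModel, test_pairs: list[DataPair],
             thickness_cfg: ThicknessConfig | None = None):
    """Metrics on held-out pairs: denoised-vs-target PSNR/SSIM, mask
    overlap, and thickness MAE against the reference masks."""
    if not test_pairs:
        raise ValueError("empty test set")
    thickness_cfg = thickness_cfg or ThicknessConfig()
    batch = np.stack([p.noisy for p in test_pairs])[:, None]
    den, logits = model.predict(batch.astype(np.float32))
    refs = [p.target for p in test_pairs]
    outs = [den[i, 0] for i in range(len(test_pairs))] \
        if den is not None else refs
    ref_masks = [p.label for p in test_pairs]
    if logits is not None:
        out_masks = [np.argmax(logits[i], axis=0).astype(np.uint8)
                     for i in range(len(test_pairs))]
    else:
        out_masks = None
    report = evaluate_dataset(refs, outs, ref_masks=ref_masks,
                              out_masks=out_masks)
    thickness = None
    if out_masks is not None:
        pred_prof = [measure_thickness(m, thickness_cfg) for m in out_masks]
        ref_prof = [measure_thickness(m, thickness_cfg) for m in ref_masks]
        try:
            thickness = thickness_mae(pred_prof, ref_prof)
        except ValueError:
            thickness = None
    return report, thickness
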