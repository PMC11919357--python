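"""Training-pair construction.

The denoising target for each B-frame is the arithmetic mean over its
acquisition repetitions (frame averaging); the network input is repetition 1
alone. Frames are cropped into fixed 256 x 256 boxes whose transverse start
offsets depend on the sample lens: [0, 256) and [144, 400) for the intraoral
lens (400-pixel frames), [0, 256), [256, 512) and [344, 600) for the LSM03
lens (600-pixel frames). Windows are half-open and 0-based.

Segmentation supervision is semi-supervised: the first frame of a volume
carries a manual mask, the rest carry pseudo-labels from a teacher. Since no
pre-trained teacher ships with this package, :class:`TeacherOracle` offers a
corrupting-oracle mode that degrades the ground-truth mask with smooth
boundary jitter and pixel-level label noise, emulating an imperfect teacher
with controllable error; an ``external-model`` mode delegates to any
user-supplied callable. Masks are encoded as soft labels: the annotated
class receives a confidence below 1 and the remainder is spread uniformly
over the other classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .phantom import EPITHELIUM, STROMA, LayerMaskVolume, OctVolume

__all__ = [
    "CropSpec", "DataPair", "TeacherOracle", "frame_average",
    "extract_patches", "stitch_patches", "pseudo_label",
    "encode_soft_labels", "make_dataset", "INTRAORAL_STARTS", "LSM03_STARTS",
    "crop_spec_for_lens",
]

INTRAORAL_STARTS = (0, 144)        # 400-pixel transverse frames
LSM03_STARTS = (0, 256, 344)       # 600-pixel transverse frames


@dataclass
class CropSpec:
    """Fixed-size crop boxes: half-open 0-based transverse windows."""

    patch_height: int = 256
    patch_width: int = 256
    transverse_starts: tuple = (0,)
    axial_start: int = 0

    def windows(self):
        return [(s, s + self.patch_width) for s in self.transverse_starts]

    def validate(self, depth: int, width: int) -> None:
        if self.axial_start + self.patch_height > depth:
            raise ValueError(
                f"axial window [{self.axial_start}, "
                f"{self.axial_start + self.patch_height}) exceeds depth "
                f"{depth}")
        for lo, hi in self.windows():
            if lo < 0 or hi > width:
                raise ValueError(f"transverse window [{lo}, {hi}) exceeds "
                                 f"frame width {width}")


def crop_spec_for_lens(lens_tag: str, patch: int = 256) -> CropSpec:
    starts = {"intraoral": INTRAORAL_STARTS,
              "LSM03": LSM03_STARTS}.get(lens_tag)
    if starts is None:
        raise ValueError(f"unknown lens tag {lens_tag!r}")
    return CropSpec(patch, patch, starts)


@dataclass
class DataPair:
    """(noisy input, frame-averaged target, hard mask, soft label) patches
    sharing one location."""

    noisy: np.ndarray
    target: np.ndarray
    label: np.ndarray
    soft_label: np.ndarray
    provenance: tuple = ("", 0, (0, 0))    # (volume id, frame, window)

    def __post_init__(self):
        if not (self.noisy.shape == self.target.shape
                == self.label.shape == self.soft_label.shape[:2]):
            raise ValueError("patch shapes disagree")
        rows = self.soft_label.sum(axis=-1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("soft-label rows must sum to 1")


def frame_average(volume: OctVolume) -> np.ndarray:
    """Collapse the repetition axis by arithmetic mean: [F, Z, X] target."""
    return volume.data.mean(axis=1)


def extract_patches(frame: np.ndarray, spec: CropSpec) -> list[np.ndarray]:
    """One patch per transverse window of ``spec`` (copies, row = z)."""
    spec.validate(*frame.shape)
    z0 = spec.axial_start
    return [frame[z0:z0 + spec.patch_height, lo:hi].copy()
            for lo, hi in spec.windows()]


def stitch_patches(patches: Sequence[np.ndarray], spec: CropSpec,
                   depth: int, width: int) -> np.ndarray:
    """Reassemble patches at their windows; overlaps are averaged.

    Uncovered pixels are returned as zero.
    """
    out = np.zeros((depth, width), dtype=np.float64)
    cnt = np.zeros((depth, width), dtype=np.float64)
    z0 = spec.axial_start
    for patch, (lo, hi) in zip(patches, spec.windows()):
        out[z0:z0 + spec.patch_height, lo:hi] += patch
        cnt[z0:z0 + spec.patch_height, lo:hi] += 1.0
    np.divide(out, cnt, out=out, where=cnt > 0)
    return out


@dataclass
class TeacherOracle:
    """Pseudo-label source.

    ``corrupting-oracle`` degrades the true mask: both boundary curves are
    displaced by smooth seeded noise of scale ``jitter`` pixels, the mask is
    rebuilt, and each pixel's label is then resampled uniformly over the K
    classes with probability ``flip_rate``. ``external-model`` calls
    ``model(averaged_frame) -> mask``.
    """

    mode: str = "corrupting-oracle"
    jitter: float = 2.0
    flip_rate: float = 0.01
    seed: int = 0
    smoothness: float = 20.0
    model: Callable | None = None
    n_classes: int = 3

    def __post_init__(self):
        if self.mode not in ("corrupting-oracle", "external-model"):
            raise ValueError(f"unknown teacher mode {self.mode!r}")
        if self.mode == "external-model" and self.model is None:
            raise ValueError("external-model mode needs a callable")
        self._rng = np.random.default_rng(self.seed)


def _rebuild_mask(s_px: np.ndarray, b_px: np.ndarray, depth: int
                  ) -> np.ndarray:
    z = np.arange(depth)[:, None]
    lab = np.zeros((depth, s_px.size), dtype=np.uint8)
    lab[(z >= s_px[None, :]) & (z < b_px[None, :])] = EPITHELIUM
    lab[z >= b_px[None, :]] = STROMA
    return lab


def pseudo_label(teacher: TeacherOracle, true_mask_frame: np.ndarray,
                 boundary_curves: np.ndarray | None = None,
                 averaged_frame: np.ndarray | None = None) -> np.ndarray:
    """Produce one pseudo-label mask frame.

    ``boundary_curves`` is the (2, X) ground-truth boundary row for the
    frame (required by the corrupting oracle); ``averaged_frame`` is the
    high-quality image handed to an external teacher model.
    """
    depth, width = true_mask_frame.shape
    if teacher.mode == "external-model":
        if averaged_frame is None:
            raise ValueError("external-model mode needs the averaged frame")
        out = np.asarray(teacher.model(averaged_frame))
        if out.shape != true_mask_frame.shape or \
                not np.isin(out, np.arange(teacher.n_classes)).all():
            raise ValueError("external teacher returned an invalid mask")
        return out.astype(np.uint8)

    if boundary_curves is None:
        raise ValueError("corrupting-oracle mode needs boundary curves")
    rng = teacher._rng
    s_px, b_px = boundary_curves[0].astype(float), \
        boundary_curves[1].astype(float)
    if teacher.jitter > 0:
        for curve in (s_px, b_px):
            z = rng.standard_normal(width)
            z = gaussian_filter1d(z, sigma=teacher.smoothness, mode="wrap")
            sd = z.std()
            if sd > 0:
                z /= sd
            curve += teacher.jitter * z
    s_i = np.clip(np.floor(s_px + 0.5).astype(np.int64), 0, depth - 2)
    b_i = np.clip(np.floor(b_px + 0.5).astype(np.int64), s_i + 1, depth - 1)
    mask = _rebuild_mask(s_i, b_i, depth)
    if teacher.flip_rate > 0:
        flips = rng.random(mask.shape) < teacher.flip_rate
        mask = np.where(
            flips, rng.integers(0, teacher.n_classes, size=mask.shape),
            mask).astype(np.uint8)
    return mask


def encode_soft_labels(mask: np.ndarray, confidence: float = 0.95,
                       n_classes: int = 3) -> np.ndarray:
    """Per-pixel K-class distribution: ``confidence`` on the annotated
    class, (1-confidence)/(K-1) on each other class."""
    if not 0.0 < confidence <= 1.0:
        raise ValueError("confidence must lie in (0, 1]")
    if n_classes < 2:
        raise ValueError("need at least two classes")
    mask = np.asarray(mask)
    if mask.min(initial=0) < 0 or mask.max(initial=0) >= n_classes:
        raise ValueError(f"mask labels must lie in [0, {n_classes})")
    off = (1.0 - confidence) / (n_classes - 1)
    out = np.full(mask.shape + (n_classes,), off, dtype=np.float64)
    np.put_along_axis(out, mask[..., None].astype(np.int64), confidence,
                      axis=-1)
    return out


def make_dataset(volumes: Sequence[tuple[str, OctVolume, LayerMaskVolume]],
                 spec: CropSpec, teacher: TeacherOracle,
                 split: tuple = (0.8, 0.2, 0.0), seed: int = 0,
                 confidence: float = 0.95) -> dict[str, list[DataPair]]:
    """Assemble train/val/test DataPair collections.

    For every volume and frame, one pair per crop window: noisy patch from
    repetition 1, target from the frame average, mask from the manual
    annotation on frame 0 and from the teacher on later frames. The split is
    by volume (seeded, disjoint).
    """
    if sum(split) > 1.0 + 1e-9 or any(s < 0 for s in split):
        raise ValueError("split fractions must be non-negative and sum to "
                         "at most 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(volumes))
    n = len(volumes)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    roles = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            roles[idx] = "train"
        elif rank < n_train + n_val:
            roles[idx] = "val"
        else:
            roles[idx] = "test"
    out: dict[str, list[DataPair]] = {"train": [], "val": [], "test": []}
    for idx, (vid, vol, masks) in enumerate(volumes):
        averaged = frame_average(vol)
        for f in range(vol.n_frames):
            if f == 0:
                mask_f = masks.labels[0]
            else:
                mask_f = pseudo_label(teacher, masks.labels[f],
                                      boundary_curves=masks.boundary_curves[f],
                                      averaged_frame=averaged[f])
            noisy_patches = extract_patches(vol.data[f, 0], spec)
            target_patches = extract_patches(averaged[f], spec)
            mask_patches = extract_patches(mask_f, spec)
            for w, (lo, hi) in enumerate(spec.windows()):
                lab = mask_patches[w].astype(np.uint8)
                out[roles[idx]].append(DataPair(
                    noisy=noisy_patches[w].astype(np.float32),
                    target=target_patches[w].astype(np.float32),
                    label=lab,
                    soft_label=encode_soft_labels(lab, confidence,
                                                  teacher.n_classes),
                    provenance=(vid, f, (lo, hi))))
    return out
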