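"""Image-quality and segmentation metrics.

PSNR and SSIM quantify denoising against the frame-averaged reference;
mDice and mIoU quantify mask overlap, class-averaged. SSIM is offered both
in its global form (one statistic per image) and in the conventional
windowed form (11 x 11 Gaussian window, sigma 1.5, k1 = 0.01, k2 = 0.03),
which is the default. A class absent from both masks contributes 1 to the
class average (perfect-agreement convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SsimConfig", "ConfusionCounts", "MetricReport",
    "psnr", "ssim", "confusion", "mdice", "miou", "evaluate_dataset",
]


@dataclass
class SsimConfig:
    dynamic_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    window: str = "gaussian"     # "gaussian" (11x11, sigma 1.5) or "global"
    sigma: float = 1.5
    truncate: float = 3.5        # radius 5 -> 11x11 support

    @property
    def c1(self) -> float:
        return (self.k1 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.dynamic_range) ** 2


def psnr(y: np.ndarray, y_hat: np.ndarray, i_max: float = 1.0) -> float:
    """10 log10(i_max^2 / MSE) in dB; +inf for identical images."""
    y, y_hat = np.asarray(y, dtype=np.float64), np.asarray(y_hat,
                                                           dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    if y.size == 0:
        raise ValueError("empty images")
    if i_max <= 0:
        raise ValueError("i_max must be positive")
    mse = float(np.mean((y - y_hat) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(i_max ** 2 / mse))


def _ssim_formula(mu_x, mu_y, var_x, var_y, cov, c1, c2):
    return (((2 * mu_x * mu_y + c1) * (2 * cov + c2))
            / ((mu_x ** 2 + mu_y ** 2 + c1) * (var_x + var_y + c2)))


def ssim(y: np.ndarray, y_hat: np.ndarray,
         cfg: SsimConfig | None = None) -> float:
    """Structural similarity in [-1, 1]."""
    cfg = cfg or SsimConfig()
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("shape mismatch")
    if cfg.window == "global":
        mu_x, mu_y = y.mean(), y_hat.mean()
        var_x, var_y = y.var(), y_hat.var()
        cov = ((y - mu_x) * (y_hat - mu_y)).mean()
        return float(_ssim_formula(mu_x, mu_y, var_x, var_y, cov,
                                   cfg.c1, cfg.c2))
    if cfg.window != "gaussian":
        raise ValueError(f"unknown SSIM window {cfg.window!r}")
    radius = int(cfg.truncate * cfg.sigma + 0.5)
    if min(y.shape) < 2 * radius + 1:
        raise ValueError(f"image smaller than the {2 * radius + 1}-pixel "
                         "window")

    def filt(img):
        return gaussian_filter(img, cfg.sigma, mode="nearest",
                               truncate=cfg.truncate)

    mu_x, mu_y = filt(y), filt(y_hat)
    var_x = filt(y * y) - mu_x ** 2
    var_y = filt(y_hat * y_hat) - mu_y ** 2
    cov = filt(y * y_hat) - mu_x * mu_y
    smap = _ssim_formula(mu_x, mu_y, var_x, var_y, cov, cfg.c1, cfg.c2)
    crop = smap[radius:-radius, radius:-radius]
    return float(crop.mean())


@dataclass
class ConfusionCounts:
    """Per-class true-positive / false-positive / false-negative pixels."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.tp)


def confusion(pred: np.ndarray, ref: np.ndarray,
              n_classes: int = 3) -> ConfusionCounts:
    pred, ref = np.asarray(pred), np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError("shape mismatch")
    for m in (pred, ref):
        if m.min(initial=0) < 0 or m.max(initial=0) >= n_classes:
            raise ValueError(f"labels must lie in [0, {n_classes})")
    tp = np.zeros(n_classes, dtype=np.int64)
    fp = np.zeros(n_classes, dtype=np.int64)
    fn = np.zeros(n_classes, dtype=np.int64)
    for c in range(n_classes):
        p, r = pred == c, ref == c
        tp[c] = np.count_nonzero(p & r)
        fp[c] = np.count_nonzero(p & ~r)
        fn[c] = np.count_nonzero(~p & r)
    return ConfusionCounts(tp, fp, fn)


def _class_average(num: np.ndarray, den: np.ndarray) -> float:
    # absent-from-both classes (den == 0) contribute 1
    vals = np.ones(len(num), dtype=np.float64)
    nz = den > 0
    vals[nz] = num[nz] / den[nz]
    return float(vals.mean())


def mdice(counts: ConfusionCounts) -> float:
    """Class-averaged Dice: 2TP / (2TP + FP + FN)."""
    return _class_average(2.0 * counts.tp,
                          2.0 * counts.tp + counts.fp + counts.fn)


def miou(counts: ConfusionCounts) -> float:
    """Class-averaged intersection over union: TP / (TP + FP + FN)."""
    return _class_average(counts.tp.astype(np.float64),
                          counts.tp + counts.fp + counts.fn)


@dataclass
class MetricReport:
    """Per-image metrics with mean +/- sample standard deviation."""

    per_image: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        rows = []
        for col in self.per_image.columns:
            vals = self.per_image[col].to_numpy(dtype=np.float64)
            finite = vals[np.isfinite(vals)]
            std = float(finite.std(ddof=1)) if len(finite) > 1 else 0.0
            rows.append({"metric": col,
                         "mean": float(finite.mean()) if len(finite) else
                         np.nan,
                         "std": std, "n": int(len(finite))})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.aggregate().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {row["metric"]: {"mean": row["mean"], "std": row["std"],
                                "n": row["n"]}
                for row in self.aggregate().to_dict("records")}


def evaluate_dataset(references: list, outputs: list,
                     ref_masks: list | None = None,
                     out_masks: list | None = None,
                     n_classes: int = 3,
                     ssim_cfg: SsimConfig | None = None) -> MetricReport:
    """Per-image PSNR/SSIM (and mDice/mIoU when masks are given)."""
    if len(references) != len(outputs) or not references:
        raise ValueError("need equal-length, non-empty image collections")
    rows = []
    for i, (ref, out) in enumerate(zip(references, outputs)):
        row = {"psnr": psnr(ref, out), "ssim": ssim(ref, out, ssim_cfg)}
        if ref_masks is not None and out_masks is not None:
            counts = confusion(out_masks[i], ref_masks[i], n_classes)
            row["mdice"] = mdice(counts)
            row["miou"] = miou(counts)
        rows.append(row)
    return MetricReport(pd.DataFrame(rows))
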