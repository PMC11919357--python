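"""Synthetic layered-speckle phantoms of oral OCT volumes.

Each phantom is a two-layer tissue (epithelium over stroma) beneath a smooth
air-tissue surface, imaged as N-repetition B-frames. The noise-free
reflectivity of each layer decays exponentially with cumulative depth inside
tissue, and every repetition multiplies an independent unit-mean gamma
speckle field — a standard surrogate for fully developed speckle that obeys
the 1/NR variance law of repetition averaging. Boundary curves are low-pass
filtered seeded noise, shared across frames up to a slow drift, so masks,
pseudo-label corruption and thickness statistics behave like real volumes.

The generator is the test bed for the whole pipeline: the returned masks and
boundary curves are exact ground truth for segmentation and epithelium
thickness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PhantomConfig", "OctVolume", "LayerMaskVolume",
    "generate_phantom", "true_thickness_profile",
    "save_volume", "load_volume", "save_masks", "load_masks",
]

BACKGROUND, EPITHELIUM, STROMA = 0, 1, 2


@dataclass
class PhantomConfig:
    """Geometry, optics and noise of the synthetic volume.

    Lengths are in pixels; reflectivities are mean backscatter in (0, 1];
    ``attenuation`` is the per-pixel exponential decay inside each layer;
    ``speckle_shape`` is the gamma shape of the unit-mean multiplicative
    noise (variance 1/shape; ``numpy.inf`` disables speckle).
    """

    width: int = 256
    depth: int = 256
    n_frames: int = 4
    n_repetitions: int = 4
    surface_depth_mean: float = 40.0
    epithelium_thickness_mean: float = 45.0
    boundary_amplitude: float = 6.0
    boundary_smoothness: float = 40.0
    layer_reflectivity: tuple = (0.35, 0.55)   # (epithelium, stroma)
    attenuation: tuple = (0.002, 0.004)        # per-pixel, per layer
    speckle_shape: float = 4.0
    noise_floor: float = 0.03
    frame_drift: float = 0.2                   # fraction of amplitude
    seed: int = 0
    lens_tag: str = "LSM03"
    axial_coeff_air: float = 8.74              # µm per pixel in air

    def __post_init__(self):
        if self.n_repetitions < 1 or self.n_frames < 1:
            raise ValueError("need at least one frame and one repetition")
        if not all(0.0 < r <= 1.0 for r in self.layer_reflectivity):
            raise ValueError("reflectivities must lie in (0, 1]")
        if any(a < 0 for a in self.attenuation) or self.noise_floor < 0:
            raise ValueError("attenuation and noise floor must be >= 0")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        margin = (self.surface_depth_mean + self.epithelium_thickness_mean
                  + 2.0 * self.boundary_amplitude)
        if margin >= self.depth:
            raise ValueError("layer geometry does not fit inside the image "
                             f"(needs {margin:.0f} of {self.depth} pixels)")
        if self.surface_depth_mean - 2.0 * self.boundary_amplitude < 0:
            raise ValueError("surface would leave the top of the image")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class OctVolume:
    """Repetition-resolved B-frame stack, values in [0, 1].

    ``data`` is indexed [frame, repetition, z, x].
    """

    data: np.ndarray
    lens_tag: str = "LSM03"
    axial_coeff_air: float = 8.74

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError("expected [frame, repetition, z, x] array")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValueError("volume values must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_repetitions(self) -> int:
        return self.data.shape[1]


@dataclass
class LayerMaskVolume:
    """Per-pixel 3-class labels [frame, z, x] plus exact boundary rows.

    ``boundary_curves`` has shape [frame, 2, x]: per A-line pixel depth of
    the air-epithelium surface and of the epithelium-stroma boundary.
    """

    labels: np.ndarray
    boundary_curves: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.boundary_curves = np.asarray(self.boundary_curves,
                                          dtype=np.int64)
        if self.labels.ndim != 3 or self.boundary_curves.ndim != 3:
            raise ValueError("bad mask / boundary shapes")
        if self.labels.max(initial=0) > STROMA:
            raise ValueError("labels must be in {0, 1, 2}")


def _smooth_noise(rng: np.random.Generator, shape, smoothness: float,
                  axis: int = -1) -> np.ndarray:
    """Unit-variance low-pass noise along ``axis`` (correlation length in
    pixels)."""
    z = rng.standard_normal(shape)
    z = gaussian_filter1d(z, sigma=max(smoothness, 1e-6), axis=axis,
                          mode="wrap")
    sd = z.std()
    return z / sd if sd > 0 else z


def _boundaries(cfg: PhantomConfig, rng: np.random.Generator):
    """Integer surface and inner-boundary depth per (frame, A-line)."""
    f, x = cfg.n_frames, cfg.width
    shared_s = _smooth_noise(rng, (x,), cfg.boundary_smoothness)
    shared_t = _smooth_noise(rng, (x,), cfg.boundary_smoothness)
    drift_s = _smooth_noise(rng, (f, x), cfg.boundary_smoothness, axis=-1)
    drift_t = _smooth_noise(rng, (f, x), cfg.boundary_smoothness, axis=-1)
    drift_s = gaussian_filter1d(drift_s, sigma=max(f / 2.0, 1e-6), axis=0,
                                mode="nearest")
    drift_t = gaussian_filter1d(drift_t, sigma=max(f / 2.0, 1e-6), axis=0,
                                mode="nearest")
    a, d = cfg.boundary_amplitude, cfg.frame_drift
    surface = cfg.surface_depth_mean + a * (shared_s[None, :] + d * drift_s)
    thickness = (cfg.epithelium_thickness_mean
                 + a * (shared_t[None, :] + d * drift_t))
    inner = surface + np.maximum(thickness, 1.0)
    # round half-up so a zero-amplitude phantom has exact integer geometry
    s_px = np.floor(surface + 0.5).astype(np.int64)
    b_px = np.floor(inner + 0.5).astype(np.int64)
    s_px = np.clip(s_px, 0, cfg.depth - 2)
    b_px = np.clip(b_px, s_px + 1, cfg.depth - 1)
    return s_px, b_px


def _noise_free_frame(cfg: PhantomConfig, s_px: np.ndarray,
                      b_px: np.ndarray) -> np.ndarray:
    """Reflectivity x exp(-cumulative attenuation) + noise floor, per pixel."""
    z = np.arange(cfg.depth)[:, None]
    r_epi, r_str = cfg.layer_reflectivity
    a_epi, a_str = cfg.attenuation
    in_epi = (z >= s_px[None, :]) & (z < b_px[None, :])
    in_str = z >= b_px[None, :]
    depth_epi = z - s_px[None, :]
    t_epi = b_px - s_px
    depth_str = z - b_px[None, :]
    img = np.full((cfg.depth, cfg.width), cfg.noise_floor, dtype=np.float64)
    img += np.where(in_epi, r_epi * np.exp(-a_epi * depth_epi), 0.0)
    img += np.where(
        in_str,
        r_str * np.exp(-a_epi * t_epi[None, :] - a_str * depth_str), 0.0)
    return img


def generate_phantom(cfg: PhantomConfig):
    """Generate (OctVolume, LayerMaskVolume) from a seeded configuration.

    Identical configurations yield bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    s_px, b_px = _boundaries(cfg, rng)
    data = np.empty((cfg.n_frames, cfg.n_repetitions, cfg.depth, cfg.width),
                    dtype=np.float32)
    labels = np.empty((cfg.n_frames, cfg.depth, cfg.width), dtype=np.uint8)
    z = np.arange(cfg.depth)[:, None]
    for f in range(cfg.n_frames):
        clean = _noise_free_frame(cfg, s_px[f], b_px[f])
        for r in range(cfg.n_repetitions):
            if np.isinf(cfg.speckle_shape):
                noisy = clean
            else:
                k = cfg.speckle_shape
                speckle = rng.gamma(shape=k, scale=1.0 / k, size=clean.shape)
                noisy = clean * speckle
            data[f, r] = np.clip(noisy, 0.0, 1.0)
        lab = np.zeros((cfg.depth, cfg.width), dtype=np.uint8)
        lab[(z >= s_px[f][None, :]) & (z < b_px[f][None, :])] = EPITHELIUM
        lab[z >= b_px[f][None, :]] = STROMA
        labels[f] = lab
    curves = np.stack([s_px, b_px], axis=1)
    vol = OctVolume(data, lens_tag=cfg.lens_tag,
                    axial_coeff_air=cfg.axial_coeff_air)
    masks = LayerMaskVolume(labels, curves)
    return vol, masks


def true_thickness_profile(masks: LayerMaskVolume) -> np.ma.MaskedArray:
    """Per-A-line epithelium thickness in pixels, [frame, x].

    A-lines without any epithelium label are masked (missing) and therefore
    excluded from means.
    """
    counts = (masks.labels == EPITHELIUM).sum(axis=1)
    return np.ma.masked_equal(counts.astype(np.int64), 0)


# ---------------------------------------------------------------------------
# persistence: multi-page TIFF + PNG masks + JSON/YAML sidecars
# ---------------------------------------------------------------------------

def save_volume(vol: OctVolume, path: str | Path,
                cfg: PhantomConfig | None = None) -> None:
    """Write a volume as multi-page TIFF (page order: frame-major,
    repetition-minor) with a JSON manifest; optional config as YAML."""
    path = Path(path)
    f, r, z, x = vol.data.shape
    pages = vol.data.reshape(f * r, z, x)
    tifffile.imwrite(path, pages)
    manifest = {
        "page_order": "frame-major, repetition-minor",
        "n_frames": f, "n_repetitions": r, "depth": z, "width": x,
        "lens_tag": vol.lens_tag, "axial_coeff_air": vol.axial_coeff_air,
        "dtype": "float32", "value_range": [0.0, 1.0],
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    if cfg is not None:
        path.with_suffix(".yaml").write_text(yaml.safe_dump(cfg.to_dict()))


def load_volume(path: str | Path) -> OctVolume:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    pages = tifffile.imread(path)
    f, r = manifest["n_frames"], manifest["n_repetitions"]
    data = np.asarray(pages).reshape(f, r, manifest["depth"],
                                     manifest["width"])
    return OctVolume(data, lens_tag=manifest["lens_tag"],
                     axial_coeff_air=manifest["axial_coeff_air"])


def save_masks(masks: LayerMaskVolume, directory: str | Path) -> None:
    """One 8-bit PNG per frame (values {0,1,2}) plus boundary curves."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for f in range(masks.labels.shape[0]):
        iio.imwrite(directory / f"mask_{f:04d}.png", masks.labels[f])
    np.savetxt(directory / "boundaries.csv",
               masks.boundary_curves.reshape(-1, masks.labels.shape[2]),
               fmt="%d", delimiter=",")


def load_masks(directory: str | Path) -> LayerMaskVolume:
    directory = Path(directory)
    files = sorted(directory.glob("mask_*.png"))
    labels = np.stack([iio.imread(f) for f in files])
    flat = np.loadtxt(directory / "boundaries.csv", dtype=np.int64,
                      delimiter=",")
    curves = flat.reshape(labels.shape[0], 2, labels.shape[2])
    return LayerMaskVolume(labels, curves)
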