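"""Synthetic two-class brain phantoms.

Generates imbalanced sets of 256x256 grayscale images that stand in for
T2-weighted axial brain slices: an elliptical "brain" with a smooth radial
intensity gradient, ventricle-like dark ellipses and Gaussian tissue
texture.  Pathological phantoms additionally carry one to a few hyper- or
hypo-intense lesion blobs with irregular (harmonically perturbed ellipse)
boundaries and locally raised texture variance — the minimal texture signal
the entropy features are designed to pick up.

This is a texture phantom, not an MR simulator: there is no bias field, no
k-space physics and no anatomy beyond what the feature pipeline consumes.
Default counts mirror a small imbalanced study set (18 healthy / 48
pathological); pixel values are in [0, 1] and everything is deterministic
given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError, ValidationError


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; defaults define the standard ("easy") conditions."""

    n_healthy: int = 18
    n_pathological: int = 48
    size: int = 256
    lesion_intensity: float = 0.25      # contrast of lesion blobs vs background
    lesion_count_range: tuple[int, int] = (3, 5)
    lesion_texture_sd: float = 0.08     # extra noise sd inside lesions
    texture_noise_sd: float = 0.03      # background tissue texture sd
    mislabel_fraction: float = 0.0      # fraction of labels flipped after generation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_pathological < 0:
            raise ValidationError("class counts must be >= 0")
        if self.size < 4:
            raise ValidationError(f"size must be >= 4, got {self.size}")
        if self.lesion_intensity < 0:
            raise ValidationError("lesion_intensity must be >= 0")
        lo, hi = self.lesion_count_range
        if lo < 1 or hi < lo:
            raise ValidationError("lesion_count_range must be 1 <= lo <= hi")
        if not 0.0 <= self.mislabel_fraction < 1.0:
            raise ValidationError("mislabel_fraction must be in [0, 1)")


#: named study conditions: "easy" is the default separable set; "null"
#: removes every class difference (a chance-level control); "outlier"
#: keeps the easy images but flips a fraction of training labels to plant
#: mislabeled points.
PRESETS: dict[str, PhantomConfig] = {
    "easy": PhantomConfig(),
    "null": PhantomConfig(lesion_intensity=0.0, lesion_texture_sd=0.0),
    "outlier": PhantomConfig(mislabel_fraction=0.08),
}


def preset(name: str, **overrides) -> PhantomConfig:
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; expected {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def _ellipse_mask(xx, yy, cx, cy, ax, ay):
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2


def generate_phantom(cls: str, config: PhantomConfig, seed) -> np.ndarray:
    """One phantom slice of the requested class, deterministic given seed.

    ``cls`` is ``"healthy"`` or ``"pathological"``; ``seed`` is anything
    ``numpy.random.default_rng`` accepts (including a SeedSequence).
    """
    if cls not in ("healthy", "pathological"):
        raise ValidationError(f"class must be 'healthy' or 'pathological', got {cls!r}")
    rng = np.random.default_rng(seed)
    s = config.size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    cx = cy = (s - 1) / 2.0

    # brain ellipse with per-subject axis jitter, radial intensity falloff
    ax = 0.40 * s * (1.0 + 0.03 * rng.normal())
    ay = 0.34 * s * (1.0 + 0.03 * rng.normal())
    r2 = _ellipse_mask(xx, yy, cx, cy, ax, ay)
    brain = r2 <= 1.0
    img = np.zeros((s, s))
    img[brain] = 0.78 - 0.30 * r2[brain]

    # slightly brighter cortical rim
    img[brain & (r2 > 0.85)] += 0.08

    # two ventricle-like dark ellipses near the midline
    for side in (-1.0, 1.0):
        vx = cx + side * 0.09 * s + rng.normal(0, 0.01 * s)
        vy = cy - 0.03 * s + rng.normal(0, 0.01 * s)
        va = 0.035 * s * (1.0 + 0.10 * rng.normal())
        vb = 0.10 * s * (1.0 + 0.10 * rng.normal())
        vent = _ellipse_mask(xx, yy, vx, vy, va, vb) <= 1.0
        img[vent & brain] *= 0.35

    # tissue texture: lightly smoothed Gaussian noise inside the brain
    noise = gaussian_filter(rng.normal(0.0, 1.0, (s, s)), 0.7)
    img[brain] += config.texture_noise_sd * noise[brain]

    if cls == "pathological":
        lo, hi = config.lesion_count_range
        n_lesions = int(rng.integers(lo, hi + 1))
        theta = np.arctan2(yy - cy, xx - cx)
        for _ in range(n_lesions):
            # lesion centre well inside the brain
            while True:
                lx = cx + rng.uniform(-0.30, 0.30) * s
                ly = cy + rng.uniform(-0.25, 0.25) * s
                if _ellipse_mask(lx, ly, cx, cy, ax, ay) < 0.55:
                    break
            rad = rng.uniform(0.035, 0.09) * s
            # irregular boundary: ellipse radius modulated by low harmonics
            amp = rng.normal(0.0, 0.10, 3)
            phase = rng.uniform(0.0, 2 * np.pi, 3)
            boundary = rad * (1.0 + sum(
                a * np.cos((h + 2) * theta + ph)
                for h, (a, ph) in enumerate(zip(amp, phase))
            ))
            dist = np.hypot(xx - lx, yy - ly)
            lesion = (dist <= boundary) & brain
            sign = float(rng.choice((-1.0, 1.0)))
            # soft-edged intensity bump plus locally raised texture variance
            soft = gaussian_filter(lesion.astype(float), 1.5)
            img += sign * config.lesion_intensity * soft
            if config.lesion_texture_sd > 0:
                img[lesion] += rng.normal(0.0, config.lesion_texture_sd,
                                          int(lesion.sum()))

    return np.clip(img, 0.0, 1.0)


def generate_dataset(
    config: PhantomConfig, out_dir: Path | str | None = None
) -> tuple[list[np.ndarray], np.ndarray, pd.DataFrame]:
    """A full two-class phantom set, optionally written to disk.

    Returns ``(images, labels, manifest)`` with labels +1 pathological and
    -1 healthy.  Healthy images come first.  When ``out_dir`` is given the
    images are written as 8-bit PNGs plus a ``manifest.csv`` with columns
    ``path,label`` (the same schema the loader consumes); two calls with
    the same config produce byte-identical files.

    ``mislabel_fraction > 0`` flips that fraction of labels (rounded to the
    nearest count, at least one when positive) after generation: the images
    keep their true appearance, only the recorded labels lie, planting
    outliers for robustness experiments.
    """
    ss = np.random.SeedSequence(config.seed)
    n = config.n_healthy + config.n_pathological
    children = ss.spawn(n + 1)
    images: list[np.ndarray] = []
    labels = np.empty(n, dtype=int)
    names: list[str] = []
    for i in range(n):
        cls = "healthy" if i < config.n_healthy else "pathological"
        images.append(generate_phantom(cls, config, children[i]))
        labels[i] = -1 if cls == "healthy" else 1
        names.append(f"{cls}_{i:03d}.png")

    if config.mislabel_fraction > 0:
        rng = np.random.default_rng(children[n])
        n_flip = max(1, round(config.mislabel_fraction * n))
        flip = rng.choice(n, size=n_flip, replace=False)
        labels[flip] = -labels[flip]

    manifest = pd.DataFrame({"path": names, "label": labels})
    if n == 0:
        warnings.warn("generated an empty dataset")
    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, img in zip(names, images):
            iio.imwrite(out / name, (img * 255.0).round().astype(np.uint8))
        manifest.to_csv(out / "manifest.csv", index=False)
    return images, labels, manifest
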