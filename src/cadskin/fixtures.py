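"""Synthetic multi-class pigmented-lesion fixtures.

Generates small RGB images of a skin-like background carrying a single
elliptical lesion whose morphology (radius, border irregularity, contrast,
pigment texture) is class-dependent, so that every downstream stage —
enhancement, GAN balancing, autoencoder features, kernel classification,
Grad-CAM localisation — is testable without any external image collection.

The lesion model is deliberately minimal: an ellipse with a sinusoidal
border perturbation sunk into a smooth low-frequency background field plus
Gaussian pixel noise. Inside the lesion, pigment lowers the mean intensity
by exactly the configured ``contrast`` (the profile is identically 1 in the
lesion core), which is what makes class-conditional statistics recoverable
in tests. Anomaly images are independent high-frequency noise fields,
disjoint by construction from any lesion fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset, write_dataset
from .exceptions import ConfigError, DataError

# Severity taxonomy 0-6: code-prefixed folder names sort into label order.
SEVERITY_CLASS_NAMES = [
    "0_actinic_keratosis",
    "1_basal_cell_carcinoma",
    "2_benign_keratosis",
    "3_dermatofibroma",
    "4_melanocytic_nevus",
    "5_melanoma",
    "6_squamous_cell_carcinoma",
]

# Base skin tone (RGB) and per-channel pigment drop weights (mean 1, so the
# channel-mean intensity drop inside the lesion core equals `contrast`).
_BASE_COLOR = np.array([0.92, 0.84, 0.78])
_DROP_WEIGHTS = np.array([0.95, 1.00, 1.05])


@dataclass(frozen=True)
class ClassParams:
    """Morphology parameters of one lesion class."""

    radius_frac: float  # lesion radius as a fraction of image side
    border_amp: float  # relative amplitude of the sinusoidal border wobble
    contrast: float  # mean intensity drop inside the lesion core
    texture_sd: float  # relative sd of the pigment texture field

    def validate(self) -> None:
        if not 0.0 < self.radius_frac <= 0.5:
            raise ConfigError(f"radius_frac must be in (0, 0.5], got {self.radius_frac}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ConfigError(f"contrast must be in [0, 1], got {self.contrast}")
        if self.border_amp < 0 or self.texture_sd < 0:
            raise ConfigError("border_amp and texture_sd must be non-negative")


def default_class_params(n_classes: int) -> tuple[ClassParams, ...]:
    """Default class grid: well-spread lesion radii crossed with alternating
    contrast/border/texture levels, so no two classes share both size and
    appearance. Radius carries most of the class signal because illumination-
    normalising enhancement deliberately flattens absolute contrast."""
    out = []
    for c in range(n_classes):
        t = c / max(n_classes - 1, 1)
        hi = c % 2 == 1  # alternate the appearance attributes
        out.append(
            ClassParams(
                radius_frac=0.08 + 0.36 * t,
                border_amp=0.18 if hi else 0.03,
                contrast=0.55 if hi else 0.30,
                texture_sd=0.20 if hi else 0.05,
            )
        )
    return tuple(out)


@dataclass(frozen=True)
class FixtureSpec:
    """Full description of a synthetic fixture dataset.

    Identical spec + seed arguments produce bit-identical images.
    ``center_box`` bounds the lesion-center position as fractions of the
    image side (x0, x1, y0, y1); narrowing it confines lesions to a known
    region, which the Grad-CAM localisation checks rely on.
    """

    image_size: int = 64
    n_classes: int = 7
    class_params: tuple[ClassParams, ...] = field(default=())
    background_noise_sd: float = 0.02
    seed: int = 0
    center_box: tuple[float, float, float, float] = (0.30, 0.70, 0.30, 0.70)

    def __post_init__(self):
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.image_size < 8:
            raise ConfigError(f"image_size must be >= 8, got {self.image_size}")
        if not self.class_params:
            object.__setattr__(self, "class_params", default_class_params(self.n_classes))
        if len(self.class_params) != self.n_classes:
            raise ConfigError(
                f"expected {self.n_classes} class_params, got {len(self.class_params)}"
            )
        for p in self.class_params:
            p.validate()

    def class_names(self) -> list[str]:
        if self.n_classes == 7:
            return list(SEVERITY_CLASS_NAMES)
        return [f"class_{c:02d}" for c in range(self.n_classes)]


@dataclass
class LesionSample:
    image: np.ndarray  # (H, W, 3) float in [0, 1]
    class_id: int
    center: tuple[float, float]  # (x, y) pixel coordinates
    core_mask: np.ndarray  # bool (H, W): pixels where the pigment profile is 1


def make_lesion_image(spec: FixtureSpec, class_id: int, seed: int) -> LesionSample:
    """Draw one lesion image for ``class_id`` from the class's morphology."""
    if not 0 <= class_id < spec.n_classes:
        raise DataError(
            f"class_id {class_id} out of range for {spec.n_classes} classes"
        )
    p = spec.class_params[class_id]
    s = spec.image_size
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, class_id, seed & 0x7FFFFFFF])

    yy, xx = np.mgrid[0:s, 0:s].astype(float)

    # smooth background field: two low-frequency cosine waves
    bg = np.zeros((s, s))
    for _ in range(2):
        fx, fy = rng.uniform(0.5, 1.5, size=2) / s
        ph = rng.uniform(0, 2 * math.pi)
        bg += np.cos(2 * math.pi * (fx * xx + fy * yy) + ph)
    field = 0.97 + 0.03 * (bg / 2.0)  # in [0.94, 1.0]

    # lesion geometry: perturbed ellipse
    x0, x1, y0, y1 = spec.center_box
    cx = rng.uniform(x0, x1) * s
    cy = rng.uniform(y0, y1) * s
    r0 = p.radius_frac * s
    axis_ratio = rng.uniform(0.7, 1.0)
    rot = rng.uniform(0, math.pi)
    lobes = 3 + class_id  # border wobble frequency is part of the class morphology
    ph_b = rng.uniform(0, 2 * math.pi)

    dx, dy = xx - cx, yy - cy
    xr = dx * math.cos(rot) + dy * math.sin(rot)
    yr = (-dx * math.sin(rot) + dy * math.cos(rot)) / axis_ratio
    rr = np.hypot(xr, yr)
    theta = np.arctan2(yr, xr)
    boundary = r0 * (1.0 + p.border_amp * np.sin(lobes * theta + ph_b))
    edge_w = max(1.0, 0.08 * r0)
    profile = np.clip((boundary - rr) / edge_w, 0.0, 1.0)

    texture = rng.normal(0.0, p.texture_sd, size=(s, s))
    drop = profile * p.contrast * (1.0 + texture)

    img = _BASE_COLOR[None, None, :] * field[..., None] - drop[..., None] * _DROP_WEIGHTS
    img += rng.normal(0.0, spec.background_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    return LesionSample(
        image=img,
        class_id=class_id,
        center=(cx, cy),
        core_mask=profile >= 1.0,
    )


def make_dataset(
    spec: FixtureSpec,
    counts_per_class: list[int],
    seed: int,
    root=None,
) -> LabeledDataset:
    """Generate ``counts_per_class[c]`` images per class.

    When ``root`` is given the dataset is also written as the conventional
    one-folder-per-class layout with a plain-text manifest.
    """
    if len(counts_per_class) != spec.n_classes:
        raise DataError(
            f"counts_per_class has {len(counts_per_class)} entries, "
            f"spec has {spec.n_classes} classes"
        )
    if any(c < 0 for c in counts_per_class):
        raise DataError("counts must be non-negative")
    if sum(counts_per_class) == 0:
        raise DataError("all class counts are zero")

    images, labels, meta = [], [], []
    idx = 0
    for c, count in enumerate(counts_per_class):
        for _ in range(count):
            sample = make_lesion_image(spec, c, seed=seed + idx)
            images.append(sample.image)
            labels.append(c)
            meta.append(
                {
                    "center": sample.center,
                    "core_mask": sample.core_mask,
                    "synthetic": False,
                }
            )
            idx += 1
    ds = LabeledDataset(
        images=images,
        labels=np.array(labels, dtype=int),
        class_names=spec.class_names(),
        metadata=meta,
    )
    if root is not None:
        write_dataset(ds, root)
    return ds


def make_anomaly_images(n: int, spec: FixtureSpec, seed: int) -> list[np.ndarray]:
    """High-frequency noise fields, disjoint from the lesion distribution."""
    if n < 1:
        raise DataError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, 0x5EED, seed & 0x7FFFFFFF])
    s = spec.image_size
    out = []
    for _ in range(n):
        img = rng.uniform(0.0, 1.0, size=(s, s, 3))
        out.append(img)
    return out
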