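"""Shared fixtures: session-scoped trained models so expensive training
runs once and is reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from cadskin.cae import AEConfig, train_cae
from cadskin.data import split_dataset
from cadskin.fixtures import FixtureSpec, make_dataset


@pytest.fixture(scope="session")
def lesion_dataset_4c():
    """200 lesion images, 4 classes, 64 px (the small training corpus)."""
    spec = FixtureSpec(image_size=64, n_classes=4, seed=5)
    return spec, make_dataset(spec, [50] * 4, seed=0)


@pytest.fixture(scope="session")
def trained_small_cae(lesion_dataset_4c):
    """Autoencoder trained for 10 epochs on the 200-image corpus."""
    spec, ds = lesion_dataset_4c
    split = split_dataset(ds, 0.8, seed=0)
    cfg = AEConfig(
        input_size=64, n_classes=4, epochs=10, seed=0, encoder_widths=(16, 32, 64)
    )
    model, history = train_cae(split.train, split.validation, cfg)
    return {"spec": spec, "split": split, "cfg": cfg, "model": model, "history": history}


@pytest.fixture(scope="session")
def gradcam_model():
    """Autoencoder trained on fixtures with lesion centers spanning the frame,
    so saliency can be probed at off-center positions."""
    spec = FixtureSpec(
        image_size=64, n_classes=4, seed=5, center_box=(0.2, 0.8, 0.2, 0.8)
    )
    ds = make_dataset(spec, [50] * 4, seed=0)
    split = split_dataset(ds, 0.8, seed=0)
    cfg = AEConfig(
        input_size=64, n_classes=4, epochs=15, seed=0, encoder_widths=(16, 32, 64)
    )
    model, history = train_cae(split.train, split.validation, cfg)
    return {"spec": spec, "cfg": cfg, "model": model, "history": history}


def dense_gaussian_blur(img2d: np.ndarray, sigma: float, truncate: float = 4.0):
    """Brute-force separable Gaussian with explicit kernel and symmetric
    (edge-repeating) padding — the independent convolution oracle."""
    r = int(truncate * sigma + 0.5)
    t = np.arange(-r, r + 1)
    k1 = np.exp(-0.5 * (t / sigma) ** 2)
    k1 /= k1.sum()
    pad = np.pad(img2d, r, mode="symmetric")
    tmp = np.zeros_like(pad)
    for i, w in enumerate(k1):
        tmp += w * np.roll(pad, r - i, axis=0)
    out = np.zeros_like(pad)
    for i, w in enumerate(k1):
        out += w * np.roll(tmp, r - i, axis=1)
    return out[r:-r, r:-r]


def blur_rgb(img: np.ndarray, sigma: float) -> np.ndarray:
    return np.stack(
        [dense_gaussian_blur(img[..., c], sigma) for c in range(img.shape[2])], axis=-1
    )
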