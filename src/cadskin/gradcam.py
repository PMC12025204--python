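"""Grad-CAM saliency maps over the autoencoder's classification pathway.

The gradient of the target class's pre-softmax logit is backpropagated to a
convolutional layer on the encoder path; channel weights are the spatial
means of those gradients, and the heatmap is the rectified weighted sum of
the channel activations, bilinearly upsampled to the input grid and
max-normalised (an all-zero map is returned as-is).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from . import nn
from .cae import AEModel, _as_batch
from .data import bilinear_resize
from .exceptions import ConfigError, ShapeError


@dataclass
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1]
    class_id: int
    layer: str


def gradcam(
    model: AEModel, img: np.ndarray, class_id: int, layer: int | None = None
) -> Heatmap:
    """Class-activation heatmap for ``class_id`` at an encoder conv layer.

    ``layer`` indexes the encoder's convolutional layers (0 = first conv);
    the default is the last one, standard Grad-CAM practice.
    """
    cfg = model.cfg
    if not 0 <= class_id < cfg.n_classes:
        raise ConfigError(f"class_id {class_id} out of range")
    conv_positions = model.conv_layer_indices
    if layer is None:
        layer = len(conv_positions) - 1
    if not 0 <= layer < len(conv_positions):
        raise ConfigError(
            f"layer must index one of {len(conv_positions)} encoder conv layers"
        )
    layer_index = conv_positions[layer]
    if not isinstance(model.encoder.layers[layer_index], nn.Conv2D):
        raise ConfigError("target layer is not a convolution")

    x, single = _as_batch(img, cfg.input_size)
    if not single:
        raise ShapeError("gradcam expects a single image")

    z = model.encoder.forward(x, train=False)
    logits = model.head.forward(z, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, class_id] = 1.0
    dz = model.head.backward(dlogits)
    grad = model.encoder.backward_to(dz.reshape(z.shape), layer_index)
    act = model.encoder.output_of(layer_index)

    weights = grad[0].mean(axis=(0, 1))  # (C,)
    cam = np.maximum((act[0] * weights).sum(axis=-1), 0.0)
    cam = bilinear_resize(cam[..., None], cfg.input_size, cfg.input_size)[..., 0]
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(values=cam, class_id=class_id, layer=f"conv{layer}")


def overlay(img: np.ndarray, heatmap: Heatmap, alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend a colormapped heatmap onto the image."""
    img = np.asarray(img, dtype=float)
    if img.shape[:2] != heatmap.values.shape:
        raise ShapeError(
            f"image {img.shape[:2]} and heatmap {heatmap.values.shape} differ"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ConfigError(f"alpha must be in [0,1], got {alpha}")
    colors = colormaps["jet"](heatmap.values)[..., :3]
    return np.clip((1.0 - alpha) * img + alpha * colors, 0.0, 1.0)


def quadrant_mass(heatmap: Heatmap, quadrant: tuple[int, int]) -> float:
    """Fraction of total heatmap mass inside one quadrant (row-half, col-half)."""
    v = heatmap.values
    total = v.sum()
    if total <= 0:
        return 0.0
    h2, w2 = v.shape[0] // 2, v.shape[1] // 2
    r, c = quadrant
    rows = slice(0, h2) if r == 0 else slice(h2, v.shape[0])
    cols = slice(0, w2) if c == 0 else slice(w2, v.shape[1])
    return float(v[rows, cols].sum() / total)
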