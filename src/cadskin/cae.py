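"""Convolutional autoencoder with classification head and anomaly detection.

The encoder stacks 3x3 convolutions (ReLU) each followed by 2x2/stride-2 max
pooling; the decoder mirrors it with nearest-neighbour up-sampling and ends
in a sigmoid, so reconstructions live in (0, 1). The decoder always contains
exactly two up-sampling stages: its output grid is 4x the bottleneck grid
(the super-resolution reading), which equals the input grid for the default
two-stage encoder. A flatten -> dense ReLU (dropout) -> softmax head turns
the bottleneck code into class probabilities.

Training minimises

    recon_loss_weight * BCE(x, x_hat) + class_loss_weight * CE(y, p)

with L2 weight regularisation, using Adam. Reconstruction error (mean
absolute pixel distance) on a trained model separates in-distribution images
from anomalies; the flagging threshold is mean + k * sd of training errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .data import LabeledDataset, bilinear_resize
from .exceptions import ConfigError, DataError, ShapeError, TrainingError


@dataclass
class AEConfig:
    input_size: int = 64
    encoder_widths: tuple[int, ...] = (32, 64)
    dense_units: int = 64
    n_classes: int = 7
    learning_rate: float = 0.001
    epochs: int = 50
    batch_size: int = 32
    l2_weight: float = 0.01
    dropout: float = 0.5
    recon_loss_weight: float = 1.0
    class_loss_weight: float = 1.0
    bce_epsilon: float = 1e-7
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ConfigError("learning rate, batch size and epochs must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0,1), got {self.dropout}")
        if self.l2_weight < 0 or self.recon_loss_weight < 0 or self.class_loss_weight < 0:
            raise ConfigError("loss weights must be non-negative")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        n_pool = len(self.encoder_widths)
        if self.input_size % (2**n_pool) != 0:
            raise ConfigError(
                f"input_size {self.input_size} not divisible by 2^{n_pool}"
            )

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // (2 ** len(self.encoder_widths))

    @property
    def bottleneck_channels(self) -> int:
        return self.encoder_widths[-1]

    @property
    def latent_dim(self) -> int:
        return self.bottleneck_size**2 * self.bottleneck_channels


@dataclass
class AEModel:
    encoder: nn.Sequential
    decoder: nn.Sequential
    head: nn.Sequential
    cfg: AEConfig
    conv_layer_indices: list[int]  # indices of Conv2D layers inside encoder

    def param_count(self) -> int:
        return sum(
            p.size for p in self.encoder.params + self.decoder.params + self.head.params
        )

    @property
    def all_params(self) -> list[np.ndarray]:
        return self.encoder.params + self.decoder.params + self.head.params

    @property
    def all_grads(self) -> list[np.ndarray]:
        return self.encoder.grads + self.decoder.grads + self.head.grads


def build_model(cfg: AEConfig) -> AEModel:
    """Deterministically initialised encoder/decoder/classifier triple."""
    cfg.validate()
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0xCAE])

    enc_layers: list[nn.Layer] = []
    conv_idx = []
    c = 3
    for w in cfg.encoder_widths:
        conv_idx.append(len(enc_layers))
        enc_layers += [nn.Conv2D(c, w, 3, rng), nn.ReLU(), nn.MaxPool2()]
        c = w

    # decoder: exactly two up-sampling stages (4x the bottleneck grid)
    c0 = cfg.bottleneck_channels
    c1 = max(c0 // 2, 8)
    c2 = max(c0 // 4, 8)
    dec_layers: list[nn.Layer] = [
        nn.Conv2D(c0, c1, 3, rng),
        nn.ReLU(),
        nn.Upsample2(),
        nn.Conv2D(c1, c2, 3, rng),
        nn.ReLU(),
        nn.Upsample2(),
        nn.Conv2D(c2, 3, 3, rng),  # linear; sigmoid applied at decode time
    ]

    head_layers: list[nn.Layer] = [
        nn.Flatten(),
        nn.Dense(cfg.latent_dim, cfg.dense_units, rng),
        nn.ReLU(),
        nn.Dropout(cfg.dropout, np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0xD09])),
        nn.Dense(cfg.dense_units, cfg.n_classes, rng),
    ]
    return AEModel(
        encoder=nn.Sequential(enc_layers),
        decoder=nn.Sequential(dec_layers),
        head=nn.Sequential(head_layers),
        cfg=cfg,
        conv_layer_indices=conv_idx,
    )


def _as_batch(img: np.ndarray, size: int) -> tuple[np.ndarray, bool]:
    arr = np.asarray(img, dtype=nn.FLOAT)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[1] != size or arr.shape[2] != size or arr.shape[3] != 3:
        raise ShapeError(
            f"expected ({size},{size},3) image(s), got array of shape {img.shape}"
        )
    return arr, single


def encode(model: AEModel, img: np.ndarray) -> np.ndarray:
    """Bottleneck activations z for one image or a batch."""
    x, single = _as_batch(img, model.cfg.input_size)
    z = model.encoder.forward(x, train=False)
    return z[0] if single else z


def decode(model: AEModel, z: np.ndarray) -> np.ndarray:
    """Sigmoid reconstruction on the 4x-bottleneck grid."""
    z = np.asarray(z, dtype=nn.FLOAT)
    single = z.ndim == 3
    if single:
        z = z[None]
    b, c = model.cfg.bottleneck_size, model.cfg.bottleneck_channels
    if z.shape[1:] != (b, b, c):
        raise ShapeError(f"latent code must be ({b},{b},{c}), got {z.shape[1:]}")
    xhat = nn.sigmoid(model.decoder.forward(z, train=False))
    return xhat[0] if single else xhat


def super_resolve(model: AEModel, img: np.ndarray) -> np.ndarray:
    """Encode + decode: the decoder output on the 4x-bottleneck grid."""
    return decode(model, encode(model, img))


def classify_proba(model: AEModel, img: np.ndarray) -> np.ndarray:
    """Softmax class probabilities from the bottleneck code."""
    z = encode(model, img)
    single = z.ndim == 3
    logits = model.head.forward(z[None] if single else z, train=False)
    p = nn.softmax(logits)
    return p[0] if single else p


def reconstruction_loss(x: np.ndarray, xhat: np.ndarray, eps: float = 1e-7) -> float:
    """Binary cross-entropy averaged over every pixel/channel element."""
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ShapeError(f"shape mismatch {x.shape} vs {xhat.shape}")
    xh = np.clip(xhat, eps, 1.0 - eps)
    return float(-np.mean(x * np.log(xh) + (1.0 - x) * np.log(1.0 - xh)))


def _class_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    return float(-np.mean(np.log(np.clip(p[np.arange(len(y)), y], eps, None))))


def _recon_target(xb: np.ndarray, out_size: int) -> np.ndarray:
    if xb.shape[1] == out_size:
        return xb
    return np.stack([bilinear_resize(im, out_size, out_size) for im in xb]).astype(
        nn.FLOAT
    )


def _eval_losses(model: AEModel, x: np.ndarray, y: np.ndarray, batch: int = 64):
    rec, cls, correct = 0.0, 0.0, 0
    out_size = 4 * model.cfg.bottleneck_size
    for s in range(0, len(x), batch):
        xb, yb = x[s : s + batch], y[s : s + batch]
        z = model.encoder.forward(xb, train=False)
        xhat = nn.sigmoid(model.decoder.forward(z, train=False))
        p = nn.softmax(model.head.forward(z, train=False))
        rec += reconstruction_loss(
            _recon_target(xb, out_size), xhat, model.cfg.bce_epsilon
        ) * len(xb)
        cls += _class_loss(p, yb) * len(xb)
        correct += int((p.argmax(axis=1) == yb).sum())
    n = len(x)
    return rec / n, cls / n, correct / n


def train_cae(
    train: LabeledDataset, val: LabeledDataset | None, cfg: AEConfig
) -> tuple[AEModel, dict]:
    """Joint reconstruction + classification training (Adam, L2, dropout)."""
    cfg.validate()
    if len(train) == 0:
        raise DataError("training dataset is empty")
    if train.labels.max() >= cfg.n_classes:
        raise DataError("training labels exceed n_classes")
    x = train.stacked()
    if x.shape[1] != cfg.input_size:
        raise ShapeError(
            f"training images are {x.shape[1]} px, config expects {cfg.input_size}"
        )
    y = train.labels
    xv = val.stacked() if val is not None and len(val) else None
    yv = val.labels if xv is not None else None

    model = build_model(cfg)
    opt = nn.Adam(
        model.all_params, lr=cfg.learning_rate, betas=(0.9, 0.999), l2=cfg.l2_weight
    )
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x7E41])
    history = {
        "learning_rate": cfg.learning_rate,
        "train_recon": [],
        "train_class": [],
        "val_recon": [],
        "val_class": [],
        "val_accuracy": [],
    }
    out_size = 4 * cfg.bottleneck_size
    w_rec, w_cls = cfg.recon_loss_weight, cfg.class_loss_weight

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x))
        ep_rec, ep_cls = 0.0, 0.0
        for s in range(0, len(x), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            target = _recon_target(xb, out_size)

            z = model.encoder.forward(xb, train=True)
            u = model.decoder.forward(z, train=True)
            xhat = nn.sigmoid(u)
            logits = model.head.forward(z, train=True)
            p = nn.softmax(logits)

            l_rec = reconstruction_loss(target, xhat, cfg.bce_epsilon)
            l_cls = _class_loss(p, yb)
            if not (np.isfinite(l_rec) and np.isfinite(l_cls)):
                raise TrainingError("non-finite training loss", step=epoch)

            du = (w_rec * (xhat - target) / target.size).astype(nn.FLOAT)
            dz_rec = model.decoder.backward(du)
            dlogits = p.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits *= w_cls / len(yb)
            dz_cls = model.head.backward(dlogits.astype(nn.FLOAT))
            model.encoder.backward(dz_rec + dz_cls.reshape(z.shape))
            opt.step(model.all_grads)
            ep_rec += l_rec * len(idx)
            ep_cls += l_cls * len(idx)

        history["train_recon"].append(ep_rec / len(x))
        history["train_class"].append(ep_cls / len(x))
        if xv is not None:
            vr, vc, va = _eval_losses(model, xv, yv)
            history["val_recon"].append(vr)
            history["val_class"].append(vc)
            history["val_accuracy"].append(va)
    return model, history


@dataclass
class ReconstructionReport:
    errors: np.ndarray
    threshold: float | None = None
    flags: np.ndarray | None = None


def anomaly_scores(model: AEModel, images) -> ReconstructionReport:
    """Mean absolute pixel distance between each image and its reconstruction."""
    if len(images) == 0:
        raise DataError("no images given")
    errors = []
    for img in images:
        x = np.asarray(img, dtype=float)
        xhat = super_resolve(model, x)
        if xhat.shape != x.shape:
            xhat = bilinear_resize(xhat, x.shape[0], x.shape[1])
        errors.append(float(np.mean(np.abs(x - xhat))))
    return ReconstructionReport(errors=np.array(errors))


def flag_anomalies(errors, k: float) -> ReconstructionReport:
    """Threshold at mean + k * sd of the supplied (training) errors."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 2:
        raise DataError("need at least 2 reconstruction errors")
    threshold = float(errors.mean() + k * errors.std())
    return ReconstructionReport(
        errors=errors, threshold=threshold, flags=errors > threshold
    )


def save_model(model: AEModel, path) -> None:
    """Array archive with a layer-name manifest and the config."""
    arrays = {}
    manifest = []
    for tag, seq in (
        ("encoder", model.encoder),
        ("decoder", model.decoder),
        ("head", model.head),
    ):
        for i, layer in enumerate(seq.layers):
            for j, p in enumerate(layer.params):
                key = f"{tag}_{i:02d}_{type(layer).__name__}_{j}"
                arrays[key] = p
                manifest.append(key)
    np.savez(
        path,
        manifest=np.array(manifest),
        config=np.array(json.dumps(asdict(model.cfg))),
        **arrays,
    )


def load_model(path) -> AEModel:
    with np.load(path) as archive:
        cfg_dict = json.loads(str(archive["config"]))
        cfg_dict["encoder_widths"] = tuple(cfg_dict["encoder_widths"])
        cfg = AEConfig(**cfg_dict)
        model = build_model(cfg)
        manifest = list(archive["manifest"])
        arrays = [archive[str(k)] for k in manifest]
    flat = model.all_params
    if len(arrays) != len(flat):
        raise ShapeError("archive parameter count does not match the model")
    for p, a in zip(flat, arrays):
        p[...] = a
    return model
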