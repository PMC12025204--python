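"""GAN-based minority-class balancing.

A small DCGAN-style generator/discriminator pair is trained per minority
class with the classic minimax value function

    V(D, G) = E_x[log D(x)] + E_z[log(1 - D(G(z)))]

by alternating stochastic-gradient steps: the discriminator ascends V, the
generator descends its log(1 - D(G(z))) term (a non-saturating -log D(G(z))
variant is available behind a flag for stability, off by default). Trained
generators synthesise images for under-represented classes until every class
matches the majority count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .data import LabeledDataset
from .exceptions import ConfigError, DataError, TrainingError


@dataclass
class GanConfig:
    latent_dim: int = 100
    image_size: int = 32
    channels: int = 3
    base_width: int = 32
    lr_g: float = 1e-3
    lr_d: float = 1e-3
    batch_size: int = 16
    steps: int = 500
    seed: int = 0
    logit_epsilon: float = 1e-7  # clamp for the log arguments of V(D, G)
    non_saturating: bool = False
    sample_interval: int = 0  # emit monitoring samples every k steps (0 = off)

    def validate(self) -> None:
        if self.latent_dim < 1:
            raise ConfigError(f"latent_dim must be >= 1, got {self.latent_dim}")
        if self.lr_g <= 0 or self.lr_d <= 0:
            raise ConfigError("learning rates must be > 0")
        if not 0.0 < self.logit_epsilon < 0.5:
            raise ConfigError("logit_epsilon must be in (0, 0.5)")
        n_up = math.log2(self.image_size / 4)
        if self.image_size < 8 or n_up != int(n_up):
            raise ConfigError(
                f"image_size must be 4 * 2^k with k >= 1, got {self.image_size}"
            )


def _build_generator(cfg: GanConfig, rng: np.random.Generator) -> nn.Sequential:
    n_up = int(math.log2(cfg.image_size / 4))
    w0 = cfg.base_width * 2 ** max(n_up - 1, 0)
    layers: list[nn.Layer] = [
        nn.Dense(cfg.latent_dim, 4 * 4 * w0, rng),
        nn.Reshape((4, 4, w0)),
        nn.ReLU(),
    ]
    c = w0
    for _ in range(n_up):
        c_next = max(c // 2, 8)
        layers += [nn.Upsample2(), nn.Conv2D(c, c_next, 3, rng), nn.ReLU()]
        c = c_next
    layers += [nn.Conv2D(c, cfg.channels, 3, rng), nn.Sigmoid()]
    return nn.Sequential(layers)


def _build_discriminator(cfg: GanConfig, rng: np.random.Generator) -> nn.Sequential:
    n_down = int(math.log2(cfg.image_size / 4))
    layers: list[nn.Layer] = []
    c = cfg.channels
    width = cfg.base_width // 2
    for _ in range(n_down):
        layers += [nn.Conv2D(c, width, 3, rng), nn.LeakyReLU(0.2), nn.MaxPool2()]
        c = width
        width *= 2
    layers += [nn.Flatten(), nn.Dense(4 * 4 * c, 1, rng)]
    return nn.Sequential(layers)


@dataclass
class GanState:
    """Generator + discriminator parameters and training bookkeeping."""

    generator: nn.Sequential
    discriminator: nn.Sequential
    cfg: GanConfig
    step: int = 0
    history: dict = field(default_factory=lambda: {"d_loss": [], "g_loss": [], "value": []})

    def d_proba(self, images: np.ndarray) -> np.ndarray:
        """Discriminator output D(x) in (0,1), clamped to [eps, 1-eps]."""
        logits = self.discriminator.forward(images.astype(nn.FLOAT))
        eps = self.cfg.logit_epsilon
        return np.clip(nn.sigmoid(logits)[:, 0], eps, 1.0 - eps)


def init_gan(cfg: GanConfig) -> GanState:
    cfg.validate()
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x6A4])
    return GanState(
        generator=_build_generator(cfg, rng),
        discriminator=_build_discriminator(cfg, rng),
        cfg=cfg,
    )


def gan_value(state: GanState, real_batch: np.ndarray, noise_batch: np.ndarray) -> float:
    """Empirical value function of the minimax game on the given batches."""
    if len(real_batch) == 0 or len(noise_batch) == 0:
        raise DataError("batches must be non-empty")
    fake = state.generator.forward(np.asarray(noise_batch, dtype=nn.FLOAT))
    p_real = state.d_proba(np.asarray(real_batch)).astype(np.float64)
    p_fake = state.d_proba(fake).astype(np.float64)
    return float(np.mean(np.log(p_real)) + np.mean(np.log(1.0 - p_fake)))


def train_gan(data, cfg: GanConfig) -> GanState:
    """Alternating minimax updates: D ascends V, then G descends its term."""
    cfg.validate()
    if isinstance(data, LabeledDataset):
        images = data.stacked()
    else:
        images = np.stack([np.asarray(im, dtype=nn.FLOAT) for im in data])
    if images.shape[1] != cfg.image_size or images.shape[2] != cfg.image_size:
        raise DataError(
            f"images are {images.shape[1]}x{images.shape[2]}, "
            f"config expects {cfg.image_size}"
        )
    state = init_gan(cfg)
    g, d = state.generator, state.discriminator
    opt_g = nn.Adam(g.params, lr=cfg.lr_g, betas=(0.5, 0.999))
    opt_d = nn.Adam(d.params, lr=cfg.lr_d, betas=(0.5, 0.999))
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x7A1])
    m = cfg.batch_size
    eps = cfg.logit_epsilon

    for step in range(cfg.steps):
        # --- discriminator: ascend log D(x) + log(1 - D(G(z)))
        real = images[rng.integers(0, len(images), size=m)]
        z = rng.standard_normal((m, cfg.latent_dim)).astype(nn.FLOAT)
        fake = g.forward(z, train=False)
        batch = np.concatenate([real, fake], axis=0)
        logits = d.forward(batch, train=True)[:, 0]
        p = nn.sigmoid(logits)
        pc = np.clip(p, eps, 1.0 - eps)
        d_loss = -(np.mean(np.log(pc[:m])) + np.mean(np.log(1.0 - pc[m:])))
        dlogit = np.empty_like(p)
        dlogit[:m] = (p[:m] - 1.0) / m
        dlogit[m:] = p[m:] / m
        d.backward(dlogit[:, None])
        opt_d.step(d.grads)

        # --- generator
        z = rng.standard_normal((m, cfg.latent_dim)).astype(nn.FLOAT)
        fake = g.forward(z, train=True)
        logits = d.forward(fake, train=True)[:, 0]
        p = nn.sigmoid(logits)
        pc = np.clip(p, eps, 1.0 - eps)
        if cfg.non_saturating:
            g_loss = -float(np.mean(np.log(pc)))
            dlogit = (p - 1.0) / m
        else:
            g_loss = float(np.mean(np.log(1.0 - pc)))
            dlogit = -p / m
        dfake = d.backward(dlogit[:, None])  # D gradients discarded (no opt step)
        g.backward(dfake)
        opt_g.step(g.grads)

        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise TrainingError("non-finite GAN loss", step=step)
        state.history["d_loss"].append(float(d_loss))
        state.history["g_loss"].append(float(g_loss))
        state.history["value"].append(-float(d_loss))
        state.step = step + 1
    return state


def generate(state: GanState, n: int, seed: int) -> np.ndarray:
    """n generator samples in [0,1], deterministic given the seed."""
    if n <= 0:
        raise DataError(f"n must be positive, got {n}")
    rng = np.random.default_rng([state.cfg.seed & 0x7FFFFFFF, 0x9E2, seed & 0x7FFFFFFF])
    out = []
    for start in range(0, n, 64):
        z = rng.standard_normal((min(64, n - start), state.cfg.latent_dim)).astype(nn.FLOAT)
        out.append(state.generator.forward(z))
    return np.concatenate(out, axis=0).astype(float)


def balance_dataset(
    ds: LabeledDataset, per_class_states: dict[int, GanState], seed: int
) -> LabeledDataset:
    """Top up every class to the majority count with generator samples.

    Original items are kept untouched; synthetic items carry
    ``metadata['synthetic'] = True``.
    """
    counts = ds.class_counts()
    target = int(counts.max())
    if (counts == target).all():
        return ds
    images = list(ds.images)
    labels = list(ds.labels)
    meta = [dict(m) for m in ds.metadata]
    for c in range(ds.n_classes):
        deficit = target - int(counts[c])
        if deficit <= 0:
            continue
        if c not in per_class_states:
            raise DataError(f"no GAN state provided for deficient class {c}")
        fakes = generate(per_class_states[c], deficit, seed=seed + c)
        for im in fakes:
            images.append(np.asarray(im, dtype=float))
            labels.append(c)
            meta.append({"synthetic": True})
    return LabeledDataset(images, np.array(labels), list(ds.class_names), meta)


def save_gan(state: GanState, path) -> None:
    """Persist generator/discriminator parameters as an array archive."""
    arrays = {}
    for tag, seq in (("g", state.generator), ("d", state.discriminator)):
        for i, p in enumerate(seq.params):
            arrays[f"{tag}_{i:03d}"] = p
    np.savez(path, step=state.step, **arrays)


def load_gan(path, cfg: GanConfig) -> GanState:
    state = init_gan(cfg)
    with np.load(path) as archive:
        for tag, seq in (("g", state.generator), ("d", state.discriminator)):
            arrays = [archive[f"{tag}_{i:03d}"] for i in range(len(seq.params))]
            seq.load_state(arrays)
        state.step = int(archive["step"])
    return state
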