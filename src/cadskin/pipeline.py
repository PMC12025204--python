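"""End-to-end orchestration: data -> enhancement -> (optional) GAN balancing
-> stratified split -> autoencoder training -> latent extraction -> feature
reduction -> kernel SVM -> evaluation.

One global seed deterministically derives every stage seed, so re-running
with the same configuration reproduces the report bit for bit. GAN balancing
is applied to the training partition only, which keeps synthetic images out
of the validation set.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import cae, gan, qsvm
from .metrics import confusion, metrics as compute_metrics
from .config import PipelineConfig, config_to_dict
from .data import LabeledDataset, load_folder_dataset, resize_normalize, split_dataset
from .enhance import enhance_pipeline
from .exceptions import CadSkinError
from .fixtures import FixtureSpec, make_dataset

log = logging.getLogger("cadskin")


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["fixtures", "split", "gan", "balance", "cae"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] & 0x7FFFFFFF) for n, c in zip(names, children)}


def _log_stage(name: str, verbosity: int) -> None:
    if verbosity > 0:
        log.info("[%s] %s", time.strftime("%H:%M:%S"), name)


def _latents(model, ds: LabeledDataset, batch: int = 64) -> np.ndarray:
    chunks = []
    x = ds.stacked()
    for s in range(0, len(x), batch):
        z = cae.encode(model, x[s : s + batch])
        chunks.append(z.reshape(len(z), -1))
    return np.concatenate(chunks, axis=0).astype(float)


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> dict:
    """Execute every stage and return (and optionally write) the run report."""
    cfg.validate()
    seeds = _stage_seeds(cfg.seed)
    report: dict = {"seed": cfg.seed, "stage_seeds": seeds}

    try:
        # ---- data
        _log_stage("load/generate dataset", cfg.verbosity)
        dc = cfg.dataset
        if dc.root is not None:
            ds = load_folder_dataset(dc.root)
            ds = LabeledDataset(
                images=[resize_normalize(im, dc.image_size) for im in ds.images],
                labels=ds.labels,
                class_names=ds.class_names,
                metadata=ds.metadata,
            )
        else:
            spec = FixtureSpec(
                image_size=dc.image_size,
                n_classes=dc.n_classes,
                background_noise_sd=dc.background_noise_sd,
                seed=seeds["fixtures"],
            )
            counts = list(dc.counts_per_class or [70] * dc.n_classes)
            ds = make_dataset(spec, counts, seed=seeds["fixtures"])
        if dc.permute_labels:
            # negative control: any residual accuracy is leakage, not signal
            perm_rng = np.random.default_rng(seeds["fixtures"] ^ 0x5A5A5A)
            ds = LabeledDataset(
                images=ds.images,
                labels=perm_rng.permutation(ds.labels),
                class_names=ds.class_names,
                metadata=ds.metadata,
            )
        report["n_images"] = len(ds)
        report["class_counts"] = ds.class_counts().tolist()

        # ---- enhancement (one consistent image space for GAN and CAE)
        if cfg.enhance_enabled:
            _log_stage("enhancement", cfg.verbosity)
            ds = LabeledDataset(
                images=[enhance_pipeline(im, cfg.enhance) for im in ds.images],
                labels=ds.labels,
                class_names=ds.class_names,
                metadata=ds.metadata,
            )

        # ---- split, then balance the training partition only
        _log_stage("stratified split", cfg.verbosity)
        split = split_dataset(ds, cfg.split_fraction, seed=seeds["split"])
        train, val = split.train, split.validation

        if cfg.gan_enabled:
            _log_stage("GAN balancing", cfg.verbosity)
            counts = train.class_counts()
            states = {}
            for c in range(train.n_classes):
                if counts[c] < counts.max():
                    gcfg = gan.GanConfig(
                        **{
                            **config_to_dict(cfg)["gan"],
                            "image_size": dc.image_size,
                            "seed": seeds["gan"] + c,
                        }
                    )
                    imgs = [train.images[i] for i in np.flatnonzero(train.labels == c)]
                    states[c] = gan.train_gan(imgs, gcfg)
            train = gan.balance_dataset(train, states, seed=seeds["balance"])
            report["balanced_class_counts"] = train.class_counts().tolist()

        # ---- autoencoder
        _log_stage("train autoencoder", cfg.verbosity)
        ae_cfg = cae.AEConfig(
            **{
                **{
                    k: v
                    for k, v in config_to_dict(cfg)["cae"].items()
                    if k != "encoder_widths"
                },
                "input_size": dc.image_size,
                "n_classes": ds.n_classes,
                "seed": seeds["cae"],
            },
            encoder_widths=cfg.cae.encoder_widths,
        )
        model, history = cae.train_cae(train, val, ae_cfg)
        report["cae_history"] = {
            "learning_rate": history["learning_rate"],
            "final_train_recon": history["train_recon"][-1] if history["train_recon"] else None,
            "final_val_accuracy": history["val_accuracy"][-1] if history["val_accuracy"] else None,
        }

        # ---- latent features -> reduced features -> QSVM
        _log_stage("latent extraction + feature reduction", cfg.verbosity)
        z_train = _latents(model, train)
        z_val = _latents(model, val)
        x_train, projection = qsvm.reduce_features(z_train, cfg.kernel.n_qubits)
        x_val = projection.transform(z_val)

        _log_stage("fit kernel SVM", cfg.verbosity)
        svm = qsvm.fit_qsvm(x_train, train.labels, cfg.kernel, C=cfg.svm_c)
        y_pred, _ = qsvm.predict(svm, x_val)

        # ---- evaluation
        _log_stage("evaluation", cfg.verbosity)
        cm = confusion(val.labels, y_pred, ds.n_classes)
        rep = compute_metrics(cm)
        proba = cae.classify_proba(model, val.stacked())
        baseline_acc = float((proba.argmax(axis=1) == val.labels).mean())

        report["confusion_matrix"] = cm.counts.tolist()
        report["metrics"] = rep.as_dict()
        report["softmax_baseline_accuracy"] = baseline_acc
        report["n_train"] = len(train)
        report["n_validation"] = len(val)
    except CadSkinError as exc:
        log.error("pipeline failed: %s", exc)
        raise

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "metrics.tsv").write_text(rep.to_text(ds.class_names) + "\n")
        _write_confusion_png(cm, ds.class_names, out / "confusion.png")
        cae.save_model(model, out / "cae_model.npz")
        qsvm.save_qsvm(svm, out / "qsvm_model.npz", projection=projection)
    return report


def _write_confusion_png(cm, class_names, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(cm.counts, cmap="Blues")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_xticks(range(len(class_names)))
    ax.set_yticks(range(len(class_names)))
    ax.set_xticklabels(class_names, rotation=90, fontsize=6)
    ax.set_yticklabels(class_names, fontsize=6)
    for (i, j), v in np.ndenumerate(cm.counts):
        ax.text(j, i, str(v), ha="center", va="center", fontsize=6)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
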