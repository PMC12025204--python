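"""Class-folder image datasets: loading, writing, resizing, stratified splits.

The on-disk convention is one sub-folder per class under a root directory;
classes are assigned indices by lexicographic folder order, so folders named
with a severity-code prefix (``0_actinic_keratosis`` ... ``6_squamous_cell_
carcinoma``) map to their severity codes. An 80/20 stratified split with a
fixed seed is the default evaluation protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from sklearn.model_selection import train_test_split

from .exceptions import ConfigError, DataError

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".bmp"}


@dataclass
class LabeledDataset:
    """Ordered collection of (image, class index) with class names.

    Images are (H, W, 3) float arrays in [0, 1]. ``metadata`` carries one
    dict per item (lesion center, synthetic flag, source path, ...).
    """

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    metadata: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise DataError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        if len(set(self.class_names)) != len(self.class_names):
            raise DataError("class names must be unique")
        k = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= k):
            raise DataError(f"labels must lie in 0..{k - 1}")
        if not self.metadata:
            self.metadata = [{} for _ in self.images]
        if len(self.metadata) != len(self.images):
            raise DataError("metadata length must match image count")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices) -> "LabeledDataset":
        indices = np.asarray(indices, dtype=int)
        return LabeledDataset(
            images=[self.images[i] for i in indices],
            labels=self.labels[indices],
            class_names=list(self.class_names),
            metadata=[self.metadata[i] for i in indices],
        )

    def stacked(self) -> np.ndarray:
        return np.stack(self.images).astype(np.float32)


@dataclass
class SplitResult:
    train: LabeledDataset
    validation: LabeledDataset
    seed: int
    train_fraction: float


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / np.iinfo(arr.dtype).max
    return np.clip(arr.astype(float), 0.0, 1.0)


def _ensure_rgb(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    if img.ndim != 3 or img.shape[2] < 3:
        raise DataError(f"expected HxW or HxWx3 image, got shape {img.shape}")
    return img[..., :3]


def load_folder_dataset(root, permissive: bool = False) -> LabeledDataset:
    """Load a one-folder-per-class dataset; classes sorted lexicographically."""
    root = Path(root)
    if not root.is_dir():
        raise DataError(f"dataset root {root} does not exist")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise DataError(f"dataset root {root} contains no class folders")

    images, labels, meta, skipped = [], [], [], []
    class_names = [d.name for d in class_dirs]
    for ci, d in enumerate(class_dirs):
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in _IMAGE_SUFFIXES:
                continue
            try:
                with Image.open(f) as im:
                    arr = np.asarray(im.convert("RGB"))
            except (UnidentifiedImageError, OSError) as exc:
                if permissive:
                    skipped.append(str(f))
                    continue
                raise DataError(f"undecodable image file {f}: {exc}") from exc
            images.append(_to_unit_float(arr))
            labels.append(ci)
            meta.append({"path": str(f), "synthetic": False})
    if not images:
        raise DataError(f"no decodable images under {root}")
    ds = LabeledDataset(images, np.array(labels), class_names, meta)
    if skipped:
        ds.skipped_files = skipped
    return ds


def write_dataset(ds: LabeledDataset, root) -> Path:
    """Write PNGs into ``root/<class_name>/img_<k>.png`` plus a manifest."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    lines = []
    counters = {c: 0 for c in range(ds.n_classes)}
    for img, label, meta in zip(ds.images, ds.labels, ds.metadata):
        cname = ds.class_names[label]
        cdir = root / cname
        cdir.mkdir(exist_ok=True)
        k = counters[int(label)]
        counters[int(label)] += 1
        path = cdir / f"img_{k:05d}.png"
        arr = np.clip(np.asarray(img) * 255.0 + 0.5, 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)
        cx, cy = meta.get("center", (float("nan"), float("nan")))
        lines.append(f"{path.relative_to(root)}\t{int(label)}\t{cx:.2f}\t{cy:.2f}")
    (root / "manifest.txt").write_text("\n".join(lines) + "\n")
    return root


def bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Pure bilinear resampling with half-pixel-center coordinate mapping."""
    in_h, in_w = img.shape[:2]
    if (in_h, in_w) == (out_h, out_w):
        return img.copy()

    def axis_coords(n_in, n_out):
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0, n_in - 1)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        return lo, hi, (src - lo)

    r0, r1, fr = axis_coords(in_h, out_h)
    c0, c1, fc = axis_coords(in_w, out_w)
    top = img[r0][:, c0] * (1 - fc)[None, :, None] + img[r0][:, c1] * fc[None, :, None]
    bot = img[r1][:, c0] * (1 - fc)[None, :, None] + img[r1][:, c1] * fc[None, :, None]
    return top * (1 - fr)[:, None, None] + bot * fr[:, None, None]


def resize_normalize(img: np.ndarray, size: int) -> np.ndarray:
    """Resize to size x size x 3 with bilinear interpolation, values in [0,1]."""
    if size < 8:
        raise ConfigError(f"size must be >= 8, got {size}")
    if not isinstance(img, np.ndarray) or img.ndim not in (2, 3):
        raise DataError("input must be an HxW or HxWxC array")
    img = _ensure_rgb(_to_unit_float(np.asarray(img)))
    return np.clip(bilinear_resize(img, size, size), 0.0, 1.0)


def split_dataset(ds: LabeledDataset, train_fraction: float, seed: int) -> SplitResult:
    """Seeded stratified split; per-class train counts within 1 of the fraction."""
    if not 0.0 < train_fraction < 1.0:
        raise ConfigError(f"train_fraction must be in (0,1), got {train_fraction}")
    counts = ds.class_counts()
    present = counts > 0
    if (counts[present] < 2).any():
        raise DataError("stratified splitting requires >= 2 items per class")
    idx = np.arange(len(ds))
    try:
        tr_idx, va_idx = train_test_split(
            idx,
            train_size=train_fraction,
            stratify=ds.labels,
            random_state=int(seed) % (2**32 - 1),
            shuffle=True,
        )
    except ValueError as exc:  # e.g. validation share smaller than class count
        raise DataError(f"stratified split infeasible: {exc}") from exc
    return SplitResult(
        train=ds.subset(np.sort(tr_idx)),
        validation=ds.subset(np.sort(va_idx)),
        seed=seed,
        train_fraction=train_fraction,
    )
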