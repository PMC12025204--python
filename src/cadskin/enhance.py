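"""Image enhancement chain: multi-scale retinex, gamma correction, histogram
equalization, unsharp masking and CLAHE, plus the composed pipeline.

Operators consume and return (H, W, 3) float images in [0, 1] (single-channel
arrays are accepted for the histogram operators). Conventions:

* Multi-scale retinex: R = sum_s w_s (log(I + eps) - log(G_sigma_s * I + eps))
  per channel, with Gaussian surrounds (reflect boundary), followed by a
  min-max rescale to [0, 1] over the whole response.
* Histogram equalization maps a level v to round_half_up((L-1)/(M N) *
  cumulative count up to v). On colour images the mapping is computed on the
  ITU-R 601 luminance and the luminance delta is added to all channels, which
  preserves the chrominance differences (B-Y, R-Y).
* A constant image is returned unchanged by HE/CLAHE (degenerate histogram);
  the raw formula would send everything to L-1 and destroy the image.
* CLAHE follows the classic tile scheme: clipped per-tile histograms (excess
  redistributed uniformly), per-tile equalization maps, bilinear interpolation
  between the four neighbouring tile maps with clamping at the borders. One
  tile with a clip limit at least the tile pixel count reduces to global HE.
* Rounding is half-up everywhere for cross-platform determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigError, ShapeError

REC601 = np.array([0.299, 0.587, 0.114])

DEFAULT_STAGE_ORDER = ("crop", "retinex", "gamma", "hist_eq", "unsharp", "clahe")


@dataclass
class EnhanceConfig:
    """Parameters of the enhancement chain.

    ``retinex_scales=None`` selects the conventional multi-scale-retinex
    sigmas {15, 80, 250} scaled by image_size/256 at call time; weights
    default to equal. ``clahe_clip`` is a multiple of the uniform histogram
    level (clip count = clip * tile_pixels / levels), the usual convention.
    """

    retinex_scales: tuple[float, ...] | None = None
    retinex_weights: tuple[float, ...] | None = None
    log_epsilon: float = 1.0 / 255.0
    gamma: float = 0.9
    levels: int = 256
    unsharp_k: float = 1.0
    unsharp_sigma: float = 1.0
    clahe_clip: float = 2.0
    clahe_tiles: tuple[int, int] = (8, 8)
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER
    crop_box: tuple[int, int, int, int] | None = None

    def validate(self) -> None:
        if self.retinex_scales is not None:
            if any(s <= 0 for s in self.retinex_scales):
                raise ConfigError("retinex scales must be positive")
            if self.retinex_weights is not None:
                if len(self.retinex_weights) != len(self.retinex_scales):
                    raise ConfigError("retinex scales/weights length mismatch")
                if abs(sum(self.retinex_weights) - 1.0) > 1e-9:
                    raise ConfigError("retinex weights must sum to 1")
        if self.gamma <= 0:
            raise ConfigError(f"gamma must be > 0, got {self.gamma}")
        if self.unsharp_k < 0:
            raise ConfigError(f"unsharp gain k must be >= 0, got {self.unsharp_k}")
        if self.levels < 2:
            raise ConfigError(f"levels must be >= 2, got {self.levels}")
        if self.clahe_clip <= 0:
            raise ConfigError("CLAHE clip limit must be > 0")
        if self.clahe_tiles[0] < 1 or self.clahe_tiles[1] < 1:
            raise ConfigError("CLAHE tile grid must be >= (1,1)")
        unknown = set(self.stage_order) - set(DEFAULT_STAGE_ORDER)
        if unknown:
            raise ConfigError(f"unknown pipeline stages: {sorted(unknown)}")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def _quantize(img: np.ndarray, levels: int) -> np.ndarray:
    return np.clip(_round_half_up(np.clip(img, 0.0, 1.0) * (levels - 1)), 0, levels - 1)


def luminance(img: np.ndarray) -> np.ndarray:
    return img @ REC601


def _apply_on_luminance(img: np.ndarray, fn) -> np.ndarray:
    """Run a grayscale mapping on Y and add the delta to every channel."""
    if img.ndim == 2:
        return fn(img)
    y = luminance(img)
    dy = fn(y) - y
    return np.clip(img + dy[..., None], 0.0, 1.0)


def _resolved_scales(cfg: EnhanceConfig, size: int):
    if cfg.retinex_scales is not None:
        scales = tuple(cfg.retinex_scales)
    else:
        scales = tuple(s * size / 256.0 for s in (15.0, 80.0, 250.0))
    if cfg.retinex_weights is not None:
        weights = tuple(cfg.retinex_weights)
    else:
        weights = tuple(1.0 / len(scales) for _ in scales)
    if len(weights) != len(scales):
        raise ConfigError("retinex scales/weights length mismatch")
    return scales, weights


def multiscale_retinex(
    img: np.ndarray, cfg: EnhanceConfig, rescale: bool = True
) -> np.ndarray:
    """Weighted sum of log(I+eps) - log(surround+eps) over Gaussian scales."""
    cfg.validate()
    img = np.asarray(img, dtype=float)
    scales, weights = _resolved_scales(cfg, max(img.shape[:2]))
    eps = cfg.log_epsilon
    out = np.zeros_like(img)
    log_i = np.log(img + eps)
    spatial_sigma = (lambda s: (s, s, 0)) if img.ndim == 3 else (lambda s: s)
    for sigma, w in zip(scales, weights):
        surround = gaussian_filter(img, sigma=spatial_sigma(sigma), mode="reflect")
        out += w * (log_i - np.log(surround + eps))
    if not rescale:
        return out
    lo, hi = out.min(), out.max()
    if hi - lo < 1e-12:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def gamma_correct(img: np.ndarray, gamma: float) -> np.ndarray:
    """Power-law mapping O = I^gamma on normalized intensities."""
    if gamma <= 0:
        raise ConfigError(f"gamma must be > 0, got {gamma}")
    return np.clip(np.asarray(img, dtype=float), 0.0, 1.0) ** gamma


def _he_gray(y: np.ndarray, levels: int) -> np.ndarray:
    q = _quantize(y, levels)
    if q.min() == q.max():  # degenerate histogram: leave unchanged
        return y.copy()
    counts = np.bincount(q.ravel(), minlength=levels)
    cdf = np.cumsum(counts)
    mapping = _round_half_up((levels - 1) * cdf / q.size)
    return mapping[q] / (levels - 1)


def hist_equalize(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Global histogram equalization via the CDF mapping T(v)."""
    if levels < 2:
        raise ConfigError(f"levels must be >= 2, got {levels}")
    img = np.asarray(img, dtype=float)
    return _apply_on_luminance(img, lambda y: _he_gray(y, levels))


def unsharp_mask(img: np.ndarray, cfg: EnhanceConfig) -> np.ndarray:
    """O = clip(I + k (I - G_sigma * I))."""
    cfg.validate()
    img = np.asarray(img, dtype=float)
    sigma = cfg.unsharp_sigma
    spatial = (sigma, sigma, 0) if img.ndim == 3 else sigma
    blurred = gaussian_filter(img, sigma=spatial, mode="reflect")
    return np.clip(img + cfg.unsharp_k * (img - blurred), 0.0, 1.0)


def _clip_histogram(counts: np.ndarray, clip_count: int) -> np.ndarray:
    """Clip and redistribute excess counts (classic Zuiderveld scheme).

    The excess is first spread uniformly over bins with enough headroom, then
    the integer remainder is handed out one count at a time over the bins
    still below the clip limit.
    """
    hist = counts.astype(np.int64).copy()
    clip_count = int(clip_count)
    excess = int(np.maximum(hist - clip_count, 0).sum())
    if excess == 0:
        return hist
    n = hist.size
    bin_incr = excess // n
    upper = clip_count - bin_incr
    low = hist < upper
    excess -= int(low.sum()) * bin_incr
    mid = (hist >= upper) & (hist < clip_count)
    excess -= int((clip_count - hist[mid]).sum())
    hist[low] += bin_incr
    hist[mid] = clip_count
    hist[hist > clip_count] = clip_count
    while excess > 0:
        prev = excess
        for start in range(n):
            under = hist < clip_count
            step = max(1, int(under.sum()) // excess) if excess else 1
            sel = under[start::step]
            hist[start::step] += sel
            excess -= int(sel.sum())
            if excess <= 0:
                break
        if excess == prev:
            break
    return hist


def _clahe_gray(y: np.ndarray, levels: int, clip: float, tiles: tuple[int, int]) -> np.ndarray:
    h, w = y.shape
    rows, cols = tiles
    if rows > h or cols > w:
        raise ConfigError(f"tile grid {tiles} larger than image {y.shape}")
    q = _quantize(y, levels)
    if q.min() == q.max():
        return y.copy()

    kh = -(-h // rows)  # ceil
    kw = -(-w // cols)
    qp = np.pad(q, ((0, rows * kh - h), (0, cols * kw - w)), mode="reflect")

    tile_pixels = kh * kw
    clip_count = max(1, int(clip * tile_pixels / levels))
    # per-tile clipped-histogram equalization maps
    blocks = qp.reshape(rows, kh, cols, kw).transpose(0, 2, 1, 3).reshape(rows, cols, -1)
    maps = np.empty((rows, cols, levels), dtype=float)
    for r in range(rows):
        for c in range(cols):
            counts = np.bincount(blocks[r, c], minlength=levels)
            counts = _clip_histogram(counts, clip_count)
            cdf = np.cumsum(counts)
            # float maps, quantized once after interpolation; redistribution
            # can overshoot the pixel total slightly, hence the clamp at L-1
            maps[r, c] = np.clip((levels - 1) * cdf / tile_pixels, 0, levels - 1)

    # bilinear interpolation between the four neighbouring tile maps,
    # clamped at the borders; tile centers sit at pixel index i*k + k/2,
    # the classic integer-grid convention
    ph, pw = qp.shape
    gy = np.clip(np.arange(ph) / kh - 0.5, 0, rows - 1)
    gx = np.clip(np.arange(pw) / kw - 0.5, 0, cols - 1)
    r0 = np.minimum(gy.astype(int), rows - 1)
    c0 = np.minimum(gx.astype(int), cols - 1)
    r1 = np.minimum(r0 + 1, rows - 1)
    c1 = np.minimum(c0 + 1, cols - 1)
    fy = (gy - r0)[:, None]
    fx = (gx - c0)[None, :]

    def lookup(ri, ci):
        return maps[ri[:, None], ci[None, :], qp]

    out = (
        lookup(r0, c0) * (1 - fy) * (1 - fx)
        + lookup(r0, c1) * (1 - fy) * fx
        + lookup(r1, c0) * fy * (1 - fx)
        + lookup(r1, c1) * fy * fx
    )
    return np.clip(_round_half_up(out[:h, :w]), 0, levels - 1) / (levels - 1)


def clahe(img: np.ndarray, cfg: EnhanceConfig) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (tile scheme)."""
    cfg.validate()
    img = np.asarray(img, dtype=float)
    return _apply_on_luminance(
        img, lambda y: _clahe_gray(y, cfg.levels, cfg.clahe_clip, cfg.clahe_tiles)
    )


def crop_region(img: np.ndarray, box: tuple[int, int, int, int]) -> np.ndarray:
    """Copy the sub-image (row0, col0, row1, col1), end-exclusive."""
    r0, c0, r1, c1 = box
    h, w = img.shape[:2]
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ShapeError(f"crop box {box} outside image of shape {img.shape[:2]}")
    return img[r0:r1, c0:c1].copy()


def enhance_pipeline(img: np.ndarray, cfg: EnhanceConfig) -> np.ndarray:
    """Apply the configured stages in cfg.stage_order."""
    cfg.validate()
    out = np.asarray(img, dtype=float)
    for stage in cfg.stage_order:
        if stage == "crop":
            if cfg.crop_box is not None:
                out = crop_region(out, cfg.crop_box)
        elif stage == "retinex":
            out = multiscale_retinex(out, cfg)
        elif stage == "gamma":
            out = gamma_correct(out, cfg.gamma)
        elif stage == "hist_eq":
            out = hist_equalize(out, cfg.levels)
        elif stage == "unsharp":
            out = unsharp_mask(out, cfg)
        elif stage == "clahe":
            out = clahe(out, cfg)
        else:  # validate() already rejects unknown names
            raise ConfigError(f"unknown stage {stage!r}")
    return np.clip(out, 0.0, 1.0)


def augment_geometric(img: np.ndarray, rng: np.random.Generator, max_shift: int = 4) -> np.ndarray:
    """Seeded train-time augmentation: flips and integer shifts (reflect pad)."""
    out = img
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    sy, sx = rng.integers(-max_shift, max_shift + 1, size=2)
    pad = max_shift
    padded = np.pad(out, ((pad, pad), (pad, pad), (0, 0)), mode="reflect")
    h, w = img.shape[:2]
    return padded[pad + sy : pad + sy + h, pad + sx : pad + sx + w].copy()
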