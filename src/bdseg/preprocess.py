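"""Image-processing chain producing noise-free, right-canonicalized
single-sided combined images.

Order of operations: fat-water sum -> min-max normalization -> per-slice
Canny edges -> half-weight edge enhancement -> Otsu foreground split ->
morphological body mask -> mask applied to the sigmoid-combined image ->
midline split with left flip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage import feature, filters, morphology

from .volumes import FatWaterVolume, SingleBreastVolume, split_and_flip

__all__ = [
    "PreprocessConfig",
    "minmax_normalize",
    "fat_water_sum",
    "sigmoid_combine",
    "canny_edges",
    "edge_enhance",
    "otsu_threshold",
    "body_mask",
    "preprocess_pipeline",
]

#: relative floor under which the fat signal is treated as exactly zero
_FAT_EPS_REL = 1e-8


@dataclass(frozen=True)
class PreprocessConfig:
    canny_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.2
    closing_radius: int = 3
    edge_weight: float = 0.5
    clip_enhanced: bool = True
    #: alternative reading of the combination exponent, OFF by default
    sigmoid_alt_form: bool = False

    def __post_init__(self) -> None:
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be < canny_high")
        if self.closing_radius < 1:
            raise ValueError("closing_radius must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def minmax_normalize(volume: np.ndarray) -> np.ndarray:
    """Linearly rescale to [0, 1]; a constant volume maps to all zeros."""
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValueError("non-finite values in volume")
    vmin, vmax = float(volume.min()), float(volume.max())
    if vmax == vmin:
        warnings.warn("constant volume: min-max normalization degenerates to zeros",
                      RuntimeWarning, stacklevel=2)
        return np.zeros_like(volume)
    return (volume - vmin) / (vmax - vmin)


def fat_water_sum(fw: FatWaterVolume) -> np.ndarray:
    return fw.fat + fw.water


def sigmoid_combine(fw: FatWaterVolume, alt_form: bool = False) -> np.ndarray:
    """Combine fat/water channels with the sigmoid decision function.

    SI_C = 1 / (1 + exp((-SI_W - 0.25) / SI_F)), evaluated voxelwise.
    Where SI_F is (relatively) zero the exponent tends to -inf whenever
    the numerator is negative, so SI_C -> 1 there; the body mask later
    zeroes such voxels if they are background.

    ``alt_form`` switches the numerator to -(SI_W - 0.25 * SI_F).
    """
    fat = fw.fat.astype(np.float64)
    water = fw.water.astype(np.float64)
    if alt_form:
        numer = -(water - 0.25 * fat)
    else:
        numer = -water - 0.25
    eps = _FAT_EPS_REL * max(float(fat.max()), 1e-300)
    degenerate = fat < eps
    safe_fat = np.where(degenerate, 1.0, fat)
    with np.errstate(over="ignore"):
        expo = numer / safe_fat
        out = 1.0 / (1.0 + np.exp(expo))
    # SI_F ~ 0: exponent sign decides the limit
    out = np.where(degenerate & (numer < 0), 1.0, out)
    out = np.where(degenerate & (numer > 0), 0.0, out)
    out = np.where(degenerate & (numer == 0), 0.5, out)
    return out


def canny_edges(volume: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Per-transverse-slice 2D Canny edge map of a normalized volume.

    Slices are taken along axis 0 (slice, row, column layout); hysteresis
    thresholds are fractions of the per-slice maximum gradient magnitude.
    """
    volume = np.asarray(volume, dtype=np.float64)
    edges = np.zeros(volume.shape, dtype=bool)
    for k in range(volume.shape[0]):
        sl = volume[k]
        if sl.max() == sl.min():
            continue
        edges[k] = feature.canny(
            sl,
            sigma=cfg.canny_sigma,
            low_threshold=cfg.canny_low,
            high_threshold=cfg.canny_high,
            use_quantiles=False,
        )
    return edges.astype(np.uint8)


def edge_enhance(norm_sum: np.ndarray, edges: np.ndarray,
                 cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Add half-weighted edges to the normalized sum image."""
    norm_sum = np.asarray(norm_sum, dtype=np.float64)
    edges = np.asarray(edges)
    if norm_sum.shape != edges.shape:
        raise ValueError("norm_sum and edges must share shape")
    out = norm_sum + cfg.edge_weight * edges
    if cfg.clip_enhanced:
        out = np.clip(out, 0.0, 1.0)
    return out


def otsu_threshold(volume: np.ndarray, nbins: int = 256):
    """Otsu threshold over a 256-bin histogram.

    Returns ``(threshold, foreground)`` with ``foreground = volume > threshold``.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.max() == volume.min():
        raise ValueError("degenerate histogram: constant volume")
    thr = float(filters.threshold_otsu(volume, nbins=nbins))
    return thr, (volume > thr).astype(np.uint8)


def body_mask(foreground: np.ndarray,
              cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """Morphological closing, per-slice hole filling, largest component.

    The ball structuring element has radius ``closing_radius``; hole filling
    is 2D per transverse slice; only the largest 26-connected component
    survives (suppresses residual noise islands).
    """
    fg = np.asarray(foreground).astype(bool)
    if not fg.any():
        raise ValueError("empty body region")
    selem = morphology.ball(cfg.closing_radius)
    closed = ndimage.binary_closing(fg, structure=selem, border_value=0)
    filled = np.empty_like(closed)
    for k in range(closed.shape[0]):
        filled[k] = ndimage.binary_fill_holes(closed[k])
    labels, n = ndimage.label(filled, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("empty body region")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    return (labels == largest).astype(np.uint8)


def preprocess_pipeline(fw: FatWaterVolume,
                        cfg: PreprocessConfig = PreprocessConfig()):
    """Full deterministic chain; returns (right, left) SingleBreastVolume."""
    sumimg = fat_water_sum(fw)
    norm = minmax_normalize(sumimg)
    edges = canny_edges(norm, cfg)
    enhanced = edge_enhance(norm, edges, cfg)
    _, fg = otsu_threshold(enhanced)
    mask = body_mask(fg, cfg)
    combined = sigmoid_combine(fw, alt_form=cfg.sigmoid_alt_form)
    cleaned = combined * mask

    img_r, img_l = split_and_flip(cleaned, fw.axis_labels)
    msk_r, msk_l = split_and_flip(mask, fw.axis_labels)
    right = SingleBreastVolume(image=img_r, body_mask=msk_r, side="right",
                               flipped=False, spacing=fw.spacing,
                               axis_labels=fw.axis_labels)
    left = SingleBreastVolume(image=img_l, body_mask=msk_l, side="left",
                              flipped=True, spacing=fw.spacing,
                              axis_labels=fw.axis_labels)
    return right, left
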