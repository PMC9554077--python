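"""Inference and post-processing for the 3D U-Net."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..preprocess import minmax_normalize
from ..volumes import FatWaterVolume, ProbabilityMap, SegmentationMask
from .model import UNet3D

__all__ = ["prepare_input", "predict_proba", "threshold_and_fill"]

DEFAULT_THRESHOLD = 0.35


def prepare_input(fw: FatWaterVolume) -> np.ndarray:
    """Stack min-max-normalized fat and water channels: (2, D, H, W)."""
    return np.stack([minmax_normalize(fw.fat), minmax_normalize(fw.water)])


def predict_proba(model: UNet3D, fw: FatWaterVolume) -> ProbabilityMap:
    """Per-voxel breast probability; deterministic (eval-mode BN stats)."""
    x = prepare_input(fw)
    model.check_shape(x.shape[1:])
    prob = model.forward(x[None], train=False)[0, 0]
    return ProbabilityMap(np.clip(prob, 0.0, 1.0))


def threshold_and_fill(p: ProbabilityMap,
                       thr: float = DEFAULT_THRESHOLD,
                       spacing=(1.0, 1.0, 1.0)) -> SegmentationMask:
    """Binarize at ``thr`` (strictly greater) and fill holes per slice."""
    if not 0.0 < thr < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    mask = p.data > thr
    if mask.any():
        filled = np.empty_like(mask)
        for k in range(mask.shape[0]):
            filled[k] = ndimage.binary_fill_holes(mask[k])
        mask = filled
    return SegmentationMask(mask.astype(np.uint8), spacing=spacing)
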