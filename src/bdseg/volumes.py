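"""Domain types, NIfTI I/O, and left/right canonicalization.

All arrays use 0-based voxel coordinates in (slice, row, column) order.
Anatomical meaning of each axis is carried explicitly in ``axis_labels``
(e.g. ``("SI", "AP", "LR")``) and is never inferred from file layout.
Single-sided processing happens in canonical "right-breast" orientation;
left-side outputs are flipped back on export.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import nibabel as nib
import numpy as np

DEFAULT_AXIS_LABELS: Tuple[str, str, str] = ("SI", "AP", "LR")

__all__ = [
    "FatWaterVolume",
    "SingleBreastVolume",
    "SegmentationMask",
    "ProbabilityMap",
    "read_fat_water",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "split_and_flip",
    "flip_lr",
    "merge_halves",
    "lr_axis",
]


def _check_3d(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValueError(f"{name} must be a 3D array, got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class FatWaterVolume:
    """Paired fat-only / water-only 3D intensity volumes on a common grid."""

    fat: np.ndarray
    water: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_labels: Tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        fat = _check_3d(self.fat, "fat")
        water = _check_3d(self.water, "water")
        if fat.shape != water.shape:
            raise ValueError("incompatible fat/water grids")
        for arr, name in ((fat, "fat"), (water, "water")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"invalid intensity volume: non-finite {name} values")
            if arr.min() < 0:
                raise ValueError(f"invalid intensity volume: negative {name} values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")
        object.__setattr__(self, "fat", fat)
        object.__setattr__(self, "water", water)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "axis_labels", tuple(self.axis_labels))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.fat.shape


@dataclass(frozen=True)
class SingleBreastVolume:
    """Right-canonicalized single-sided processed volume.

    ``image`` is the combined (sigmoid-decision) intensity in [0, 1] with
    background zeroed by ``body_mask``.  ``flipped`` records whether the
    array was mirrored out of the original left side.
    """

    image: np.ndarray
    body_mask: np.ndarray
    side: str
    flipped: bool
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_labels: Tuple[str, str, str] = DEFAULT_AXIS_LABELS

    def __post_init__(self) -> None:
        image = _check_3d(self.image, "image")
        mask = _check_3d(self.body_mask, "body_mask")
        if image.shape != mask.shape:
            raise ValueError("image and body_mask must share shape")
        if image.min() < 0 or image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("body_mask must be binary")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.flipped != (self.side == "left"):
            raise ValueError("flipped must be true exactly for the left side")
        object.__setattr__(self, "image", image.astype(np.float64, copy=False))
        object.__setattr__(self, "body_mask", mask.astype(np.uint8, copy=False))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "axis_labels", tuple(self.axis_labels))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.image.shape


@dataclass(frozen=True)
class SegmentationMask:
    """Binary breast mask with voxel spacing in mm."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = _check_3d(self.data, "data")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary (0/1)")
        object.__setattr__(self, "data", data.astype(np.uint8, copy=False))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return float(self.n_voxels * np.prod(self.spacing))


@dataclass(frozen=True)
class ProbabilityMap:
    """Per-voxel breast likelihood in [0, 1]."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = _check_3d(self.data, "data")
        if data.min() < 0 or data.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "data", data.astype(np.float64, copy=False))


# ---------------------------------------------------------------------------
# NIfTI I/O (images float32, masks uint8)
# ---------------------------------------------------------------------------

def _spacing_affine(spacing: Tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(data: np.ndarray, spacing: Tuple[float, float, float], path) -> None:
    """Write a float volume as float32 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _spacing_affine(spacing))
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def read_volume(path):
    """Read a NIfTI volume; returns (array float64, spacing)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume in {path}, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def read_fat_water(path_fat, path_water, axis_labels=DEFAULT_AXIS_LABELS) -> FatWaterVolume:
    """Read co-registered fat-only and water-only volumes.

    Negative intensities within numeric noise (|v| < 1e-6 * max) are clamped
    to zero; substantive negatives raise.
    """
    fat, spacing_f = read_volume(path_fat)
    water, spacing_w = read_volume(path_water)
    if fat.shape != water.shape:
        raise ValueError("incompatible fat/water grids")
    if not np.allclose(spacing_f, spacing_w, rtol=1e-4):
        raise ValueError("incompatible fat/water grids: spacing differs")
    out = []
    for arr, name in ((fat, "fat"), (water, "water")):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"invalid intensity volume: non-finite {name}")
        tol = 1e-6 * max(float(arr.max()), 1.0)
        if arr.min() < -tol:
            raise ValueError(f"invalid intensity volume: negative {name} intensities")
        out.append(np.clip(arr, 0, None))
    return FatWaterVolume(fat=out[0], water=out[1], spacing=spacing_f,
                          axis_labels=axis_labels)


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a binary mask as uint8 NIfTI-1; round-trips bit-exactly."""
    if not isinstance(mask, SegmentationMask):
        mask = SegmentationMask(np.asarray(mask))  # validates binarity
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _spacing_affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path) -> SegmentationMask:
    data, spacing = read_volume(path)
    return SegmentationMask(data=np.rint(data).astype(np.uint8), spacing=spacing)


# ---------------------------------------------------------------------------
# Left/right canonicalization
# ---------------------------------------------------------------------------

def lr_axis(axis_labels) -> int:
    """Index of the left-right axis, or raise if it cannot be located."""
    labels = [str(l).upper() for l in axis_labels]
    for i, lab in enumerate(labels):
        if lab in ("LR", "RL", "L-R", "R-L", "LEFT-RIGHT", "RIGHT-LEFT"):
            return i
    raise ValueError("cannot locate left-right axis")


def flip_lr(arr: np.ndarray, axis_labels=DEFAULT_AXIS_LABELS) -> np.ndarray:
    """Mirror an array along the left-right axis (an involution)."""
    return np.flip(arr, axis=lr_axis(axis_labels)).copy()


def split_and_flip(arr: np.ndarray, axis_labels=DEFAULT_AXIS_LABELS):
    """Split a bilateral array at the geometric midline of the LR axis.

    Returns ``(right, left_flipped)``, both in canonical right orientation.
    Odd widths drop the single central column from both halves so the
    halves stay congruent.
    """
    axis = lr_axis(axis_labels)
    w = arr.shape[axis]
    if w < 2:
        raise ValueError("left-right extent must be at least 2")
    half = w // 2
    sl_right = [slice(None)] * arr.ndim
    sl_left = [slice(None)] * arr.ndim
    sl_right[axis] = slice(0, half)
    sl_left[axis] = slice(w - half, w)
    right = arr[tuple(sl_right)].copy()
    left = np.flip(arr[tuple(sl_left)], axis=axis).copy()
    return right, left


def merge_halves(right: np.ndarray, left_flipped: np.ndarray,
                 axis_labels=DEFAULT_AXIS_LABELS) -> np.ndarray:
    """Inverse of :func:`split_and_flip` for even widths."""
    axis = lr_axis(axis_labels)
    return np.concatenate([right, np.flip(left_flipped, axis=axis)], axis=axis)
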