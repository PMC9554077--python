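"""Seeded synthetic fat/water breast phantoms with known ground truth.

Geometry is parametric: a torso slab with an elliptical cross-section, a
water-dominant pectoral wedge that can protrude ("jut") into the breast
region, two breast hemi-ellipsoids, and smooth random fibroglandular
blobs occupying a controllable volume fraction of each breast.  Truth
densities are always computed from the noiseless construction.

Array layout is (slice, row, column) = (SI, AP, LR); breasts protrude
toward low row indices (anterior).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy import ndimage

from .dictionary import TemplateDictionary, TemplatePair
from .preprocess import PreprocessConfig, preprocess_pipeline
from .volumes import (
    DEFAULT_AXIS_LABELS,
    FatWaterVolume,
    SegmentationMask,
    split_and_flip,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "make_test_retest_pair",
    "make_dictionary",
]


@dataclass(frozen=True)
class PhantomSpec:
    shape: Tuple[int, int, int] = (48, 64, 64)  # (slices, rows, cols)
    breast_radius_range: Tuple[float, float] = (10.0, 13.0)
    density_fraction: float = 0.30
    muscle_jut: float = 2.0
    noise_sigma: float = 0.02
    fat_level: float = 1.0
    water_level: float = 0.0
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.density_fraction <= 1.0:
            raise ValueError("density_fraction must lie in [0, 1]")
        if any(s < 16 for s in self.shape):
            raise ValueError("shape components must be >= 16")
        if self.muscle_jut < 0:
            raise ValueError("muscle_jut must be >= 0")
        lo, hi = self.breast_radius_range
        if not 0 < lo <= hi:
            raise ValueError("breast_radius_range must be positive and ordered")


@dataclass(frozen=True)
class PhantomTruth:
    breast_mask_right: SegmentationMask
    breast_mask_left: SegmentationMask
    body_support: np.ndarray
    true_magdensity: float
    spec: PhantomSpec

    def __post_init__(self) -> None:
        if not 0.0 <= self.true_magdensity <= 100.0:
            raise ValueError("true_magdensity must lie in [0, 100]")

    @property
    def breast_mask(self) -> np.ndarray:
        """Union of the two breast masks on the full grid."""
        return np.maximum(self.breast_mask_right.data, self.breast_mask_left.data)


def _coords(shape):
    return np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape),
                       indexing="ij")


def _build_labels(spec: PhantomSpec, rng: np.random.Generator):
    """Boolean tissue-label fields of the noiseless phantom.

    Returns a dict with keys torso, wedge, right, left, fibro, body.
    """
    nz, ny, nx = spec.shape
    zz, yy, xx = _coords(spec.shape)
    lo, hi = spec.breast_radius_range

    chest_row = int(round(0.55 * ny))
    # torso: posterior slab with elliptical (slice, column) cross-section
    torso_cz, torso_cx = (nz - 1) / 2.0, (nx - 1) / 2.0
    torso = (
        (yy >= chest_row)
        & (((zz - torso_cz) / (0.48 * nz)) ** 2
           + ((xx - torso_cx) / (0.46 * nx)) ** 2 <= 1.0)
        & (yy <= 0.92 * ny)
    )

    # two breast hemi-ellipsoids anterior to the chest wall
    half = nx // 2
    masks = []
    centers = []
    for cx_base in (half / 2.0, nx - 1 - half / 2.0):
        r = rng.uniform(lo, hi)
        cz = nz / 2.0 + rng.uniform(-0.05, 0.05) * nz
        cx = cx_base + rng.uniform(-1.5, 1.5) * nx / 64.0
        rz = r * rng.uniform(0.85, 1.05)
        rr = r * rng.uniform(0.95, 1.15)
        rc = r * rng.uniform(0.85, 1.05)
        ell = (((zz - cz) / rz) ** 2 + ((yy - chest_row) / rr) ** 2
               + ((xx - cx) / rc) ** 2) <= 1.0
        breast = ell & (yy < chest_row)
        if not breast.any():
            raise ValueError("infeasible geometry: breast does not fit the grid")
        if breast[:, :, :2].any() or breast[:, :, -2:].any() or breast[:, :2, :].any():
            raise ValueError("infeasible geometry: breast larger than grid")
        masks.append(breast)
        centers.append((cz, cx, r))

    # pectoral wedge: thin water-dominant layer at the chest wall, with an
    # anterior bump (the "jut") under each breast
    wedge = torso & (yy <= chest_row + 2)
    if spec.muscle_jut > 0:
        for cz, cx, r in centers:
            bump = 1.0 - (((zz - cz) / (0.6 * r)) ** 2 + ((xx - cx) / (0.6 * r)) ** 2)
            jut_depth = spec.muscle_jut * np.clip(bump, 0.0, 1.0)
            wedge |= (yy >= chest_row - jut_depth) & (yy <= chest_row + 2) & (jut_depth > 0)

    right_mask = masks[0] & ~wedge
    left_mask = masks[1] & ~wedge
    breast_all = right_mask | left_mask
    body = torso | masks[0] | masks[1] | wedge

    # fibroglandular blobs: smooth random field, thresholded per breast so
    # that exactly the requested volume fraction is water-dominant
    blob_field = ndimage.gaussian_filter(rng.standard_normal(spec.shape), sigma=2.5)
    fibro = _threshold_blobs(blob_field, (right_mask, left_mask),
                             spec.density_fraction)

    return {
        "torso": torso,
        "wedge": wedge,
        "right": right_mask,
        "left": left_mask,
        "fibro": fibro,
        "body": body,
        "blob_field": blob_field,
    }


def _threshold_blobs(blob_field, breast_masks, density_fraction):
    """Mark the top ``density_fraction`` of blob-field values per breast."""
    fibro = np.zeros(blob_field.shape, dtype=bool)
    for m in breast_masks:
        vals = blob_field[m]
        n_fg = int(round(density_fraction * vals.size))
        if n_fg > 0:
            thr = np.partition(vals, vals.size - n_fg)[vals.size - n_fg]
            fibro |= m & (blob_field >= thr)
    return fibro


def _assign_intensities(spec: PhantomSpec, labels):
    """Pure noiseless channel intensities from tissue labels."""
    fat = np.zeros(spec.shape)
    water = np.zeros(spec.shape)
    fl, wl = spec.fat_level, spec.water_level
    breast_all = labels["right"] | labels["left"]
    # torso interior: fat-dominant with some water signal
    fat[labels["torso"]] = fl
    water[labels["torso"]] = 0.25 * fl
    # wedge (muscle): water-dominant
    fat[labels["wedge"]] = 0.05 * fl
    water[labels["wedge"]] = fl
    # breast fat tissue: (fat_level, water_level); fibroglandular: swapped
    fat[breast_all] = fl
    water[breast_all] = wl
    fat[labels["fibro"]] = wl
    water[labels["fibro"]] = fl
    return fat, water


def _true_magdensity(fat: np.ndarray, water: np.ndarray, mask: np.ndarray) -> float:
    total = fat + water
    inside = mask.astype(bool) & (total > 1e-12)
    ff = 100.0 * fat[inside] / total[inside]
    return float(100.0 - ff.mean())


def _package(spec, labels, rng_noise):
    fat0, water0 = _assign_intensities(spec, labels)
    fat, water = fat0, water0
    if spec.noise_sigma > 0:
        fat = fat + rng_noise.normal(0.0, spec.noise_sigma, spec.shape)
        water = water + rng_noise.normal(0.0, spec.noise_sigma, spec.shape)
    fat = np.clip(fat, 0.0, None)
    water = np.clip(water, 0.0, None)
    fw = FatWaterVolume(fat=fat, water=water, spacing=spec.spacing,
                        axis_labels=DEFAULT_AXIS_LABELS)
    rmask, lmask = labels["right"], labels["left"]
    truth = PhantomTruth(
        breast_mask_right=SegmentationMask(rmask.astype(np.uint8), spec.spacing),
        breast_mask_left=SegmentationMask(lmask.astype(np.uint8), spec.spacing),
        body_support=labels["body"].astype(np.uint8),
        true_magdensity=_true_magdensity(fat0, water0, rmask | lmask),
        spec=spec,
    )
    return fw, truth


def make_phantom(spec: PhantomSpec):
    """Generate one bilateral phantom; fully determined by the spec seed."""
    rng = np.random.default_rng(spec.seed)
    labels = _build_labels(spec, rng)
    return _package(spec, labels, rng)


def _smooth_displacement(shape, scale, rng):
    """Smooth, zero-mean random displacement field.

    ``scale`` bounds the displacement magnitude (max <= scale voxels);
    typical magnitudes are a fraction of that, keeping the deformation
    "small and smooth" relative to breast size.
    """
    disp = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape), sigma=7.0)
                     for _ in range(3)])
    disp -= disp.mean(axis=(1, 2, 3), keepdims=True)
    mag = np.sqrt((disp ** 2).sum(axis=0))
    peak = mag.max()
    if peak > 0:
        disp *= 0.75 * scale / peak
    return disp


def _warp(arr, disp, order):
    zz, yy, xx = _coords(arr.shape)
    coords = np.stack([zz + disp[0], yy + disp[1], xx + disp[2]])
    return ndimage.map_coordinates(arr.astype(np.float64), coords, order=order,
                                   mode="nearest")


def make_test_retest_pair(spec: PhantomSpec, deform_scale: float = 2.0):
    """Two same-subject phantoms: shared anatomy, small smooth deformation,
    independent noise realizations.

    The second phantom's tissue labels are the first's pulled through a
    smooth random displacement (nearest-neighbor, so tissues stay pure and
    the true densities of the pair agree closely); noise is drawn fresh.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _build_labels(spec, rng)
    first = _package(spec, labels, rng)

    if deform_scale > 0:
        disp = _smooth_displacement(spec.shape, deform_scale, rng)
        labels2 = {k: _warp(v.astype(np.uint8), disp, order=0) > 0.5
                   for k, v in labels.items()
                   if k not in ("fibro", "blob_field")}
        # re-threshold the warped blob field so the retest anatomy keeps the
        # same fibroglandular volume fraction (same-subject contract)
        blob2 = _warp(labels["blob_field"], disp, order=1)
        labels2["blob_field"] = blob2
        labels2["fibro"] = _threshold_blobs(
            blob2, (labels2["right"], labels2["left"]), spec.density_fraction)
    else:
        labels2 = labels
    second = _package(spec, labels2, rng)
    return first, second


def make_dictionary(n: int, base_spec: PhantomSpec = PhantomSpec(),
                    pre_cfg: PreprocessConfig = PreprocessConfig()) -> TemplateDictionary:
    """Build an n-template single-sided dictionary spanning randomized
    sizes, shapes, and densities; masks are phantom truths canonicalized
    exactly like targets (via the preprocessing pipeline's split)."""
    if n < 5:
        raise ValueError("dictionary needs at least 5 templates (top-5 selection)")
    rng = np.random.default_rng(base_spec.seed)
    d = TemplateDictionary()
    lo, hi = base_spec.breast_radius_range
    for i in range(n):
        spread = (hi - lo) if hi > lo else 1.0
        spec_i = replace(
            base_spec,
            seed=int(rng.integers(0, 2 ** 31)),
            density_fraction=float(rng.uniform(0.12, 0.5)),
            breast_radius_range=(
                float(max(4.0, lo + rng.uniform(-0.2, 0.2) * spread)),
                float(hi + rng.uniform(-0.2, 0.2) * spread),
            ),
            muscle_jut=float(rng.uniform(0.0, max(base_spec.muscle_jut, 1e-9) * 1.5)),
        )
        fw, truth = make_phantom(spec_i)
        right, left = preprocess_pipeline(fw, pre_cfg)
        if i % 2 == 0:
            img = right
            mask_half, _ = split_and_flip(truth.breast_mask_right.data,
                                          fw.axis_labels)
        else:
            img = left
            _, mask_half = split_and_flip(truth.breast_mask_left.data,
                                          fw.axis_labels)
        pair = TemplatePair(
            id=f"tpl_{i:03d}",
            image=img,
            mask=SegmentationMask(mask_half, spec_i.spacing),
            meta={
                "density_fraction": spec_i.density_fraction,
                "muscle_jut": spec_i.muscle_jut,
                "seed": spec_i.seed,
            },
        )
        d.add(pair)
    return d
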