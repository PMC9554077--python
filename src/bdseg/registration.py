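"""Template-registration segmentation: NMI ranking, non-rigid B-spline
registration, mask warping, and majority-vote label fusion.

The reference registration backend is a multi-resolution cubic B-spline
free-form deformation optimized by gradient ascent on normalized mutual
information (Parzen-window estimate), initialized with a global
translation from phase correlation.  Backends are pluggable through the
``register_nonrigid`` entry point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .dictionary import TemplateDictionary
from .preprocess import PreprocessConfig, preprocess_pipeline
from .volumes import (
    FatWaterVolume,
    SegmentationMask,
    SingleBreastVolume,
    lr_axis,
)

__all__ = [
    "RegistrationConfig",
    "DeformationField",
    "nmi",
    "registration_metric",
    "select_templates",
    "register_nonrigid",
    "warp_mask",
    "vote_fusion",
    "segment_registration",
]

#: voxels with at least this many supporting masks enter the fused output
DEFAULT_MIN_VOTES = 4
DEFAULT_TOP_K = 5


@dataclass(frozen=True)
class RegistrationConfig:
    metric: str = "nmi"
    pyramid_levels: int = 3
    control_point_spacing: int = 5  # voxels at the finest level
    regularization_weight: float = 0.01
    max_iterations: Tuple[int, ...] = (60, 40, 15)
    nmi_bins: int = 64
    opt_bins: int = 32  # Parzen bins used inside the optimizer
    step_init: float = 0.2  # Adam step on control-point coefficients, voxels
    smooth_sigma: float = 1.0  # per-level Gaussian smoothing of both images

    def __post_init__(self) -> None:
        if self.metric != "nmi":
            raise ValueError("only the NMI metric is supported")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.nmi_bins < 8:
            raise ValueError("nmi_bins must be >= 8")
        if self.control_point_spacing < 2:
            raise ValueError("control_point_spacing must be >= 2 voxels")
        if self.regularization_weight < 0:
            raise ValueError("regularization_weight must be >= 0")
        if len(self.max_iterations) < self.pyramid_levels:
            raise ValueError("need one max_iterations entry per pyramid level")


@dataclass
class DeformationField:
    """Per-voxel displacement (voxel units) mapping target coordinates to
    template coordinates; ``displacement`` has shape (3,) + grid shape."""

    displacement: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    converged: bool = True

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=np.float64)
        if disp.ndim != 4 or disp.shape[0] != 3:
            raise ValueError("displacement must have shape (3, nz, ny, nx)")
        if not np.all(np.isfinite(disp)):
            raise ValueError("displacement must be finite everywhere")
        self.displacement = disp

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.displacement.shape[1:]

    def sample_coords(self) -> np.ndarray:
        """Absolute template-space coordinates for every target voxel."""
        grids = np.meshgrid(*(np.arange(n, dtype=np.float64)
                              for n in self.grid_shape), indexing="ij")
        return np.stack(grids) + self.displacement


# ---------------------------------------------------------------------------
# Similarity
# ---------------------------------------------------------------------------

def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(a: np.ndarray, b: np.ndarray, bins: int = 64) -> float:
    """Normalized mutual information (H(A)+H(B)) / H(A,B).

    Joint histogram with ``bins`` equal-width bins per axis over each
    array's own [min, max]. Lies in [1, 2]; equals 2 iff the joint
    histogram is a (permuted) diagonal.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("arrays must share shape")
    if a.min() == a.max() or b.min() == b.max():
        raise ValueError("constant array: NMI undefined")
    joint, _, _ = np.histogram2d(a, b, bins=bins)
    pj = joint / joint.sum()
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    return (_entropy(pa) + _entropy(pb)) / _entropy(pj.ravel())


def registration_metric(fixed: np.ndarray, moving: np.ndarray,
                        cfg: "RegistrationConfig" = None) -> float:
    """The similarity the registration backend actually optimizes: Parzen
    NMI of lightly smoothed images.

    Hard-binned NMI of raw piecewise-constant images drops under *any*
    interpolating warp (histogram peaks smear), so improvement guarantees
    are stated with this estimator.
    """
    cfg = cfg or RegistrationConfig()
    if cfg.smooth_sigma > 0:
        fixed = ndimage.gaussian_filter(fixed, cfg.smooth_sigma)
        moving = ndimage.gaussian_filter(moving, cfg.smooth_sigma)
    fixed_q = _quantize_fixed(fixed, cfg.opt_bins)
    val, _ = _parzen_nmi_and_forces(fixed_q, moving, cfg.opt_bins)
    return val


def _resample_to(img: np.ndarray, shape) -> np.ndarray:
    if img.shape == tuple(shape):
        return img
    factors = [t / s for t, s in zip(shape, img.shape)]
    return ndimage.zoom(img, factors, order=1, mode="nearest", grid_mode=True)


def select_templates(target: SingleBreastVolume, dictionary: TemplateDictionary,
                     k: int = DEFAULT_TOP_K, bins: int = 64,
                     return_scores: bool = False):
    """Ids of the k dictionary templates most similar to the target by NMI,
    descending; ties broken by dictionary insertion order."""
    if len(dictionary) < k:
        raise ValueError(f"dictionary has {len(dictionary)} templates, need >= {k}")
    scores = []
    for idx, pair in enumerate(dictionary):
        timg = _resample_to(pair.image.image, target.shape)
        scores.append((-nmi(target.image, timg, bins=bins), idx, pair.id))
    scores.sort()
    chosen = scores[:k]
    if return_scores:
        return [tid for _, _, tid in chosen], [-s for s, _, _ in chosen]
    return [tid for _, _, tid in chosen]


# ---------------------------------------------------------------------------
# B-spline FFD backend
# ---------------------------------------------------------------------------

def _bspline3(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel (support |t| < 2), matching order-3
    map_coordinates interpolation with prefilter disabled."""
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1
    m2 = (at >= 1) & (at < 2)
    out[m1] = 2.0 / 3.0 - at[m1] ** 2 + 0.5 * at[m1] ** 3
    out[m2] = ((2.0 - at[m2]) ** 3) / 6.0
    return out


class _BsplineGrid:
    """Cubic B-spline coefficient grid over a voxel lattice.

    Node spacing is an integer voxel count.  Nodes extend two spacings
    beyond the volume on every side so that evaluating the spline never
    extrapolates and the adjoint (force scatter) is exact, including at
    the boundary — a clipped adjoint corrupts boundary-node gradients
    badly enough to flip the aggregate ascent direction.
    """

    _PAD = 2  # nodes before voxel 0; node k sits at voxel (k - _PAD) * spacing

    def __init__(self, shape, spacing: int):
        self.shape = tuple(shape)
        self.spacing = int(spacing)
        self.n_nodes = tuple(
            int(np.ceil((n - 1) / self.spacing)) + 2 * self._PAD + 1
            for n in shape)
        self.coef = np.zeros((3,) + self.n_nodes)
        # separable banded basis: B[a][x, k] = bspline3((x - (k-PAD)*s)/s);
        # tensordot chains give both evaluation and its exact adjoint
        self._basis = []
        for n_vox, n_nod in zip(self.shape, self.n_nodes):
            x = np.arange(n_vox, dtype=np.float64)[:, None]
            k = np.arange(n_nod, dtype=np.float64)[None, :]
            self._basis.append(
                _bspline3((x - (k - self._PAD) * self.spacing) / self.spacing))

    def _apply(self, arr: np.ndarray, transpose: bool) -> np.ndarray:
        for axis in range(3):
            b = self._basis[axis].T if transpose else self._basis[axis]
            # contract arr's (axis+1)-th dim with b's columns
            arr = np.moveaxis(np.tensordot(b, arr, axes=(1, axis + 1)),
                              0, axis + 1)
        return arr

    def displacement(self) -> np.ndarray:
        return self._apply(self.coef, transpose=False)

    def gradient_from_forces(self, forces: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`displacement` (transposed basis chain)."""
        return self._apply(forces, transpose=True)


def _parzen_nmi_and_forces(fixed_q, moving, bins):
    """Parzen-window NMI of quantized-fixed vs moving plus dNMI/dmoving.

    ``fixed_q`` is the precomputed integer bin index of the fixed image;
    the moving image uses a cubic B-spline window over ``bins`` bins.
    Returns (nmi_value, per-voxel dNMI/dM array).
    """
    mmin, mmax = float(moving.min()), float(moving.max())
    if mmax == mmin:
        return 1.0, np.zeros_like(moving)
    scale = (bins - 1) / (mmax - mmin)
    mq = (moving - mmin) * scale  # continuous bin coordinate
    m0 = np.floor(mq).astype(np.intp) - 1  # lowest of 4 supporting bins
    frac = mq - np.floor(mq)

    n = moving.size
    fq = fixed_q.ravel()
    m0f = m0.ravel()
    fracf = frac.ravel()

    w = np.empty((4, n))
    dw = np.empty((4, n))
    for j in range(4):
        t = fracf - (j - 1)  # distance from bin m0+j
        w[j] = _bspline3(t)
        at = np.abs(t)
        d = np.zeros_like(t)
        m1 = at < 1
        m2 = (at >= 1) & (at < 2)
        d[m1] = -2.0 * t[m1] + 1.5 * t[m1] ** 2 * np.sign(t[m1])
        d[m2] = -0.5 * ((2.0 - at[m2]) ** 2) * np.sign(t[m2])
        dw[j] = d

    joint = np.zeros(bins * bins)
    for j in range(4):
        mb = np.clip(m0f + j, 0, bins - 1)
        joint += np.bincount(fq * bins + mb, weights=w[j],
                             minlength=bins * bins)
    joint = joint.reshape(bins, bins) / n
    pf = joint.sum(axis=1)
    pm = joint.sum(axis=0)
    hf, hm, hj = _entropy(pf), _entropy(pm), _entropy(joint.ravel())
    if hj <= 0:
        return 1.0, np.zeros_like(moving)
    val = (hf + hm) / hj

    with np.errstate(divide="ignore"):
        log_pj = np.where(joint > 0, np.log(joint), 0.0)
        log_pm = np.where(pm > 0, np.log(pm), 0.0)
    # dNMI/dp_joint(f,m); the constant offsets cancel since sum(dp)=0
    L = (val * (1.0 + log_pj) - (1.0 + log_pm)[None, :]) / hj

    g = np.zeros(n)
    for j in range(4):
        mb = np.clip(m0f + j, 0, bins - 1)
        g += L[fq, mb] * dw[j]
    g *= scale / n
    return val, g.reshape(moving.shape)


def _quantize_fixed(fixed, bins):
    fmin, fmax = float(fixed.min()), float(fixed.max())
    if fmax == fmin:
        raise ValueError("constant fixed image")
    idx = ((fixed - fmin) / (fmax - fmin) * (bins - 1)).astype(np.intp)
    return np.clip(idx, 0, bins - 1)


def _downsample(img, factor):
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img, sigma=factor / 2.0)
    return sm[tuple(slice(None, None, factor) for _ in img.shape)]


def _warp_image(img, disp):
    grids = np.meshgrid(*(np.arange(n, dtype=np.float64)
                          for n in disp.shape[1:]), indexing="ij")
    coords = np.stack(grids) + disp
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest")


def register_nonrigid(template_img: SingleBreastVolume,
                      target_img: SingleBreastVolume,
                      cfg: RegistrationConfig = RegistrationConfig()) -> DeformationField:
    """Register a template to a target; returns the deformation field on
    the target grid (pull semantics: target voxel -> template coordinate).

    Multi-resolution: phase-correlation translation initialization, then
    per-level B-spline coefficient gradient ascent on Parzen NMI with a
    bending (Laplacian) penalty and backtracking step control.
    """
    fixed_full = np.asarray(target_img.image, dtype=np.float64)
    moving_full = _resample_to(np.asarray(template_img.image, dtype=np.float64),
                               fixed_full.shape)
    if fixed_full.max() == fixed_full.min() or moving_full.max() == moving_full.min():
        raise ValueError("degenerate (constant) image")

    # similarity seed: translation from phase correlation plus an isotropic
    # scale about the target centroid estimated from foreground volumes
    # (templates and targets differ in breast size; FFD alone closes large
    # size gaps poorly).  u0(x) = shift + (gamma - 1)(x - cf).
    shift, _, _ = phase_cross_correlation(fixed_full, moving_full,
                                          upsample_factor=10)
    init_shift = -np.asarray(shift, dtype=np.float64)
    fix_fg = fixed_full > 1e-6
    mov_fg = moving_full > 1e-6
    if fix_fg.any() and mov_fg.any():
        gamma = float((mov_fg.sum() / fix_fg.sum()) ** (1.0 / 3.0))
        cf = np.array(ndimage.center_of_mass(fix_fg))
    else:
        gamma, cf = 1.0, np.zeros(3)
    if abs(gamma - 1.0) < 0.02:
        gamma = 1.0

    levels = [2 ** (cfg.pyramid_levels - 1 - i) for i in range(cfg.pyramid_levels)]
    grid: Optional[_BsplineGrid] = None
    converged = True
    for li, factor in enumerate(levels):
        fixed = _downsample(fixed_full, factor)
        moving = _downsample(moving_full, factor)
        if cfg.smooth_sigma > 0:
            # interpolation of an unsmoothed image penalizes any subvoxel
            # displacement (blur kink at zero), stalling gradient ascent
            fixed = ndimage.gaussian_filter(fixed, cfg.smooth_sigma)
            moving = ndimage.gaussian_filter(moving, cfg.smooth_sigma)
        fixed_q = _quantize_fixed(fixed, cfg.opt_bins)
        prev = grid
        grid = _BsplineGrid(fixed.shape, cfg.control_point_spacing)
        if prev is None:
            # linear fields are reproduced exactly by coefficients sampled
            # at the node positions (cubic B-splines reproduce degree <= 1)
            node_pos = [(np.arange(n) - grid._PAD) * grid.spacing
                        for n in grid.n_nodes]
            nz, ny, nx = np.meshgrid(*node_pos, indexing="ij")
            nodes = np.stack([nz, ny, nx]).astype(np.float64)
            for d in range(3):
                grid.coef[d] = (init_shift[d] / factor
                                + (gamma - 1.0) * (nodes[d] - cf[d] / factor))
        else:
            # evaluate the coarse displacement at the new node lattice
            s = grid.spacing
            node_vox = [np.clip((np.arange(n) - grid._PAD) * s, 0,
                                fixed.shape[a] - 1)
                        for a, n in enumerate(grid.n_nodes)]
            nz, ny, nx = np.meshgrid(*node_vox, indexing="ij")
            coarse_coords = np.stack([nz, ny, nx]).astype(np.float64) / 2.0
            q = coarse_coords / prev.spacing + prev._PAD
            for d in range(3):
                grid.coef[d] = 2.0 * ndimage.map_coordinates(
                    prev.coef[d], q, order=3, prefilter=False, mode="nearest")

        warped = _warp_image(moving, grid.displacement())
        best_val, forces_scalar = _parzen_nmi_and_forces(fixed_q, warped,
                                                         cfg.opt_bins)
        best_coef = grid.coef.copy()
        # Adam on the coefficient grid: per-coordinate scaling copes with
        # the very peaky NMI gradient far better than a max-norm step
        m = np.zeros_like(grid.coef)
        v = np.zeros_like(grid.coef)
        b1, b2, aeps = 0.9, 0.999, 1e-12
        stale = 0
        for it in range(1, cfg.max_iterations[li] + 1):
            gz, gy, gx = np.gradient(warped)
            forces = np.stack([forces_scalar * gz, forces_scalar * gy,
                               forces_scalar * gx])
            grad = grid.gradient_from_forces(forces)
            if cfg.regularization_weight > 0:
                for d in range(3):
                    grad[d] -= cfg.regularization_weight * ndimage.laplace(
                        ndimage.laplace(grid.coef[d]))
            gmax = np.abs(grad).max()
            if gmax == 0:
                break
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad * grad
            mh = m / (1 - b1 ** it)
            vh = v / (1 - b2 ** it)
            grid.coef = grid.coef + cfg.step_init * mh / (np.sqrt(vh)
                                                          + aeps + 1e-3 * gmax)
            warped = _warp_image(moving, grid.displacement())
            val, forces_scalar = _parzen_nmi_and_forces(fixed_q, warped,
                                                        cfg.opt_bins)
            if val > best_val + 1e-7:
                best_val = val
                best_coef = grid.coef.copy()
                stale = 0
            else:
                stale += 1
                if stale >= 15:
                    break
        grid.coef = best_coef
        if li == len(levels) - 1 and stale == 0 and it >= cfg.max_iterations[li]:
            converged = False

    # final field at full resolution
    final_grid = _BsplineGrid(fixed_full.shape, cfg.control_point_spacing)
    final_grid.coef = grid.coef
    disp_full = final_grid.displacement() if levels[-1] == 1 else None
    if disp_full is None:
        # upsample the coarse displacement field to the full grid
        coarse_disp = grid.displacement()
        f = levels[-1]
        disp_full = np.stack([
            ndimage.zoom(coarse_disp[d], [t / s for t, s in
                                          zip(fixed_full.shape, coarse_disp[d].shape)],
                         order=1, mode="nearest", grid_mode=True) * f
            for d in range(3)])

    # safeguard: among {optimized, similarity seed, zero} return the field
    # with the best registration metric, so the result never scores below
    # the unregistered pair
    grids = np.meshgrid(*(np.arange(n, dtype=np.float64)
                          for n in fixed_full.shape), indexing="ij")
    sim = np.stack([init_shift[d] + (gamma - 1.0) * (grids[d] - cf[d])
                    for d in range(3)])
    zero = np.zeros_like(disp_full)
    candidates = [(disp_full, converged), (sim, False), (zero, False)]
    scores = [registration_metric(fixed_full, _warp_image(moving_full, c), cfg)
              for c, _ in candidates]
    best_disp, best_conv = candidates[int(np.argmax(scores))]
    return DeformationField(displacement=best_disp, spacing=target_img.spacing,
                            converged=best_conv)


def warp_mask(mask: SegmentationMask, field: DeformationField) -> SegmentationMask:
    """Resample a binary mask through a deformation field (nearest-neighbor,
    so the output stays binary)."""
    data = mask.data
    if data.shape != field.grid_shape:
        raise ValueError("mask grid incompatible with deformation field")
    warped = ndimage.map_coordinates(data, field.sample_coords(), order=0,
                                     mode="constant", cval=0)
    return SegmentationMask(warped.astype(np.uint8), spacing=field.spacing)


def vote_fusion(masks: Sequence[SegmentationMask],
                min_votes: int = DEFAULT_MIN_VOTES) -> SegmentationMask:
    """Per-voxel vote: keep voxels contained in >= min_votes input masks."""
    if len(masks) == 0:
        raise ValueError("vote_fusion requires at least one mask")
    if not 1 <= min_votes <= len(masks):
        raise ValueError("min_votes must satisfy 1 <= min_votes <= len(masks)")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError("all masks must share a grid")
    counts = np.zeros(shape, dtype=np.int32)
    for m in masks:
        counts += m.data
    return SegmentationMask((counts >= min_votes).astype(np.uint8),
                            spacing=masks[0].spacing)


def _segment_side(side_vol: SingleBreastVolume, dictionary: TemplateDictionary,
                  reg_cfg: RegistrationConfig, k: int, min_votes: int):
    ids, scores = select_templates(side_vol, dictionary, k=k,
                                   bins=reg_cfg.nmi_bins, return_scores=True)
    warped = []
    for tid in ids:
        pair = dictionary.get(tid)
        f = register_nonrigid(pair.image, side_vol, reg_cfg)
        mask = pair.mask
        if mask.shape != side_vol.shape:
            resampled = _resample_to(mask.data.astype(np.float64), side_vol.shape)
            mask = SegmentationMask((resampled > 0.5).astype(np.uint8),
                                    spacing=side_vol.spacing)
        warped.append(warp_mask(mask, f))
    fused = vote_fusion(warped, min_votes=min_votes)
    # breast voxels cannot lie outside the subject's own body support
    fused = SegmentationMask(fused.data * side_vol.body_mask,
                             spacing=fused.spacing)
    report = {
        "template_ids": ids,
        "nmi_values": scores,
        "per_template_dice_vs_final": [_dice(w.data, fused.data) for w in warped],
    }
    return fused, report


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def segment_registration(fw: FatWaterVolume, dictionary: TemplateDictionary,
                         pre_cfg: PreprocessConfig = PreprocessConfig(),
                         reg_cfg: RegistrationConfig = RegistrationConfig(),
                         k: int = DEFAULT_TOP_K,
                         min_votes: int = DEFAULT_MIN_VOTES,
                         return_report: bool = False,
                         sides: Tuple[str, ...] = ("right", "left")):
    """Full pipeline: preprocess, then per side select top-k templates,
    register each, warp its mask, and fuse by voting.

    Returns (right_mask, left_mask) on the full original grid, the left
    mask flipped back to the original frame.  ``sides`` restricts the
    work (e.g. a single-sided test-retest protocol); the skipped side's
    mask comes back empty.
    """
    right, left = preprocess_pipeline(fw, pre_cfg)
    empty = SegmentationMask(np.zeros(right.shape, dtype=np.uint8),
                             spacing=fw.spacing)
    if "right" in sides:
        fused_r, rep_r = _segment_side(right, dictionary, reg_cfg, k, min_votes)
    else:
        fused_r, rep_r = empty, {}
    if "left" in sides:
        fused_l, rep_l = _segment_side(left, dictionary, reg_cfg, k, min_votes)
    else:
        fused_l, rep_l = empty, {}

    axis = lr_axis(fw.axis_labels)
    full_shape = fw.shape
    half = full_shape[axis] // 2

    right_full = np.zeros(full_shape, dtype=np.uint8)
    left_full = np.zeros(full_shape, dtype=np.uint8)
    sl_r = [slice(None)] * 3
    sl_r[axis] = slice(0, half)
    sl_l = [slice(None)] * 3
    sl_l[axis] = slice(full_shape[axis] - half, full_shape[axis])
    right_full[tuple(sl_r)] = fused_r.data
    left_full[tuple(sl_l)] = np.flip(fused_l.data, axis=axis)

    rm = SegmentationMask(right_full, spacing=fw.spacing)
    lm = SegmentationMask(left_full, spacing=fw.spacing)
    if return_report:
        return rm, lm, {"right": rep_r, "left": rep_l}
    return rm, lm
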