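"""MagDensity from fat-fraction maps and task-based reproducibility
statistics: paired deltas, MSE, ICC(A,1) with its F-based confidence
interval, and the small-change significance simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

from .volumes import FatWaterVolume, SegmentationMask

__all__ = [
    "FatFractionMap",
    "DensityResult",
    "PairedMeasures",
    "ICCResult",
    "PowerSimConfig",
    "fat_fraction",
    "magdensity",
    "delta_stats",
    "mse_paired",
    "icc_a1",
    "power_simulation",
]

#: fat + water totals at or below this (relative to the volume maximum)
#: leave the fat fraction undefined at that voxel
_TOTAL_EPS_REL = 1e-9


@dataclass(frozen=True)
class FatFractionMap:
    """Per-voxel fat percentage in [0, 100]; ``defined`` flags voxels with
    measurable total signal."""

    ff: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        ff = np.asarray(self.ff, dtype=np.float64)
        defined = np.asarray(self.defined).astype(bool)
        if ff.shape != defined.shape:
            raise ValueError("ff and defined must share shape")
        vals = ff[defined]
        if vals.size and (vals.min() < 0 or vals.max() > 100):
            raise ValueError("defined fat fractions must lie in [0, 100]")
        object.__setattr__(self, "ff", ff)
        object.__setattr__(self, "defined", defined)


@dataclass(frozen=True)
class DensityResult:
    magdensity: float
    n_voxels: int
    mask_volume_mm3: float
    n_undefined: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.magdensity <= 100.0:
            raise ValueError("magdensity must lie in [0, 100]")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")

    def to_dict(self) -> dict:
        return {
            "MagDensity": self.magdensity,
            "n_voxels": self.n_voxels,
            "mask_volume_mm3": self.mask_volume_mm3,
            "n_undefined": self.n_undefined,
        }


@dataclass(frozen=True)
class PairedMeasures:
    """Test and retest values (percent) per subject."""

    subjects: Tuple[str, ...]
    test: np.ndarray
    retest: np.ndarray

    def __post_init__(self) -> None:
        test = np.asarray(self.test, dtype=np.float64)
        retest = np.asarray(self.retest, dtype=np.float64)
        if not (len(self.subjects) == test.size == retest.size):
            raise ValueError("subjects, test, retest must have equal length")
        if test.size < 1:
            raise ValueError("at least one pair required")
        if not (np.all(np.isfinite(test)) and np.all(np.isfinite(retest))):
            raise ValueError("measures must be finite")
        object.__setattr__(self, "subjects", tuple(self.subjects))
        object.__setattr__(self, "test", test)
        object.__setattr__(self, "retest", retest)

    @property
    def n(self) -> int:
        return self.test.size

    @property
    def delta(self) -> np.ndarray:
        """Retest minus test, per subject."""
        return self.retest - self.test


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    msr: float
    msc: float
    mse_ms: float
    n: int
    k: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.icc <= 1.0:
            raise ValueError("icc must lie in [-1, 1]")
        if not self.ci_low <= self.icc <= self.ci_high:
            raise ValueError("confidence interval must bracket the estimate")

    def to_dict(self) -> dict:
        return {
            "ICC": self.icc,
            "CI95_low": self.ci_low,
            "CI95_high": self.ci_high,
            "MSR": self.msr,
            "MSC": self.msc,
            "MSE_ms": self.mse_ms,
            "n": self.n,
            "k": self.k,
        }


@dataclass(frozen=True)
class PowerSimConfig:
    n_per_group: int = 10
    true_change: float = 1.0
    sd: float = 1.42
    reps: int = 2000
    seed: int = 0
    sided: str = "two"

    def __post_init__(self) -> None:
        if self.n_per_group < 2 or self.true_change <= 0 or self.sd <= 0:
            raise ValueError("n_per_group >= 2, true_change > 0, sd > 0 required")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


# ---------------------------------------------------------------------------
# Density
# ---------------------------------------------------------------------------

def fat_fraction(fw: FatWaterVolume) -> FatFractionMap:
    """ff = 100 * fat / (fat + water); undefined where total ~ 0."""
    total = fw.fat + fw.water
    eps = _TOTAL_EPS_REL * max(float(total.max()), 1e-300)
    defined = total > eps
    ff = np.zeros_like(total)
    np.divide(fw.fat, total, out=ff, where=defined)
    ff *= 100.0
    return FatFractionMap(ff=np.clip(ff, 0.0, 100.0), defined=defined)


def magdensity(ff: FatFractionMap, mask: SegmentationMask) -> DensityResult:
    """MagDensity = 100 - mean fat fraction over defined voxels in the mask.

    Undefined voxels inside the mask are excluded from the mean and counted
    in the report.
    """
    if ff.ff.shape != mask.shape:
        raise ValueError("fat-fraction map and mask grids differ")
    inside = mask.data.astype(bool)
    if not inside.any():
        raise ValueError("empty mask")
    usable = inside & ff.defined
    n_undef = int(inside.sum() - usable.sum())
    if not usable.any():
        raise ValueError("mask entirely undefined in the fat-fraction map")
    md = 100.0 - float(ff.ff[usable].mean())
    return DensityResult(magdensity=md, n_voxels=int(usable.sum()),
                         mask_volume_mm3=mask.volume_mm3, n_undefined=n_undef)


# ---------------------------------------------------------------------------
# Test-retest statistics
# ---------------------------------------------------------------------------

def delta_stats(p: PairedMeasures) -> Tuple[float, float, float]:
    """(mean delta, mean |delta|, max |delta|) with delta = retest - test."""
    d = p.delta
    return float(d.mean()), float(np.abs(d).mean()), float(np.abs(d).max())


def mse_paired(p: PairedMeasures) -> float:
    """Mean over subjects of (retest - test)^2."""
    return float((p.delta ** 2).mean())


def _anova_two_way(data: np.ndarray):
    """Mean squares of the two-way single-replication ANOVA decomposition.

    ``data`` is n subjects x k measurements.  Returns (MSR, MSC, MSE).
    """
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1(p: PairedMeasures, alpha: float = 0.05) -> ICCResult:
    """Two-way mixed, single-measure, absolute-agreement ICC(A,1).

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)); the
    confidence interval is the McGraw-Wong F-based interval.
    """
    if p.n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    data = np.column_stack([p.test, p.retest])
    n, k = data.shape
    if np.allclose(data, data.flat[0]):
        raise ValueError("zero total variance: ICC undefined")
    msr, msc, mse = _anova_two_way(data)
    if np.array_equal(p.test, p.retest):
        # identical columns: MSC and MSE are analytically zero, so the
        # estimate is exactly 1 (avoids float noise in the sums of squares)
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0, msr=float(msr),
                         msc=0.0, mse_ms=0.0, n=n, k=k)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise ValueError("zero total variance: ICC undefined")
    icc = (msr - mse) / denom
    icc = float(np.clip(icc, -1.0, 1.0))

    if mse == 0 and msc == 0:
        # perfect agreement: degenerate interval
        lo = hi = icc
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
        if np.isfinite(a) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr)
        else:
            lo, hi = icc, icc
        lo = float(np.clip(lo, -1.0, icc))
        hi = float(np.clip(hi, icc, 1.0))
    return ICCResult(icc=icc, ci_low=lo, ci_high=hi, msr=float(msr),
                     msc=float(msc), mse_ms=float(mse), n=n, k=k)


# ---------------------------------------------------------------------------
# Significance simulation
# ---------------------------------------------------------------------------

def power_simulation(cfg: PowerSimConfig) -> Tuple[float, float]:
    """Detectability of a small mean change between two groups.

    Analytic branch: the two-sample t-test p-value at exactly the stated
    group means (difference ``true_change``) and common SD.  Monte-Carlo
    branch: fraction of ``reps`` seeded replicate experiments achieving
    p < 0.05.
    """
    n = cfg.n_per_group
    se = cfg.sd * np.sqrt(2.0 / n)
    t = cfg.true_change / se
    df = 2 * n - 2
    if cfg.sided == "two":
        p_analytic = 2.0 * stats.t.sf(abs(t), df)
    else:
        p_analytic = stats.t.sf(t, df)

    rng = np.random.default_rng(cfg.seed)
    hits = 0
    for _ in range(cfg.reps):
        g1 = rng.normal(0.0, cfg.sd, n)
        g2 = rng.normal(cfg.true_change, cfg.sd, n)
        res = stats.ttest_ind(g2, g1)
        p = res.pvalue if cfg.sided == "two" else (
            res.pvalue / 2 if res.statistic > 0 else 1 - res.pvalue / 2)
        if p < 0.05:
            hits += 1
    power = hits / cfg.reps
    return float(p_analytic), float(power)
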