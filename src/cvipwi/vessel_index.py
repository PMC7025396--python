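"""Temporal signal-variance mapping and collateral vessel index (CVI).

In T2*-weighted DSC perfusion raw data, large (pial) vessels show a deep,
sharp bolus-related signal drop at comparatively low mean intensity, so the
temporal coefficient of variation CV = sigma/mu is markedly higher in
vessels than in parenchyma.  Thresholding the CV map at the upper half of
its robust intensity range isolates a "highCV" vessel compartment; after
removing ventricular CSF, the lowest-intensity voxels at the bolus peak
(outer CSF / partial-volume cortex) and everything outside the
leptomeningeal vessel-atlas compartment, the collateral vessel index is the
ratio of the remaining highCV volume on the affected hemisphere to that on
the unaffected hemisphere:

    CVI = highCV_affected (mm^3) / highCV_unaffected (mm^3)

A CVI near 1 means symmetric (well-collateralized) pial vasculature; values
well below 1 indicate poor collateral supply on the affected side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import BinaryMask, Geometry, HemisphereSplit, PerfusionSeries, ScalarMap
from .errors import DegenerateInputError, UndefinedIndexError

__all__ = [
    "CviResult",
    "temporal_stats",
    "cv_map",
    "robust_range",
    "threshold_highcv",
    "bolus_peak_index",
    "strip_low_intensity",
    "exclude_ventricles",
    "leptomeningeal_mask",
    "compute_cvi",
]


@dataclass
class CviResult:
    """Collateral vessel index with its intermediates."""

    cvi: float
    highcv_affected_mm3: float
    highcv_unaffected_mm3: float
    highcv_mask: BinaryMask
    cv_map: ScalarMap
    threshold_used: float
    bolus_peak_index: int

    def dichotomize(self, cutoff: float = 0.963) -> str:
        """Collateral status at the published cutoff (>= is good/moderate)."""
        return "good_moderate" if self.cvi >= cutoff else "poor"


def temporal_stats(
    series: PerfusionSeries, brain: BinaryMask
) -> Tuple[ScalarMap, ScalarMap]:
    """Per-voxel temporal standard deviation and mean inside the brain.

    sigma uses the population (1/N) normalization.  Voxels outside the
    brain mask are set to 0 in both maps.
    """
    series.geometry.require_match(brain.geometry, "series and brain mask")
    mu = series.data.mean(axis=3)
    sigma = series.data.std(axis=3)  # ddof=0
    outside = ~brain.data
    mu[outside] = 0.0
    sigma[outside] = 0.0
    return (
        ScalarMap(sigma, series.geometry, units="a.u."),
        ScalarMap(mu, series.geometry, units="a.u."),
    )


def cv_map(sigma: ScalarMap, mu: ScalarMap) -> ScalarMap:
    """Coefficient of variation CV = sigma/mu, dimensionless.

    Voxels with mu at or below a machine-scale floor (1e-6 times the median
    positive mu) get CV = 0 so that background never enters the robust
    range.
    """
    sigma.geometry.require_match(mu.geometry, "sigma and mu maps")
    mu_pos = mu.data[mu.data > 0]
    eps = 1e-6 * float(np.median(mu_pos)) if mu_pos.size else 0.0
    cv = np.zeros_like(mu.data)
    ok = mu.data > eps
    cv[ok] = sigma.data[ok] / mu.data[ok]
    return ScalarMap(cv, sigma.geometry, units="dimensionless")


def robust_range(
    map_: ScalarMap,
    mask: BinaryMask,
    lower_pct: float = 2.0,
    upper_pct: float = 98.0,
) -> Tuple[float, float]:
    """Robust intensity range of the strictly positive in-mask values.

    The 2nd and 98th percentiles (linear interpolation) trim extreme tails,
    mirroring the "robust range" convention of common FMRI viewers.
    """
    map_.geometry.require_match(mask.geometry, "map and mask")
    values = map_.data[mask.data]
    values = values[values > 0]
    if values.size < 100:
        raise DegenerateInputError(
            f"robust range needs >= 100 positive in-mask voxels, got {values.size}"
        )
    rmin, rmax = np.percentile(values, [lower_pct, upper_pct])
    return float(rmin), float(rmax)


def threshold_highcv(
    cv: ScalarMap,
    mask: BinaryMask,
    range_fraction: float = 0.5,
    lower_pct: float = 2.0,
    upper_pct: float = 98.0,
) -> Tuple[BinaryMask, float]:
    """Keep the upper part of the CV robust range (default: upper 50%).

    Returns the highCV mask and the CV threshold used.  The comparison is
    inclusive (>=) so a constant map keeps all in-mask voxels.
    """
    rmin, rmax = robust_range(cv, mask, lower_pct, upper_pct)
    thr = rmin + range_fraction * (rmax - rmin)
    high = (cv.data >= thr) & mask.data
    return BinaryMask(high, cv.geometry, label="highCV"), float(thr)


def bolus_peak_index(series: PerfusionSeries, brain: BinaryMask) -> int:
    """Time point of the maximum contrast-induced signal decrease.

    The volume index minimizing the in-brain mean signal; ties break to the
    earliest index.
    """
    series.geometry.require_match(brain.geometry, "series and brain mask")
    if brain.count == 0:
        raise DegenerateInputError("empty brain mask")
    course = series.data[brain.data].mean(axis=0)
    return int(np.argmin(course))


def strip_low_intensity(
    highcv: BinaryMask,
    series: PerfusionSeries,
    t_star: int,
    fraction: float = 0.05,
    scope: BinaryMask | None = None,
) -> BinaryMask:
    """Remove the lowest-intensity fraction of highCV voxels at the bolus peak.

    Outer CSF and cortex adjacent to pial vessels show high CV at very low
    signal; subtracting the ``fraction`` (default 5%) of voxels with the
    lowest signal at t* suppresses them and partial-volume effects.  The
    intensity quantile is computed over the highCV voxels themselves unless
    a different ``scope`` mask is given.  Voxels strictly below the quantile
    are removed, so an all-equal intensity set is left untouched.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if not 0 <= t_star < series.n_volumes:
        raise ValueError(f"t_star {t_star} outside series of {series.n_volumes}")
    highcv.geometry.require_match(series.geometry, "highCV and series")
    if highcv.count == 0:
        warnings.warn("strip_low_intensity: highCV mask is empty")
        return BinaryMask(highcv.data.copy(), highcv.geometry, label=highcv.label)
    if fraction == 0:
        return BinaryMask(highcv.data.copy(), highcv.geometry, label=highcv.label)
    frame = series.data[..., t_star]
    pool = frame[(scope.data if scope is not None else highcv.data)]
    q = np.quantile(pool, fraction)
    keep = highcv.data & ~(frame < q)
    return BinaryMask(keep, highcv.geometry, label=highcv.label)


def exclude_ventricles(highcv: BinaryMask, ventricles: BinaryMask) -> BinaryMask:
    """Remove ventricular CSF and choroid plexus from the highCV mask."""
    return highcv.subtract(ventricles, label=highcv.label)


def leptomeningeal_mask(
    atlas_density: ScalarMap, sinus_veins: BinaryMask
) -> BinaryMask:
    """Binary leptomeningeal compartment from a vessel-density atlas.

    Positive-density atlas voxels minus the venous sinuses and large
    cerebral veins.  The spatial extent of the compartment (lateral and
    cranial convexity) is taken from the atlas file's own support.
    """
    atlas_density.geometry.require_match(sinus_veins.geometry, "atlas and sinus mask")
    lepto = (atlas_density.data > 0) & ~sinus_veins.data
    return BinaryMask(lepto, atlas_density.geometry, label="leptomeningeal")


def compute_cvi(
    highcv: BinaryMask,
    lepto: HemisphereSplit,
    geometry: Geometry,
    cv: ScalarMap | None = None,
    threshold_used: float = float("nan"),
    t_star: int = -1,
) -> CviResult:
    """Collateral vessel index from the final highCV mask.

    Volumes are in-compartment highCV voxel counts times the voxel volume
    in mm^3; CVI = affected / unaffected.  A zero unaffected volume leaves
    the index undefined and raises rather than returning infinity.
    """
    geometry.require_match(highcv.geometry, "highCV and geometry")
    vv = geometry.voxel_volume
    aff = highcv.intersect(lepto.affected).count * vv
    unaff = highcv.intersect(lepto.unaffected).count * vv
    if unaff <= 0:
        raise UndefinedIndexError(
            "CVI undefined: no highCV voxels in the unaffected leptomeningeal "
            "compartment"
        )
    return CviResult(
        cvi=aff / unaff,
        highcv_affected_mm3=aff,
        highcv_unaffected_mm3=unaff,
        highcv_mask=highcv,
        cv_map=cv if cv is not None else ScalarMap(
            np.zeros(geometry.shape), geometry, units="dimensionless"
        ),
        threshold_used=threshold_used,
        bolus_peak_index=t_star,
    )


def extract_highcv(
    series: PerfusionSeries,
    brain: BinaryMask,
    ventricles: BinaryMask,
    range_fraction: float = 0.5,
    lower_pct: float = 2.0,
    upper_pct: float = 98.0,
    strip_fraction: float = 0.05,
    strip_scope: str = "highcv",
) -> Tuple[BinaryMask, ScalarMap, float, int]:
    """Full highCV extraction: CV map -> threshold -> ventricle exclusion
    -> low-intensity strip.

    Returns (highCV mask, CV map, threshold, bolus peak index).  The series
    is assumed motion-corrected.
    """
    sigma, mu = temporal_stats(series, brain)
    cv = cv_map(sigma, mu)
    high, thr = threshold_highcv(cv, brain, range_fraction, lower_pct, upper_pct)
    high = exclude_ventricles(high, ventricles)
    t_star = bolus_peak_index(series, brain)
    scope = brain if strip_scope == "brain" else None
    high = strip_low_intensity(high, series, t_star, strip_fraction, scope=scope)
    return high, cv, thr, t_star
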