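"""Threshold-defined ischaemic core, TTP-delay compartments, mismatch
ratios and the hypoperfusion intensity ratio (HIR).

The ischaemic core is the ADC < 600e-6 mm^2/s compartment.  Hypoperfusion
is graded on non-deconvolved time-to-peak (TTP) maps referenced to the
contralesional hemisphere: TTP-delay = TTP minus the median TTP of the
unaffected hemisphere.  Tissue at risk is delay >= 4.5 s (equivalent to
Tmax >= 6 s), severe hypoperfusion is delay >= 9.5 s (Tmax >= 10 s), and
HIR = severe / at-risk volume.  Mismatch ratios divide perfusion-lesion
volumes by the acute diffusion-lesion volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .core import BinaryMask, Geometry, PerfusionSeries, ScalarMap
from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "LesionReport",
    "segment_core",
    "ttp_map",
    "ttp_delay",
    "compartments",
    "mismatch_ratios",
    "clean_lesion",
    "cortical_volume",
    "normalize_adc_units",
]


@dataclass
class LesionReport:
    """Per-case lesion volumetry (all volumes in mm^3)."""

    core_mm3: float
    core_cortical_mm3: Optional[float]
    perfusion_lesion_mm3: float   # TTP-delay > 0
    at_risk_mm3: float            # TTP-delay >= 4.5 s
    severe_mm3: float             # TTP-delay >= 9.5 s
    mismatch_entire: Optional[float]
    mismatch_at_risk: Optional[float]
    hir: float
    contralesional_median_ttp_s: float

    def __post_init__(self):
        if not self.severe_mm3 <= self.at_risk_mm3 <= self.perfusion_lesion_mm3 + 1e-9:
            raise ValueError("lesion compartments must be nested")
        if not 0.0 <= self.hir <= 1.0:
            raise ValueError(f"HIR must lie in [0, 1], got {self.hir}")


def normalize_adc_units(adc: ScalarMap, brain: BinaryMask, units: str = "auto") -> ScalarMap:
    """Return the ADC map in mm^2/s.

    ``units`` may be "mm2/s", "1e-6 mm2/s", or "auto".  Auto-detection uses
    the in-brain median: values in [100, 3000] indicate the 1e-6 mm^2/s
    convention, values in [1e-4, 3e-3] plain mm^2/s; anything else requires
    an explicit declaration.
    """
    if units in ("mm2/s", "mm^2/s"):
        return ScalarMap(adc.data.copy(), adc.geometry, units="mm2/s")
    if units in ("1e-6 mm2/s", "um2/s", "1e-6 mm^2/s"):
        return ScalarMap(adc.data * 1e-6, adc.geometry, units="mm2/s")
    if units != "auto":
        raise ConfigurationError(f"unknown ADC unit tag {units!r}")
    vals = adc.data[brain.data & (adc.data > 0)]
    if vals.size == 0:
        raise ConfigurationError("cannot auto-detect ADC units: no positive in-brain voxels")
    med = float(np.median(vals))
    if 100 <= med <= 3000:
        return ScalarMap(adc.data * 1e-6, adc.geometry, units="mm2/s")
    if 1e-4 <= med <= 3e-3:
        return ScalarMap(adc.data.copy(), adc.geometry, units="mm2/s")
    raise ConfigurationError(
        f"ADC units ambiguous (in-brain median {med:.3g}); declare adc_units"
    )


def clean_lesion(
    mask: BinaryMask, brain: BinaryMask, min_component_mm3: float = 300.0
) -> BinaryMask:
    """Automatic artifact correction for thresholded lesion masks.

    Restricts the mask to the brain, removes 26-connected components
    smaller than ``min_component_mm3`` and fills fully enclosed holes.
    """
    mask.geometry.require_match(brain.geometry, "lesion and brain masks")
    data = mask.data & brain.data
    if not data.any():
        return BinaryMask(data, mask.geometry, label=mask.label)
    labels = measure.label(data, connectivity=3)  # 26-connectivity in 3D
    min_vox = min_component_mm3 / mask.geometry.voxel_volume
    counts = np.bincount(labels.ravel())
    keep = counts >= min_vox
    keep[0] = False
    data = keep[labels]
    data = ndi.binary_fill_holes(data)
    return BinaryMask(data, mask.geometry, label=mask.label)


def segment_core(
    adc: ScalarMap,
    brain: BinaryMask,
    threshold: float = 600e-6,
    units: str = "auto",
    min_component_mm3: float = 300.0,
) -> BinaryMask:
    """Ischaemic core: 0 < ADC < threshold (mm^2/s) within the brain.

    Zero-ADC voxels (background / masked-out) are excluded, and the result
    is artifact-corrected with :func:`clean_lesion`.
    """
    adc.geometry.require_match(brain.geometry, "ADC and brain mask")
    adc_si = normalize_adc_units(adc, brain, units)
    raw = (adc_si.data > 0) & (adc_si.data < threshold) & brain.data
    return clean_lesion(
        BinaryMask(raw, adc.geometry, label="ischaemic_core"), brain,
        min_component_mm3,
    )


def ttp_map(series: PerfusionSeries, brain: BinaryMask) -> ScalarMap:
    """Non-deconvolved time-to-peak in seconds.

    For T2*-weighted DSC data the bolus peak is the signal *minimum*, so
    TTP = tr * argmin_t S(v, t) at frame resolution, ties to the earliest
    frame.  Outside the brain the map is NaN.
    """
    series.geometry.require_match(brain.geometry, "series and brain mask")
    ttp = series.tr * np.argmin(series.data, axis=3).astype(float)
    ttp[~brain.data] = np.nan
    return ScalarMap(ttp, series.geometry, units="s")


def ttp_delay(ttp: ScalarMap, brain_unaffected: BinaryMask) -> Tuple[ScalarMap, float]:
    """TTP-delay referenced to the contralesional hemisphere.

    delay = max(0, TTP - median TTP over the unaffected-hemisphere brain
    voxels).  Returns the delay map (NaN preserved outside the brain) and
    the reference median in seconds.
    """
    ttp.geometry.require_match(brain_unaffected.geometry, "TTP and reference mask")
    ref = ttp.data[brain_unaffected.data]
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise DegenerateInputError("empty contralesional reference mask")
    median = float(np.median(ref))
    delay = ttp.data - median
    np.clip(delay, 0.0, None, out=delay)  # NaN passes through
    return ScalarMap(delay, ttp.geometry, units="s"), median


@dataclass
class DelayCompartments:
    """Perfusion-lesion compartments derived from a TTP-delay map."""

    perfusion_lesion: BinaryMask  # delay > 0
    at_risk: BinaryMask           # delay >= at_risk threshold
    severe: BinaryMask            # delay >= severe threshold
    mismatch_region: BinaryMask   # perfusion lesion minus core
    hir: float

    def volumes_mm3(self):
        return (
            self.perfusion_lesion.volume_mm3,
            self.at_risk.volume_mm3,
            self.severe.volume_mm3,
        )


def compartments(
    delay: ScalarMap,
    core: BinaryMask,
    brain: BinaryMask,
    at_risk_s: float = 4.5,
    severe_s: float = 9.5,
    min_component_mm3: float = 300.0,
    restrict_to: Optional[BinaryMask] = None,
) -> DelayCompartments:
    """Grade hypoperfusion severity from the TTP-delay map.

    The perfusion lesion is delay > 0; tissue at risk delay >= 4.5 s;
    severe hypoperfusion delay >= 9.5 s.  All three are artifact-corrected
    with the same :func:`clean_lesion` parameters, the core is subtracted
    from the perfusion lesion to form the mismatch region, and
    HIR = severe / at-risk volume (0 when there is no tissue at risk).
    ``restrict_to`` optionally confines the lesion to a hemisphere or
    vascular territory.
    """
    delay.geometry.require_match(core.geometry, "delay map and core")
    d = delay.data
    domain = brain.data if restrict_to is None else (brain.data & restrict_to.data)
    with np.errstate(invalid="ignore"):
        lesion_raw = (d > 0) & domain
        at_risk_raw = (d >= at_risk_s) & domain
        severe_raw = (d >= severe_s) & domain
    geom = delay.geometry

    def clean(arr, label):
        return clean_lesion(BinaryMask(arr, geom, label), brain, min_component_mm3)

    lesion = clean(lesion_raw, "perfusion_lesion")
    at_risk = clean(at_risk_raw, "tissue_at_risk")
    severe = clean(severe_raw, "severe_hypoperfusion")
    mismatch = lesion.subtract(core, label="mismatch_region")
    hir = severe.volume_mm3 / at_risk.volume_mm3 if at_risk.count > 0 else 0.0
    return DelayCompartments(lesion, at_risk, severe, mismatch, hir)


def mismatch_ratios(
    perfusion_lesion_mm3: float,
    at_risk_mm3: float,
    dwi_lesion_mm3: float,
) -> Tuple[Optional[float], Optional[float]]:
    """Entire and at-risk PWI/DWI mismatch ratios.

    Both divide by the acute diffusion-lesion volume; a zero DWI lesion
    leaves the ratios undefined (returned as None) rather than infinite.
    """
    if dwi_lesion_mm3 <= 0:
        return None, None
    return perfusion_lesion_mm3 / dwi_lesion_mm3, at_risk_mm3 / dwi_lesion_mm3


def cortical_volume(
    core: BinaryMask, cortex: BinaryMask, geometry: Geometry
) -> Tuple[float, float]:
    """Cortical and subcortical parts of the core volume, mm^3."""
    geometry.require_match(core.geometry, "core and geometry")
    core.geometry.require_match(cortex.geometry, "core and cortex masks")
    cortical = core.intersect(cortex).count * geometry.voxel_volume
    total = core.count * geometry.voxel_volume
    return cortical, total - cortical
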