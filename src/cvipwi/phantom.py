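"""Synthetic 4D DSC phantoms with ground-truth compartments.

The phantom emulates a gradient-echo EPI bolus-passage acquisition in
acute large-vessel stroke: an ellipsoidal brain with CSF-filled
ventricles, a pial vessel shell along the lateral/cranial convexity, a
midline venous-sinus strip, a cortical ribbon, and an optional ischaemic
core block with lowered ADC.  Signal-time curves follow a peak-normalized
gamma-variate bolus: vessels show a deep (~50% of baseline) sharp drop,
parenchyma a shallow (~15%) drop, CSF none.  Inter-hemispheric collateral
asymmetry is controlled by thinning the pial vessel shell on one side so
that affected = asymmetry_ratio x unaffected vessel volume, and affected-
side kinetics can be delayed to create TTP-delay lesions.

Every mask the pipeline consumes (brain, ventricles, vessel-density atlas,
sinus, cortex) is returned as ground truth, so each processing stage can
be verified against construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .core import BinaryMask, Geometry, PerfusionSeries, ScalarMap

__all__ = ["PhantomSpec", "Phantom", "gamma_variate", "build_phantom", "default_suite"]


def gamma_variate(
    t: np.ndarray, t0: float, alpha: float, beta: float, amplitude: float
) -> np.ndarray:
    """Peak-normalized gamma-variate bolus curve.

    0 for t < t0; for t >= t0,
    amplitude * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta),
    which peaks at exactly ``amplitude`` at t = t0 + alpha*beta.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"gamma-variate needs alpha, beta > 0, got {alpha}, {beta}")
    t = np.asarray(t, dtype=float)
    dt = t - t0
    out = np.zeros_like(t)
    pos = dt > 0
    x = dt[pos] / (alpha * beta)
    out[pos] = amplitude * x**alpha * np.exp(alpha - dt[pos] / beta)
    return out


@dataclass
class PhantomSpec:
    """Parameters of a synthetic DSC acquisition.

    Defaults emulate the clinical protocol at half matrix: 64x64x19 voxels
    of 1.8 x 1.8 x 5.2 mm (4 mm slices + 1.2 mm gap), 67 volumes at
    TR = 1.5 s, bolus arrival 24 s with the peak near volume 19.
    """

    name: str = "phantom"
    shape: Tuple[int, int, int] = (64, 64, 19)
    voxel_size: Tuple[float, float, float] = (1.8, 1.8, 5.2)
    n_volumes: int = 67
    tr: float = 1.5
    baseline: Dict[str, float] = field(
        default_factory=lambda: {"vessel": 150.0, "parenchyma": 240.0, "csf": 250.0}
    )
    bolus_t0: float = 24.0
    bolus_alpha: float = 3.0
    bolus_beta: float = 1.5
    # bolus amplitude as a fraction of the compartment baseline
    drop_fraction: Dict[str, float] = field(
        default_factory=lambda: {"vessel": 0.5, "parenchyma": 0.15, "csf": 0.0}
    )
    asymmetry_ratio: float = 1.0   # affected / unaffected pial vessel volume
    delay_affected: float = 0.0    # s added to affected-side bolus arrival
    noise_sigma: float = 5.0       # a.u. Gaussian noise (baseline SNR ~ 48)
    motion: Optional[Sequence[Tuple[float, float, float]]] = None  # voxel shifts
    affected_side: str = "left"
    with_core: bool = True
    core_block: Tuple[int, int, int] = (10, 20, 5)  # voxels; 1000-voxel core
    adc_values: Dict[str, float] = field(
        default_factory=lambda: {"parenchyma": 800.0, "csf": 3000.0, "core": 450.0}
    )  # 1e-6 mm^2/s
    seed: int = 0

    def __post_init__(self):
        if any(f < 0 for f in self.drop_fraction.values()):
            raise ValueError("bolus amplitudes must be >= 0")
        v = self.drop_fraction["vessel"] * self.baseline["vessel"]
        p = self.drop_fraction["parenchyma"] * self.baseline["parenchyma"]
        if v <= p:
            raise ValueError("vessel bolus amplitude must exceed parenchyma's")
        if self.asymmetry_ratio < 0:
            raise ValueError("asymmetry_ratio must be >= 0")
        if self.motion is not None and len(self.motion) != self.n_volumes:
            raise ValueError("motion must give one shift per volume")

    @property
    def geometry(self) -> Geometry:
        affine = np.diag(list(self.voxel_size) + [1.0])
        affine[:3, 3] = -(np.array(self.shape) - 1) / 2 * np.array(self.voxel_size)
        return Geometry(self.shape, self.voxel_size, affine, left_right_axis=0)


@dataclass
class Phantom:
    """A built phantom: the series, the ADC map and all truth masks."""

    series: PerfusionSeries
    adc: ScalarMap
    brain: BinaryMask
    ventricles: BinaryMask
    vessels_affected: BinaryMask
    vessels_unaffected: BinaryMask
    atlas_density: ScalarMap
    sinus: BinaryMask
    cortex: BinaryMask
    core: BinaryMask
    delay_region: BinaryMask
    spec: PhantomSpec

    @property
    def vessels(self) -> BinaryMask:
        return BinaryMask(
            self.vessels_affected.data | self.vessels_unaffected.data,
            self.brain.geometry, label="pial_vessels",
        )


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, semi):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _inplane_boundary(mask3d: np.ndarray, width: int = 1) -> np.ndarray:
    """Per-slice ring of given width (2D erosion, 4-connectivity)."""
    out = np.zeros_like(mask3d)
    structure = ndi.generate_binary_structure(2, 1)
    for k in range(mask3d.shape[2]):
        sl = mask3d[:, :, k]
        if not sl.any():
            continue
        out[:, :, k] = sl & ~ndi.binary_erosion(sl, structure, iterations=width)
    return out


def _thin_to(flat_idx: np.ndarray, k: int) -> np.ndarray:
    """Keep k evenly spaced entries of a sorted index list (deterministic)."""
    n = flat_idx.size
    if k >= n:
        return flat_idx
    pick = (np.arange(k) * n) // k
    return flat_idx[pick]


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Construct the series, ADC map and truth masks from a spec.

    All randomness (noise only) is driven by ``spec.seed``; truth masks
    depend solely on the deterministic geometry parameters.
    """
    nx, ny, nz = spec.shape
    geom = spec.geometry
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2

    # brains are anteroposteriorly elongated: eccentric axial cross-section
    brain = _ellipsoid(spec.shape, (cx, cy, cz), (0.36 * nx, 0.44 * ny, 0.45 * nz))
    vent_semi = (0.047 * nx, 0.125 * ny, 0.13 * nz)
    dx = 0.086 * nx
    ventricles = _ellipsoid(spec.shape, (cx - dx, cy, cz), vent_semi) | _ellipsoid(
        spec.shape, (cx + dx, cy, cz), vent_semi
    )
    ventricles &= brain

    shell = _inplane_boundary(brain)
    shell[:, :, :2] = False  # pial compartment: lateral and cranial convexity
    xs = np.arange(nx)[:, None, None]
    midline = np.abs(xs - cx) <= 0.04 * nx
    sinus = shell & np.broadcast_to(midline, spec.shape)
    lepto_shell = shell & ~sinus

    # hemisphere halves (even axis: exact midplane between nx/2-1 and nx/2)
    left = np.zeros(spec.shape, dtype=bool)
    left[: nx // 2] = True
    right = np.zeros(spec.shape, dtype=bool)
    right[(nx + 1) // 2:] = True
    aff_half, unaff_half = (left, right) if spec.affected_side == "left" else (right, left)

    # vessel shell thinning to realize the requested volume asymmetry
    aff_idx = np.flatnonzero((lepto_shell & aff_half).ravel())
    unaff_idx = np.flatnonzero((lepto_shell & unaff_half).ravel())
    r = spec.asymmetry_ratio
    if r <= 1.0:
        keep_aff = _thin_to(aff_idx, int(round(r * unaff_idx.size)))
        keep_unaff = unaff_idx
    else:
        keep_aff = aff_idx
        keep_unaff = _thin_to(unaff_idx, int(round(aff_idx.size / r)))
    if keep_unaff.size == 0:
        raise ValueError("spec empties the unaffected vessel shell")
    vessels_aff = np.zeros(brain.size, dtype=bool)
    vessels_aff[keep_aff] = True
    vessels_aff = vessels_aff.reshape(spec.shape)
    vessels_unaff = np.zeros(brain.size, dtype=bool)
    vessels_unaff[keep_unaff] = True
    vessels_unaff = vessels_unaff.reshape(spec.shape)
    vessels = vessels_aff | vessels_unaff

    band = np.zeros_like(brain)
    structure = ndi.generate_binary_structure(2, 1)
    for k in range(nz):
        sl = brain[:, :, k]
        if sl.any():
            band[:, :, k] = sl & ~ndi.binary_erosion(sl, structure, iterations=3)
    cortex = band & ~vessels & ~sinus & ~ventricles

    core = np.zeros(spec.shape, dtype=bool)
    if spec.with_core:
        bxl, byl, bzl = spec.core_block
        x0 = int(round(0.28 * nx - bxl / 2))  # MCA territory, affected side
        y0 = int(round(ny / 2 - byl / 2))
        z0 = int(round(nz / 2 - bzl / 2))
        core[x0:x0 + bxl, y0:y0 + byl, z0:z0 + bzl] = True
        if spec.affected_side == "right":
            core = core[::-1]
        core &= brain & ~ventricles & ~vessels
    delay_region = (aff_half & brain) if spec.delay_affected > 0 else np.zeros_like(brain)

    # signal-time curves per compartment x hemisphere
    t = np.arange(spec.n_volumes) * spec.tr
    data = np.zeros(spec.shape + (spec.n_volumes,), dtype=float)
    parenchyma = brain & ~vessels & ~sinus & ~ventricles
    comp_masks = {
        "vessel": vessels | sinus,
        "parenchyma": parenchyma,
        "csf": ventricles,
    }
    for comp, cmask in comp_masks.items():
        base = spec.baseline[comp]
        amp = spec.drop_fraction[comp] * base
        for half, t0 in (
            (unaff_half, spec.bolus_t0),
            (aff_half, spec.bolus_t0 + spec.delay_affected),
        ):
            sel = cmask & half
            if sel.any():
                data[sel, :] = base - gamma_variate(t, t0, spec.bolus_alpha,
                                                    spec.bolus_beta, amp)

    if spec.motion is not None:
        for ti, shift in enumerate(spec.motion):
            if any(s != 0 for s in shift):
                data[..., ti] = ndi.shift(
                    data[..., ti], shift, order=1, cval=0.0, mode="constant"
                )

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    np.clip(data, 0.0, None, out=data)

    adc = np.zeros(spec.shape, dtype=float)
    adc[brain] = spec.adc_values["parenchyma"]
    adc[ventricles] = spec.adc_values["csf"]
    adc[core] = spec.adc_values["core"]

    mk = lambda arr, label: BinaryMask(arr, geom, label=label)
    return Phantom(
        series=PerfusionSeries(data, geom, tr=spec.tr),
        adc=ScalarMap(adc, geom, units="1e-6 mm2/s"),
        brain=mk(brain, "brain"),
        ventricles=mk(ventricles, "ventricles"),
        vessels_affected=mk(vessels_aff, "pial_vessels_affected"),
        vessels_unaffected=mk(vessels_unaff, "pial_vessels_unaffected"),
        atlas_density=ScalarMap(shell.astype(float), geom, units="a.u."),
        sinus=mk(sinus, "sinus_veins"),
        cortex=mk(cortex, "cortex"),
        core=mk(core, "true_core"),
        delay_region=mk(delay_region, "true_delay_region"),
        spec=spec,
    )


def single_volume_shift(
    n_volumes: int, volume: int, shift: Tuple[float, float, float]
) -> List[Tuple[float, float, float]]:
    """Motion schedule with one displaced volume, all others still."""
    sched = [(0.0, 0.0, 0.0)] * n_volumes
    sched[volume] = tuple(float(s) for s in shift)
    return sched


def default_suite() -> List[PhantomSpec]:
    """Named phantom specs covering the study conditions used in tests."""
    base = PhantomSpec()
    return [
        replace(base, name="symmetric-noisefree", noise_sigma=0.0),
        replace(base, name="symmetric"),
        replace(base, name="asymmetry-0.25", asymmetry_ratio=0.25),
        replace(base, name="asymmetry-0.5", asymmetry_ratio=0.5),
        replace(base, name="asymmetry-1.5", asymmetry_ratio=1.5),
        replace(base, name="delayed-6s", delay_affected=6.0),
        replace(base, name="severe-delay", delay_affected=10.5),
        replace(
            base, name="motion-2vox",
            motion=single_volume_shift(base.n_volumes, base.n_volumes // 2,
                                       (2.0, 0.0, 0.0)),
        ),
        replace(base, name="noisy", noise_sigma=10.0),
    ]
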