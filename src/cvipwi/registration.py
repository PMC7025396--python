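"""Rigid registration: motion correction of the DSC series and
coregistration of diffusion-derived maps into perfusion space.

The contract is 6-DOF rigid registration with the temporal mean volume as
motion-correction reference and a multi-resolution similarity optimization
(default metric: Pearson correlation, switchable to Mattes mutual
information).  SimpleITK provides the optimizer; resampling is done with
scipy so that out-of-field handling (NaN for scalar maps, 0 for masks and
series volumes) is explicit.

Transforms are stored as 4x4 world-space (mm, RAS) matrices mapping points
of the *fixed* image to points of the *moving* image — the resampling
convention, compatible with the row-major text matrices written by
``RigidTransform.save``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core import BinaryMask, Geometry, PerfusionSeries, ScalarMap
from .errors import RegistrationError

__all__ = ["RigidTransform", "motion_correct", "coregister", "apply_transform"]

# RAS <-> LPS change of basis (ITK works in LPS world coordinates)
_FLIP = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass
class RigidTransform:
    """6-DOF world-space transform (mm, RAS), fixed-to-moving points."""

    matrix: np.ndarray  # 4x4
    cost_value: float = float("nan")

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("rigid transform must be 4x4")
        R = self.matrix[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-5):
            raise ValueError("rotation block is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-5):
            raise ValueError("rotation block must be proper (det +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4), cost_value=0.0)

    @property
    def translation_mm(self) -> np.ndarray:
        return self.matrix[:3, 3].copy()

    @property
    def rotation_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        R = self.matrix[:3, :3]
        c = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix), self.cost_value)

    def save(self, path: Union[str, Path]) -> None:
        np.savetxt(str(path), self.matrix, fmt="%.10g")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RigidTransform":
        return cls(np.loadtxt(str(path)))


def _as_sitk(data: np.ndarray, geometry: Geometry) -> sitk.Image:
    """3D numpy array + RAS affine -> SimpleITK image (LPS)."""
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(np.asarray(data, dtype=np.float64).transpose(2, 1, 0))
    )
    lps = _FLIP @ geometry.affine
    M = lps[:3, :3]
    spacing = np.linalg.norm(M, axis=0)
    direction = M / spacing
    img.SetSpacing(tuple(spacing))
    img.SetDirection(tuple(direction.ravel()))
    img.SetOrigin(tuple(lps[:3, 3]))
    return img


def _physical_bounds(geometry: Geometry) -> Tuple[np.ndarray, np.ndarray]:
    """Axis-aligned world-space bounding box of a grid (RAS mm)."""
    shape = np.array(geometry.shape)
    corners = np.array(
        [[i, j, k, 1.0] for i in (0, shape[0] - 1)
         for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)]
    )
    pts = (geometry.affine @ corners.T).T[:, :3]
    return pts.min(axis=0), pts.max(axis=0)


def _fov_overlap_fraction(a: Geometry, b: Geometry) -> float:
    amin, amax = _physical_bounds(a)
    bmin, bmax = _physical_bounds(b)
    inter = np.minimum(amax, bmax) - np.maximum(amin, bmin)
    if np.any(inter <= 0):
        return 0.0
    return float(np.prod(inter) / np.prod(amax - amin))


def _euler_to_matrix_ras(tfm: sitk.Euler3DTransform) -> np.ndarray:
    R = np.array(tfm.GetMatrix()).reshape(3, 3)
    c = np.array(tfm.GetCenter())
    t = np.array(tfm.GetTranslation())
    lps = np.eye(4)
    lps[:3, :3] = R
    lps[:3, 3] = t + c - R @ c
    return _FLIP @ lps @ _FLIP


def _register(
    fixed: sitk.Image,
    moving: sitk.Image,
    metric: str = "correlation",
    shrink=(4, 2, 1),
    sigmas=(2.0, 1.0, 0.0),
    iterations: int = 200,
) -> Tuple[np.ndarray, float]:
    reg = sitk.ImageRegistrationMethod()
    if metric == "correlation":
        reg.SetMetricAsCorrelation()
    elif metric == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
    else:
        raise RegistrationError(f"unknown similarity metric {metric!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)  # dense sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=iterations,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    init = sitk.CenteredTransformInitializer(
        fixed, moving, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    reg.SetInitialTransform(init, inPlace=False)
    reg.SetShrinkFactorsPerLevel(list(shrink))
    reg.SetSmoothingSigmasPerLevel(list(sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    out = reg.Execute(fixed, moving)
    euler = sitk.Euler3DTransform(out.GetNthTransform(0)
                                  if isinstance(out, sitk.CompositeTransform)
                                  else out)
    return _euler_to_matrix_ras(euler), float(reg.GetMetricValue())


def coregister(
    moving: ScalarMap, fixed: ScalarMap, metric: str = "correlation"
) -> RigidTransform:
    """Rigidly register ``moving`` to ``fixed`` (6 DOF, multi-resolution).

    Returns the fixed-to-moving world transform suitable for
    :func:`apply_transform` onto the fixed geometry.  Deterministic given
    identical inputs (dense metric sampling, fixed schedule).
    """
    if _fov_overlap_fraction(fixed.geometry, moving.geometry) < 0.10:
        raise RegistrationError(
            "fields of view overlap by less than 10%; refusing to register"
        )
    try:
        matrix, cost = _register(
            _as_sitk(fixed.data, fixed.geometry),
            _as_sitk(moving.data, moving.geometry),
            metric=metric,
        )
    except RuntimeError as exc:
        raise RegistrationError(f"optimizer failure: {exc}") from exc
    return RigidTransform(matrix, cost_value=cost)


def apply_transform(
    obj: Union[ScalarMap, BinaryMask],
    transform: RigidTransform,
    target_geometry: Geometry,
):
    """Resample a map or mask onto ``target_geometry`` through a transform.

    Scalar maps are interpolated trilinearly with NaN outside the source
    field of view; masks use nearest-neighbour with 0 outside.
    """
    # target voxel -> world -> (fixed-to-moving) -> source voxel
    vox = (
        np.linalg.inv(obj.geometry.affine)
        @ transform.matrix
        @ target_geometry.affine
    )
    if isinstance(obj, BinaryMask):
        out = ndimage.affine_transform(
            obj.data.astype(np.float32), vox[:3, :3], vox[:3, 3],
            output_shape=target_geometry.shape, order=0, cval=0.0,
            mode="constant",
        )
        return BinaryMask(out > 0.5, target_geometry, label=obj.label)
    out = ndimage.affine_transform(
        np.asarray(obj.data, dtype=float), vox[:3, :3], vox[:3, 3],
        output_shape=target_geometry.shape, order=1, cval=np.nan,
        mode="constant",
    )
    return ScalarMap(out, target_geometry, units=obj.units)


def _max_displacement_mm(tfm: RigidTransform, geometry: Geometry) -> float:
    """Upper bound on the displacement of any field-of-view point (mm)."""
    lo, hi = _physical_bounds(geometry)
    radius = 0.5 * float(np.linalg.norm(hi - lo))
    R = tfm.matrix[:3, :3]
    spectral = np.linalg.svd(R - np.eye(3), compute_uv=False)[0]
    return spectral * radius + float(np.linalg.norm(tfm.translation_mm))


def motion_correct(
    series: PerfusionSeries,
    metric: str = "correlation",
    identity_tol_mm: float | None = None,
) -> Tuple[PerfusionSeries, List[RigidTransform]]:
    """Register every volume of a DSC series to the temporal mean volume.

    Returns the corrected series (identical geometry, out-of-field voxels
    set to 0) and one rigid transform per volume.  Volumes whose estimated
    motion displaces no field-of-view point by more than ``identity_tol_mm``
    (default: a quarter of the smallest voxel edge, matching the rigid
    registration accuracy of this module) are copied unresampled with an
    identity transform: displacements below the registration precision are
    dominated by estimator noise and reference-contamination bias, and
    resampling them would only blur the time series.
    """
    geom = series.geometry
    if identity_tol_mm is None:
        identity_tol_mm = 0.25 * min(geom.voxel_size)
    mean_vol = series.data.mean(axis=3)
    fixed = _as_sitk(mean_vol, geom)
    corrected = np.empty_like(series.data)
    transforms: List[RigidTransform] = []
    for t in range(series.n_volumes):
        try:
            matrix, cost = _register(
                fixed, _as_sitk(series.data[..., t], geom), metric=metric,
                shrink=(1,), sigmas=(1.0,), iterations=100,
            )
        except RuntimeError as exc:
            raise RegistrationError(
                f"motion correction failed at volume {t}: {exc}"
            ) from exc
        tfm = RigidTransform(matrix, cost_value=cost)
        if _max_displacement_mm(tfm, geom) < identity_tol_mm:
            tfm = RigidTransform.identity()
            tfm.cost_value = cost
            corrected[..., t] = series.data[..., t]
        else:
            vox = np.linalg.inv(geom.affine) @ tfm.matrix @ geom.affine
            corrected[..., t] = ndimage.affine_transform(
                series.data[..., t], vox[:3, :3], vox[:3, 3],
                output_shape=geom.shape, order=1, cval=0.0, mode="constant",
            )
        transforms.append(tfm)
    corrected = np.clip(corrected, 0.0, None)
    return PerfusionSeries(corrected, geom, tr=series.tr), transforms
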