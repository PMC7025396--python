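"""Shared data model, geometry handling and NIfTI I/O.

All images in the pipeline share a :class:`Geometry` (shape, voxel sizes in
mm, voxel-to-world affine).  Volumes are reoriented to RAS voxel order on
load so that "left" and "right" are unambiguous: along the left-right axis,
voxel indices below the grid midpoint lie in the left hemisphere (+x points
right in RAS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple, Union

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, FormatError, HeaderError

__all__ = [
    "Geometry",
    "PerfusionSeries",
    "ScalarMap",
    "BinaryMask",
    "HemisphereSplit",
    "read_volume",
    "write_volume",
    "split_hemispheres",
]


@dataclass(frozen=True)
class Geometry:
    """Voxel grid of a 3D volume.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis (x, y, z), RAS order.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform in mm (RAS).
    left_right_axis : int
        Array axis whose midpoint defines the median plane.
    """

    shape: Tuple[int, int, int]
    voxel_size: Tuple[float, float, float]
    affine: np.ndarray = field(repr=False)
    left_right_axis: int = 0

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if len(self.shape) != 3:
            raise HeaderError(f"geometry must be 3D, got shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise HeaderError(f"non-positive voxel size {self.voxel_size}")
        if self.affine.shape != (4, 4):
            raise HeaderError("affine must be 4x4")
        if not 0 <= self.left_right_axis <= 2:
            raise HeaderError(f"invalid left_right_axis {self.left_right_axis}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def matches(self, other: "Geometry", atol: float = 1e-4) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_match(self, other: "Geometry", what: str = "volumes") -> None:
        if not self.matches(other):
            raise HeaderError(f"geometry mismatch between {what}")


def _check_3d(data: np.ndarray, geometry: Geometry) -> None:
    if data.shape[:3] != geometry.shape:
        raise HeaderError(
            f"array shape {data.shape[:3]} does not match geometry {geometry.shape}"
        )


@dataclass
class PerfusionSeries:
    """4D DSC time series S(v, t) in arbitrary signal units."""

    data: np.ndarray  # (x, y, z, t)
    geometry: Geometry
    tr: float  # seconds between volumes

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"perfusion series must be 4D, got {self.data.ndim}D")
        _check_3d(self.data, self.geometry)
        if self.data.shape[3] < 3:
            raise FormatError("perfusion series needs at least 3 volumes")
        if self.tr is None or self.tr <= 0:
            raise ConfigurationError("repetition time tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("perfusion series contains non-finite values")
        if np.any(self.data < 0):
            raise FormatError("perfusion series contains negative signal")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def volume(self, t: int) -> "ScalarMap":
        """Extract one time point as a scalar map."""
        return ScalarMap(self.data[..., t].copy(), self.geometry, units="a.u.")


@dataclass
class ScalarMap:
    """3D float map (sigma, mu, CV, ADC, TTP, TTP-delay...) on a geometry."""

    data: np.ndarray
    geometry: Geometry
    units: str = "a.u."

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"scalar map must be 3D, got {self.data.ndim}D")
        _check_3d(self.data, self.geometry)


@dataclass
class BinaryMask:
    """3D boolean map on a geometry."""

    data: np.ndarray
    geometry: Geometry
    label: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data) > 0
        if self.data.ndim != 3:
            raise FormatError(f"mask must be 3D, got {self.data.ndim}D")
        _check_3d(self.data, self.geometry)

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.geometry.voxel_volume

    def intersect(self, other: "BinaryMask", label: str = "") -> "BinaryMask":
        self.geometry.require_match(other.geometry, "masks")
        return BinaryMask(self.data & other.data, self.geometry, label or self.label)

    def subtract(self, other: "BinaryMask", label: str = "") -> "BinaryMask":
        self.geometry.require_match(other.geometry, "masks")
        return BinaryMask(self.data & ~other.data, self.geometry, label or self.label)


@dataclass
class HemisphereSplit:
    """A mask split at the median plane into affected/unaffected halves."""

    affected: BinaryMask
    unaffected: BinaryMask


def _tr_from_header(img) -> float:
    """TR in seconds from pixdim[4], honouring the header time unit."""
    zooms = img.header.get_zooms()
    if len(zooms) < 4:
        return 0.0
    tr = float(zooms[3])
    _, t_unit = img.header.get_xyzt_units()
    if t_unit == "msec":
        tr /= 1000.0
    elif t_unit == "usec":
        tr /= 1e6
    elif t_unit in ("unknown", "", None) and tr > 10:
        # clinical exports often store ms without declaring the unit
        tr /= 1000.0
    return tr


def read_volume(
    path: Union[str, Path],
    expected_dims: int,
    tr: float | None = None,
    left_right_axis: int = 0,
) -> Union[PerfusionSeries, ScalarMap]:
    """Read a NIfTI volume, reorienting to RAS.

    Parameters
    ----------
    path : str or Path
        NIfTI-1/2 file, optionally gzip-compressed.
    expected_dims : int
        3 for a scalar map, 4 for a perfusion series.
    tr : float, optional
        Repetition time in seconds; overrides/backs up pixdim[4] for 4D
        reads.  If both are present and disagree by more than 1% a warning
        is logged and the explicit value wins.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error paths
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != expected_dims:
        raise FormatError(
            f"{path}: expected {expected_dims}D image, got {data.ndim}D"
        )
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise HeaderError(f"{path}: non-positive voxel sizes {zooms}")
    geometry = Geometry(
        shape=data.shape[:3],
        voxel_size=zooms,
        affine=img.affine,
        left_right_axis=left_right_axis,
    )
    if expected_dims == 3:
        return ScalarMap(data.astype(float), geometry)
    header_tr = _tr_from_header(img)
    if tr is not None and header_tr > 0 and abs(header_tr - tr) > 0.01 * tr:
        warnings.warn(
            f"{path}: header TR {header_tr:.4g}s differs from configured "
            f"{tr:.4g}s; using configured value"
        )
    eff_tr = tr if tr is not None else (header_tr if header_tr > 0 else None)
    if eff_tr is None or eff_tr <= 0:
        raise ConfigurationError(
            f"{path}: TR not present in header; pass tr explicitly"
        )
    return PerfusionSeries(data.astype(float), geometry, tr=eff_tr)


def write_volume(
    obj: Union[ScalarMap, BinaryMask, PerfusionSeries], path: Union[str, Path]
) -> None:
    """Write a map, mask or series as NIfTI-1.

    Masks are stored as 8-bit 0/1 volumes for viewer interoperability;
    series carry TR in pixdim[4] with the time unit set to seconds.
    """
    path = Path(path)
    if isinstance(obj, BinaryMask):
        img = nib.Nifti1Image(obj.data.astype(np.uint8), obj.geometry.affine)
    elif isinstance(obj, PerfusionSeries):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.geometry.affine)
        img.header.set_zooms(tuple(obj.geometry.voxel_size) + (obj.tr,))
        img.header.set_xyzt_units(xyz="mm", t="sec")
    elif isinstance(obj, ScalarMap):
        img = nib.Nifti1Image(obj.data.astype(np.float32), obj.geometry.affine)
    else:
        raise TypeError(f"cannot write object of type {type(obj)}")
    if not isinstance(obj, PerfusionSeries):
        img.header.set_zooms(tuple(obj.geometry.voxel_size))
        img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))


def hemisphere_slices(n: int):
    """Index ranges of the two hemispheres along an axis of length n.

    For odd n the exact median-plane slice belongs to neither half.
    """
    low = slice(0, n // 2)
    high = slice((n + 1) // 2, n)
    return low, high


def split_hemispheres(mask: BinaryMask, affected_side: str) -> HemisphereSplit:
    """Split a mask at the grid midplane along the left-right axis.

    In RAS voxel order, indices below the midpoint are the left hemisphere.
    """
    side = str(affected_side).lower()
    if side not in ("left", "right"):
        raise ConfigurationError(f"unknown affected side {affected_side!r}")
    axis = mask.geometry.left_right_axis
    n = mask.geometry.shape[axis]
    low_sl, high_sl = hemisphere_slices(n)

    def half(sl):
        sel = np.zeros(mask.geometry.shape, dtype=bool)
        idx = [slice(None)] * 3
        idx[axis] = sl
        sel[tuple(idx)] = True
        return sel

    left = mask.data & half(low_sl)
    right = mask.data & half(high_sl)
    if side == "left":
        aff, unaff = left, right
    else:
        aff, unaff = right, left
    return HemisphereSplit(
        affected=BinaryMask(aff, mask.geometry, label=f"{mask.label}|affected"),
        unaffected=BinaryMask(unaff, mask.geometry, label=f"{mask.label}|unaffected"),
    )
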