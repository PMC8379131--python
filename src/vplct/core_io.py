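"""Volume / displacement-field / label-map I/O and grid geometry.

Conventions used throughout the package:

* Volumes are 3D arrays indexed (x, y, z) in RAS+ world orientation.
* World coordinates are ``origin + index * spacing`` (mm); axes are
  assumed axis-aligned after reorientation on load.
* Displacement fields live on the fixed (expiration) grid and store mm
  vectors mapping fixed points to moving (inspiration) points:
  ``phi(x) = x + u(x)``.
* HU data is clipped to the 12-bit CT range [-1024, 3071] on load.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DataError, GeometryError, InputError, ShapeError, UsageError

HU_MIN = -1024.0
HU_MAX = 3071.0


class Unit(str, enum.Enum):
    """Physical unit tag carried by a ScalarVolume."""

    HU = "HU"
    IODINE_HU = "iodine_HU"
    FRACTION = "fraction"
    PERCENT = "percent"
    DIMENSIONLESS = "dimensionless"


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing (mm/voxel) and origin (mm) of a regular 3D grid."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 2 for n in self.shape):
            raise ShapeError(f"grid shape must be 3 axes each >= 2, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return float(sx * sy * sz)

    def world_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid of world (mm) coordinates of all voxel centers."""
        axes = [
            self.origin[i] + np.arange(self.shape[i]) * self.spacing[i]
            for i in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))  # type: ignore[return-value]

    def matches(self, other: "GridGeometry", tol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _validate_geometry(spacing, origin) -> tuple[tuple, tuple]:
    spacing = tuple(float(s) for s in spacing)
    origin = tuple(float(o) for o in origin)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise GeometryError(f"spacing must be 3 positive floats, got {spacing}")
    if len(origin) != 3:
        raise GeometryError(f"origin must have 3 components, got {origin}")
    return spacing, origin


@dataclass
class ScalarVolume:
    """A 3D scalar grid with physical geometry and a unit tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: Unit = Unit.DIMENSIONLESS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"volume must be 3D, got {self.data.ndim} axes")
        if any(n < 2 for n in self.data.shape):
            raise ShapeError(f"each axis must have >= 2 voxels, got {self.data.shape}")
        self.spacing, self.origin = _validate_geometry(self.spacing, self.origin)
        self.unit = Unit(self.unit)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(tuple(self.data.shape), self.spacing, self.origin)

    def with_data(self, data: np.ndarray, unit: Unit | None = None) -> "ScalarVolume":
        """Same grid, new voxel values."""
        return ScalarVolume(data, self.spacing, self.origin, unit or self.unit)


@dataclass
class DisplacementField:
    """Per-voxel mm vectors on the fixed grid; phi(x) = x + u(x)."""

    vectors: np.ndarray  # shape (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ShapeError(
                f"field must be (nx, ny, nz, 3), got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise DataError("displacement field contains non-finite vectors")
        self.spacing, self.origin = _validate_geometry(self.spacing, self.origin)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(tuple(self.vectors.shape[:3]), self.spacing, self.origin)


@dataclass
class VesselROI:
    """Integer label map: 0 background, 1 pulmonary-artery trunk, 2 ascending aorta."""

    label_map: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    LABEL_PA_TRUNK = 1
    LABEL_AORTA = 2

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        if self.label_map.ndim != 3:
            raise ShapeError("ROI label map must be 3D")
        if not np.issubdtype(self.label_map.dtype, np.integer):
            raise DataError("ROI label map must have an integer dtype")
        self.spacing, self.origin = _validate_geometry(self.spacing, self.origin)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(tuple(self.label_map.shape), self.spacing, self.origin)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _load_canonical(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error breadth
        raise InputError(f"cannot read NIfTI file {path}: {exc}") from exc
    return nib.as_closest_canonical(img)


def _geometry_from(img: nib.Nifti1Image):
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return spacing, origin


def read_volume(path, unit: Unit = Unit.HU) -> ScalarVolume:
    """Read a 3D NIfTI scalar volume, reoriented to RAS+.

    HU volumes are clipped to [-1024, 3071] on load.
    """
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[-1] == 1 else data
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D image, got {data.ndim} axes")
    data = np.asarray(data, dtype=np.float32)
    unit = Unit(unit)
    if unit in (Unit.HU, Unit.IODINE_HU) and not np.all(np.isfinite(data)):
        # CT input data must be finite; derived maps may carry NaN masks
        raise DataError(f"{path}: volume contains non-finite voxels")
    if unit == Unit.HU:
        data = np.clip(data, HU_MIN, HU_MAX)
    spacing, origin = _geometry_from(img)
    return ScalarVolume(data, spacing, origin, unit)


def write_volume(vol: ScalarVolume, path) -> None:
    """Write a ScalarVolume as NIfTI-1 (float32)."""
    img = nib.Nifti1Image(
        np.asarray(vol.data, dtype=np.float32), _affine(vol.spacing, vol.origin)
    )
    nib.save(img, str(path))


def read_field(path) -> DisplacementField:
    """Read a displacement field stored as a 4D (x, y, z, 3) NIfTI in mm."""
    img = _load_canonical(path)
    data = np.asarray(np.asanyarray(img.dataobj), dtype=np.float64)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention (t=1)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ShapeError(f"{path}: expected a 3-component vector image")
    spacing, origin = _geometry_from(img)
    return DisplacementField(data, spacing, origin)


def write_field(fld: DisplacementField, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(fld.vectors, dtype=np.float32), _affine(fld.spacing, fld.origin)
    )
    nib.save(img, str(path))


def read_labels(path) -> ScalarVolume:
    """Read an integer label map; dtype is preserved as integer."""
    img = _load_canonical(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D label map")
    data = np.rint(np.asarray(data)).astype(np.int16)
    spacing, origin = _geometry_from(img)
    return ScalarVolume(data, spacing, origin, Unit.DIMENSIONLESS)


def write_labels(labels: np.ndarray, spacing, origin, path) -> None:
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise DataError("label map must be integer-typed")
    img = nib.Nifti1Image(labels.astype(np.int16), _affine(spacing, origin))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling


def resample_to_grid(
    vol: ScalarVolume,
    target: GridGeometry,
    interpolation: str = "linear",
) -> ScalarVolume:
    """Resample a volume onto a target grid geometry.

    ``linear`` for scalar data, ``nearest`` for label maps. Out-of-support
    voxels are filled with -1024 for HU data and 0 otherwise.
    """
    if interpolation not in ("linear", "nearest"):
        raise UsageError(f"unknown interpolation {interpolation!r}")
    if np.issubdtype(vol.data.dtype, np.integer) and interpolation == "linear":
        raise UsageError("label maps must be resampled with nearest interpolation")
    fill = HU_MIN if vol.unit == Unit.HU else 0.0
    # index coordinates of target voxel centers in the source grid
    idx = [
        (target.origin[i] + np.arange(target.shape[i]) * target.spacing[i] - vol.origin[i])
        / vol.spacing[i]
        for i in range(3)
    ]
    grid = np.meshgrid(*idx, indexing="ij")
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float64),
        np.stack(grid),
        order=order,
        mode="constant",
        cval=fill,
    )
    if np.issubdtype(vol.data.dtype, np.integer):
        out = np.rint(out).astype(vol.data.dtype)
    return ScalarVolume(out, target.spacing, target.origin, vol.unit)
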