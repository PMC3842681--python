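"""Grid-based volume types and NIfTI/MetaImage I/O.

All objects live on an axis-aligned right-handed grid: array index
``(i, j, k)`` maps to the world position ``origin + index * spacing``
(millimetres).  Arrays follow the SimpleITK numpy convention, so array
axis 0 is the slowest-varying (z) file axis; spacing and origin tuples
are stored in the same array-axis order.  Oblique direction cosines are
rejected at read time rather than silently re-gridded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, GridMismatchError

__all__ = [
    "GridGeometry",
    "ImageVolume",
    "BinaryMask",
    "AtlasProposal",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "assert_common_grid",
]

#: Tolerance (mm) within which spacings/origins are considered equal.
GRID_TOL_MM = 1e-4

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")


@dataclass(frozen=True)
class GridGeometry:
    """Shape, spacing and origin of an axis-aligned 3D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each array axis; every component >= 1.
    spacing
        Voxel edge length in mm along each array axis; strictly positive.
    origin
        World position (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("GridGeometry requires 3 components per field")
        if any(s < 1 for s in self.shape):
            raise ValueError(f"shape components must be >= 1, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def diagonal_mm(self) -> float:
        """Physical length of the grid diagonal (voxel-center to voxel-center)."""
        return math.sqrt(sum(((n - 1) * s) ** 2 for n, s in zip(self.shape, self.spacing)))

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers, as an open meshgrid."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def approx_equal(self, other: "GridGeometry", tol_mm: float = GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol_mm for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol_mm for a, b in zip(self.origin, other.origin))
        )


@dataclass
class ImageVolume:
    """A 3D scalar intensity volume on a :class:`GridGeometry`."""

    geometry: GridGeometry
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.shape != self.geometry.shape:
            raise ValueError(
                f"intensity shape {self.intensities.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass
class BinaryMask:
    """A boolean membership volume on a :class:`GridGeometry`."""

    geometry: GridGeometry
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.shape != self.geometry.shape:
            raise ValueError(
                f"membership shape {self.membership.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.membership.sum())

    def is_empty(self) -> bool:
        return not bool(self.membership.any())

    def is_full(self) -> bool:
        return bool(self.membership.all())


@dataclass
class AtlasProposal:
    """One atlas's deformed image and deformed structure mask on the target grid."""

    atlas_id: str
    image: ImageVolume
    mask: BinaryMask

    def __post_init__(self) -> None:
        if not self.image.geometry.approx_equal(self.mask.geometry):
            raise GridMismatchError(
                f"proposal {self.atlas_id!r}: image and mask geometries differ"
            )
        if self.mask.is_empty():
            warnings.warn(
                f"proposal {self.atlas_id!r} has an empty mask; fusion will reject it",
                stacklevel=2,
            )


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise FormatError(
            f"{path}: unsupported format (expected one of {', '.join(_SUPPORTED_SUFFIXES)})"
        )


def _read_sitk(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # ITK wraps all reader failures in RuntimeError
        raise FormatError(f"{path}: unreadable ({exc})") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected 3D data, got {img.GetDimension()}D")
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError(
            f"{path}: expected 3D scalar data, got "
            f"{img.GetNumberOfComponentsPerPixel()} components per voxel"
        )
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError(
            f"{path}: oblique/non-identity direction cosines are not supported"
        )
    arr = sitk.GetArrayFromImage(img)  # numpy axes (z, y, x)
    geom = GridGeometry(
        shape=arr.shape,
        spacing=tuple(img.GetSpacing()[::-1]),
        origin=tuple(img.GetOrigin()[::-1]),
    )
    return arr, geom


def _write_sitk(arr: np.ndarray, geom: GridGeometry, path: str | Path) -> None:
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise IOError(f"{path.parent}: parent directory does not exist")
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(geom.spacing[::-1]))
    img.SetOrigin(tuple(geom.origin[::-1]))
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise IOError(f"{path}: cannot write ({exc})") from exc


def read_image(path: str | Path) -> ImageVolume:
    """Read a 3D scalar image (NIfTI or MetaImage); spacing/origin in mm."""
    arr, geom = _read_sitk(path)
    return ImageVolume(geom, arr.astype(np.float32))


def write_image(vol: ImageVolume, path: str | Path) -> None:
    """Write an image as float32 NIfTI/MetaImage (format chosen by suffix)."""
    _write_sitk(vol.intensities.astype(np.float32), vol.geometry, path)


def read_mask(path: str | Path, label: int | None = None) -> BinaryMask:
    """Read a label volume as a binary mask.

    Nonzero voxels become members.  If more than one nonzero label value is
    present, ``label`` must select one; otherwise a :class:`FormatError` is
    raised so that multi-structure files are never silently merged.
    """
    arr, geom = _read_sitk(path)
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded, atol=1e-6):
        raise FormatError(f"{path}: mask file contains non-integer values")
    labels = np.unique(rounded[rounded != 0])
    if label is not None:
        return BinaryMask(geom, rounded == label)
    if len(labels) > 1:
        raise FormatError(
            f"{path}: multiple labels {sorted(int(v) for v in labels)} present; "
            "pass a label selector to choose one"
        )
    return BinaryMask(geom, rounded != 0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an unsigned 8-bit volume (0 = background, 1 = member)."""
    _write_sitk(mask.membership.astype(np.uint8), mask.geometry, path)


def _geometry_of(item) -> GridGeometry:
    if isinstance(item, GridGeometry):
        return item
    return item.geometry


def assert_common_grid(items: Sequence, tol_mm: float = GRID_TOL_MM) -> None:
    """Raise :class:`GridMismatchError` unless all items share one grid.

    ``items`` may be geometries or any objects with a ``.geometry`` attribute;
    the error names the first offending item (by position and, when available,
    ``atlas_id``).
    """
    items = list(items)
    if not items:
        raise ValueError("assert_common_grid requires a non-empty list")
    ref = _geometry_of(items[0])
    for pos, item in enumerate(items[1:], start=1):
        geom = _geometry_of(item)
        if not ref.approx_equal(geom, tol_mm):
            ident = getattr(item, "atlas_id", None)
            label = f"item {pos}" + (f" ({ident!r})" if ident else "")
            raise GridMismatchError(
                f"{label} is on a different grid: {geom} vs reference {ref}"
            )
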