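"""Core 3-D image data model and NIfTI I/O shared by all pipeline stages.

An :class:`ImageVolume` is a scalar field (SUV, CT-like arbitrary units, or
dose in Gy) sampled on a regular, possibly anisotropic grid.  Array axes
follow a fixed anatomical convention:

* axis 0 — left-right (lateral, *x*)
* axis 1 — anterior-posterior (*y*)
* axis 2 — craniocaudal (superior-inferior, *z*)

Physical coordinates are millimetres; the world position of voxel
``(i, j, k)`` is ``origin + (i*dx, j*dy, k*dz)``.  Volumes are stored as
NIfTI-1 with a diagonal (RAS) affine; PET-like and CT-like volumes of one
phantom case share a single grid, so no registration step exists anywhere
in the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "Structure",
    "read_volume",
    "write_volume",
    "structure_to_volume",
    "volume_to_structure",
    "activity_to_suv",
    "assert_congruent",
]


@dataclass
class ImageVolume:
    """A 3-D scalar grid with anisotropic spacing and a world origin."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("grid must have at least one voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be three positive numbers, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def center(self) -> tuple[float, float, float]:
        """Physical centre of the grid (mm), generally between voxel centres."""
        return tuple(
            self.origin[a] + (self.shape[a] - 1) / 2.0 * self.spacing[a] for a in range(3)
        )

    def physical_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Map physical points (..., 3) to continuous index coordinates."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def contains_point(self, point_mm) -> bool:
        idx = self.physical_to_index(np.asarray(point_mm, dtype=float))
        return bool(np.all(idx >= 0) and np.all(idx <= np.asarray(self.shape) - 1))


@dataclass
class Structure:
    """A named binary mask congruent with a reference :class:`ImageVolume` grid."""

    label: str
    mask: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("structure mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")

    @classmethod
    def on_grid(cls, label: str, mask: np.ndarray, grid: ImageVolume) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError("mask shape does not match reference grid")
        return cls(label, mask, grid.spacing, grid.origin)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    @property
    def volume_cm3(self) -> float:
        """Volume in cm³: voxel count × voxel volume / 1000."""
        return float(np.count_nonzero(self.mask)) * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.mask.any())


def _grid_key(obj) -> tuple:
    return (tuple(obj.mask.shape if isinstance(obj, Structure) else obj.data.shape),
            obj.spacing, obj.origin)


def assert_congruent(a, b) -> None:
    """Raise if two volumes/structures do not share one grid."""
    sa, sb = _grid_key(a), _grid_key(b)
    if sa[0] != sb[0]:
        raise ValueError(f"grid shapes differ: {sa[0]} vs {sb[0]}")
    if not (np.allclose(sa[1], sb[1]) and np.allclose(sa[2], sb[2])):
        raise ValueError("grid spacing/origin differ")


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1 with a diagonal RAS affine."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.data), affine)
    nib.save(img, str(path))


def read_volume(path) -> ImageVolume:
    """Read a 3-D NIfTI volume; spacing/origin taken from the header."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing in header: {spacing}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(data, spacing, origin)


def structure_to_volume(s: Structure) -> ImageVolume:
    """Encode a mask as a 0/1 uint8 volume for NIfTI export."""
    return ImageVolume(s.mask.astype(np.uint8), s.spacing, s.origin)


def volume_to_structure(vol: ImageVolume, label: str) -> Structure:
    return Structure(label, np.asarray(vol.data) > 0.5, vol.spacing, vol.origin)


def activity_to_suv(activity: ImageVolume, injected_dose_mbq: float,
                    body_weight_kg: float) -> ImageVolume:
    """Convert an activity-concentration volume (kBq/mL) to SUV.

    Standard body-weight normalisation assuming tissue density 1 g/mL:
    ``SUV(x) = activity(x) / (injected_dose * 1000 / body_weight)``, i.e.
    activity divided by injected activity per gram of body mass.
    """
    if injected_dose_mbq <= 0:
        raise ValueError("injected dose must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    denom = injected_dose_mbq * 1000.0 / body_weight_kg
    return ImageVolume(np.asarray(activity.data, dtype=float) / denom,
                       activity.spacing, activity.origin)
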