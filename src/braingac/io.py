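"""Reading, writing and slicing MR head volumes and binary masks.

Volumes are stored as plain numpy grids together with voxel spacing and an
affine; anatomical orientation labels are derived from the affine with
nibabel, so slice iteration can be requested as ``axial``, ``coronal`` or
``sagittal`` regardless of how the array axes happen to be laid out on disk.
Supported formats are NIfTI-1 (``.nii``/``.nii.gz``) and Analyze 7.5
(``.hdr``/``.img``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence, Tuple

import nibabel as nib
import numpy as np

from .errors import VolumeFormatError

ORIENTATIONS = ("axial", "coronal", "sagittal")

# Axis codes perpendicular to each anatomical slice plane (RAS-style labels).
_PLANE_CODES = {
    "axial": ("S", "I"),
    "coronal": ("A", "P"),
    "sagittal": ("R", "L"),
}


def _validate_3d(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data)
    if data.ndim > 3 and all(s == 1 for s in data.shape[3:]):
        data = data.reshape(data.shape[:3])
    if data.ndim != 3:
        raise VolumeFormatError(
            f"expected a 3-D image, got {data.ndim} dimensions {data.shape}"
        )
    if any(s < 1 for s in data.shape):
        raise VolumeFormatError(f"degenerate volume shape {data.shape}")
    return data


@dataclass
class Volume:
    """A 3-D scalar intensity grid with voxel spacing and orientation.

    Parameters
    ----------
    data:
        3-D array of intensities (any scalar dtype; never mutated by the
        package — computations run on float copies).
    spacing:
        Per-axis voxel size in mm, strictly positive.
    affine:
        4x4 voxel-to-world matrix; identity (RAS) if unknown.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = _validate_3d(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def orientation(self) -> Tuple[str, str, str]:
        """Axis-label triple (nibabel axcodes) identifying the grid axes."""
        return nib.orientations.aff2axcodes(self.affine)

    def axis_for(self, orientation: str) -> int:
        """Array axis perpendicular to the named anatomical slice plane."""
        if orientation not in ORIENTATIONS:
            raise ValueError(
                f"unknown orientation {orientation!r}; expected one of {ORIENTATIONS}"
            )
        codes = _PLANE_CODES[orientation]
        for axis, code in enumerate(self.orientation):
            if code in codes:
                return axis
        raise ValueError(
            f"orientation labels {self.orientation} do not identify a {orientation} axis"
        )

    def as_float(self) -> np.ndarray:
        """Float64 copy of the intensity grid (original data left untouched)."""
        return np.asarray(self.data, dtype=np.float64).copy()


@dataclass
class BinaryMask:
    """A boolean grid aligned to a parent :class:`Volume`."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = _validate_3d(self.data)
        self.data = data.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.data.sum())


def _load(path: str) -> nib.spatialimages.SpatialImage:
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    try:
        return nib.load(path)
    except Exception as exc:  # nibabel raises several format-specific types
        raise VolumeFormatError(f"cannot read {path!r} as NIfTI/Analyze: {exc}") from exc


def read_volume(path: str) -> Volume:
    """Read a NIfTI-1 or Analyze 7.5 image as a :class:`Volume`.

    Integer intensities are preserved bit-exactly (no scaling is applied when
    the header declares none).
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    affine = img.affine if img.affine is not None else np.eye(4)
    return Volume(data=_validate_3d(data), spacing=tuple(zooms), affine=affine)


def read_mask(path: str) -> BinaryMask:
    """Read a mask image; any nonzero voxel counts as in."""
    vol = read_volume(path)
    return BinaryMask(data=vol.data != 0, spacing=vol.spacing, affine=vol.affine)


def _image_for_path(data: np.ndarray, affine: np.ndarray, spacing, path: str):
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(data, affine)
    elif lower.endswith((".hdr", ".img")):
        img = nib.AnalyzeImage(data, affine)
    else:
        raise VolumeFormatError(
            f"unsupported output extension for {path!r}; use .nii/.nii.gz/.hdr/.img"
        )
    img.header.set_zooms(tuple(spacing)[: len(img.header.get_zooms())])
    return img


def write_volume(vol: Volume, path: str) -> None:
    """Write a volume; format chosen from the file extension."""
    img = _image_for_path(np.asarray(vol.data), vol.affine, vol.spacing, path)
    nib.save(img, path)


def write_mask(mask: BinaryMask, path: str) -> None:
    """Write a mask as 8-bit unsigned, in=1, out=0."""
    img = _image_for_path(
        mask.data.astype(np.uint8), mask.affine, mask.spacing, path
    )
    nib.save(img, path)


def iter_slices(vol: Volume, orientation: str) -> Iterator[Tuple[int, np.ndarray]]:
    """Yield ``(index, slice)`` pairs perpendicular to the named plane.

    Indices are 0-based and ascending; slices are views into the volume.
    """
    axis = vol.axis_for(orientation)
    moved = np.moveaxis(vol.data, axis, 0)
    for idx in range(moved.shape[0]):
        yield idx, moved[idx]


def stack_slices(slices: Sequence[np.ndarray], vol: Volume, orientation: str) -> np.ndarray:
    """Inverse of :func:`iter_slices`: restack slices into a volume-shaped grid."""
    axis = vol.axis_for(orientation)
    stacked = np.stack(list(slices), axis=0)
    return np.moveaxis(stacked, 0, axis)
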