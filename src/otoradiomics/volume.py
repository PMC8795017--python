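"""In-memory containers for 3D MR volumes and segmentation masks.

Arrays are indexed ``(x, y, z)`` with per-axis voxel spacing in millimetres.
NIfTI i/o goes through nibabel; the affine is diagonal (axis-aligned grids),
which is all the synthetic cohorts and the preprocessing chain require.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "SegMask", "load_volume", "load_mask"]


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities (arbitrary units).
    spacing : tuple of float
        Voxel edge length per axis, mm. Must be positive.
    origin : tuple of float
        World coordinate of voxel (0, 0, 0), mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine())
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


@dataclass
class SegMask:
    """Binary region-of-interest grid aligned to an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={arr.ndim}")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError(f"mask values must be 0/1, found {uniq[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine())
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


def _load(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, zooms, origin


def load_volume(path) -> ImageVolume:
    """Read a NIfTI image into an :class:`ImageVolume`."""
    data, spacing, origin = _load(path)
    return ImageVolume(data=np.asarray(data, dtype=np.float64), spacing=spacing, origin=origin)


def load_mask(path) -> SegMask:
    """Read a NIfTI binary mask into a :class:`SegMask`."""
    data, spacing, origin = _load(path)
    return SegMask(data=(np.asarray(data) > 0.5).astype(np.uint8), spacing=spacing, origin=origin)
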