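"""Volumetric containers for CT sub-volumes and nodule masks.

Axis order is fixed as ``(z, y, x)`` throughout the package; voxel
spacing and world origin are stored in millimetres in the same order.
World coordinates follow ``world = origin + index * spacing`` with
0-based indices.  NIfTI files are read and written through nibabel,
transposing between the on-disk ``(x, y, z)`` layout and the in-memory
``(z, y, x)`` layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "NoduleMask", "load_nifti", "load_nifti_mask"]


def _as_triplet(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.size != 3:
        raise ValueError(f"expected 3 components, got {a.size}")
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass
class VoxelGrid:
    """A 3D block of CT attenuation values in Hounsfield units.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        HU values; must be finite.
    spacing : (sz, sy, sx)
        Voxel size in mm per axis; all positive.
    origin : (oz, oy, ox)
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array (z, y, x)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")
        self.spacing = _as_triplet(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        self.origin = _as_triplet(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, index) -> np.ndarray:
        """Map (fractional) (z, y, x) indices to world mm."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        w = np.asarray(world, dtype=float)
        return (w - np.asarray(self.origin)) / np.asarray(self.spacing)

    def save_nifti(self, path) -> None:
        save_nifti(self, path)


@dataclass
class NoduleMask:
    """Binary lesion mask aligned voxel-for-voxel with a :class:`VoxelGrid`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be a 3D array (z, y, x)")
        self.spacing = _as_triplet(self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive on all axes")
        self.origin = _as_triplet(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def num_foreground(self) -> int:
        return int(self.values.sum())

    def centroid_world(self) -> np.ndarray:
        """World-mm centroid of the foreground voxels."""
        if self.num_foreground == 0:
            raise ValueError("mask has no foreground voxels")
        idx = np.argwhere(self.values).mean(axis=0)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def save_nifti(self, path) -> None:
        grid = VoxelGrid(self.values.astype(np.float64), self.spacing, self.origin)
        save_nifti(grid, path)


def _affine(spacing, origin) -> np.ndarray:
    # on-disk axis order is (x, y, z)
    sz, sy, sx = spacing
    oz, oy, ox = origin
    aff = np.diag([sx, sy, sz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def save_nifti(grid: VoxelGrid, path) -> None:
    data = np.transpose(grid.values, (2, 1, 0))
    img = nib.Nifti1Image(data.astype(np.float32), _affine(grid.spacing, grid.origin))
    nib.save(img, str(path))


def load_nifti(path) -> VoxelGrid:
    """Load a volume, returning values in (z, y, x) order with mm spacing."""
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(np.float64)
    aff = img.affine
    spacing = (abs(aff[2, 2]), abs(aff[1, 1]), abs(aff[0, 0]))
    origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
    return VoxelGrid(data, spacing, origin)


def load_nifti_mask(path) -> NoduleMask:
    grid = load_nifti(path)
    return NoduleMask(grid.values > 0.5, grid.spacing, grid.origin)
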