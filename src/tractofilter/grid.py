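"""Voxel grids and gray-matter parcellations.

World coordinates are in millimetres. Voxel indices are 0-based and a world
point ``p`` belongs to voxel ``floor((p - origin) / voxel_size)`` — voxel
boxes are half-open, so a point exactly on a shared face belongs to the
higher-index voxel. ``origin`` is the world position of the *corner* of
voxel (0, 0, 0), not its centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib


@dataclass(frozen=True)
class VoxelGrid:
    """A regular axis-aligned voxel grid.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along x, y, z (all >= 1).
    voxel_size : tuple of float
        Edge length of a voxel along each axis, in mm (all > 0).
    origin : tuple of float
        World-mm coordinate of the corner of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"grid dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive floats, got {self.voxel_size}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size", tuple(float(s) for s in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.voxel_size
        return sx * sy * sz

    @property
    def extent(self) -> np.ndarray:
        """World-mm size of the grid box along each axis."""
        return np.asarray(self.dims, float) * np.asarray(self.voxel_size, float)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine mapping indices to voxel *centres*."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = np.asarray(self.origin) + 0.5 * np.asarray(self.voxel_size)
        return aff

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (..., 3) to integer voxel indices (floor rule)."""
        q = (np.asarray(points, float) - np.asarray(self.origin)) / np.asarray(self.voxel_size)
        return np.floor(q).astype(np.int64)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, float)
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.voxel_size)

    def contains(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices)
        return np.all((idx >= 0) & (idx < np.asarray(self.dims)), axis=-1)

    def ravel(self, indices: np.ndarray) -> np.ndarray:
        """Linear voxel index in x-fastest raster order."""
        idx = np.asarray(indices, np.int64)
        nx, ny, _ = self.dims
        return idx[..., 0] + nx * (idx[..., 1] + ny * idx[..., 2])

    def unravel(self, linear: np.ndarray) -> np.ndarray:
        lin = np.asarray(linear, np.int64)
        nx, ny, _ = self.dims
        i = lin % nx
        j = (lin // nx) % ny
        k = lin // (nx * ny)
        return np.stack([i, j, k], axis=-1)

    @classmethod
    def from_affine(cls, dims, affine) -> "VoxelGrid":
        """Build a grid from an axis-aligned NIfTI affine (no rotation/shear)."""
        aff = np.asarray(affine, float)
        lin = aff[:3, :3]
        if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-8):
            raise ValueError("only axis-aligned (diagonal) affines are supported; resample upstream")
        voxel_size = np.diag(lin)
        if np.any(voxel_size <= 0):
            raise ValueError("negative or zero voxel sizes in affine; flip axes upstream")
        origin = aff[:3, 3] - 0.5 * voxel_size
        return cls(tuple(int(d) for d in dims), tuple(voxel_size), tuple(origin))


@dataclass(frozen=True)
class Parcellation:
    """Integer-labelled volume: 0 = background/white matter, 1..R = GM ROIs."""

    grid: VoxelGrid
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.shape != tuple(self.grid.dims):
            raise ValueError(f"label volume shape {lab.shape} != grid dims {self.grid.dims}")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("parcellation labels must be integers")
        if lab.min() < 0:
            raise ValueError("parcellation labels must be non-negative")
        object.__setattr__(self, "labels", lab)

    @property
    def roi_labels(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v != 0]

    def label_at(self, point: np.ndarray) -> int:
        """Label of the voxel containing a world point (0 if outside grid)."""
        idx = self.grid.world_to_voxel(point)
        if not self.grid.contains(idx):
            return 0
        return int(self.labels[tuple(idx)])

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.labels.astype(np.int32), self.grid.affine)

    @classmethod
    def from_nifti(cls, img_or_path) -> "Parcellation":
        img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) else nib.load(str(img_or_path))
        grid = VoxelGrid.from_affine(img.shape[:3], img.affine)
        data = np.asanyarray(img.dataobj)
        return cls(grid, np.rint(data).astype(np.int64))


def fraction_map_to_nifti(grid: VoxelGrid, fraction_map: np.ndarray) -> nib.Nifti1Image:
    arr = np.asarray(fraction_map, np.float64).reshape(grid.dims)
    return nib.Nifti1Image(arr.astype(np.float32), grid.affine)


def fraction_map_from_nifti(img_or_path) -> tuple[VoxelGrid, np.ndarray]:
    img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) else nib.load(str(img_or_path))
    grid = VoxelGrid.from_affine(img.shape[:3], img.affine)
    return grid, np.asanyarray(img.dataobj).astype(np.float64)
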