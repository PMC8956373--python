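"""HU volume container and I/O with exact voxel/world coordinate mapping.

The world frame is LPS millimetres (the native CT frame). Voxel indices are
0-based, continuous, and refer to voxel *centers*:

    world = origin + direction @ (spacing * index)

Data is stored index-ordered ``data[i, j, k]`` so that axis ``n`` of the array
corresponds to column ``n`` of the direction matrix. SimpleITK handles the
on-disk formats (NIfTI, NRRD) and their metadata conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates


class VolumeFormatError(ValueError):
    """Raised for unreadable or non-scalar volume files."""


@dataclass
class Volume:
    """A scalar HU grid with world-coordinate metadata.

    Attributes
    ----------
    data : (nx, ny, nz) array of HU values, index order matching direction columns.
    spacing : per-axis voxel size in mm, strictly positive.
    origin : world position (mm) of the center of voxel (0, 0, 0).
    direction : 3x3 orthonormal matrix; column n is the world direction of axis n.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"expected 3-D scalar grid, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive on all axes")
        if not np.isclose(abs(np.linalg.det(self.direction)), 1.0, atol=1e-9):
            raise ValueError("direction must be orthonormal (|det| = 1)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map continuous voxel indices (may lie outside the grid) to world mm."""
        idx = np.asarray(index, dtype=float)
        return (idx * self.spacing) @ self.direction.T + self.origin

    def world_to_voxel(self, point: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_world`."""
        p = np.asarray(point, dtype=float)
        return ((p - self.origin) @ self.direction) / self.spacing

    def world_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of all voxel centers."""
        n = np.array(self.shape)
        corners = np.array([[i, j, k] for i in (0, n[0] - 1) for j in (0, n[1] - 1) for k in (0, n[2] - 1)])
        w = self.voxel_to_world(corners)
        return w.min(axis=0), w.max(axis=0)


def voxel_to_world(v: Volume, index: np.ndarray) -> np.ndarray:
    return v.voxel_to_world(index)


def world_to_voxel(v: Volume, point: np.ndarray) -> np.ndarray:
    return v.world_to_voxel(point)


def voxel_center_grid(v: Volume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates of every voxel center as three (nx, ny, nz) arrays."""
    idx = np.indices(v.shape, dtype=float)
    flat = idx.reshape(3, -1).T
    w = v.voxel_to_world(flat)
    return tuple(w[:, a].reshape(v.shape) for a in range(3))  # type: ignore[return-value]


def read_volume(path: str | Path) -> Volume:
    """Read a scalar NIfTI or NRRD volume, honoring spacing/origin/direction."""
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # SimpleITK wraps all reader failures
        raise VolumeFormatError(f"unreadable volume {path}: {exc}") from exc
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise VolumeFormatError("volume must have scalar voxels")
    if img.GetDimension() != 3:
        raise VolumeFormatError(f"expected 3-D volume, got {img.GetDimension()}-D")
    # sitk arrays are [k, j, i]; transpose into index order [i, j, k]
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    direction = np.array(img.GetDirection(), dtype=float).reshape(3, 3)
    return Volume(
        data=data,
        spacing=np.array(img.GetSpacing()),
        origin=np.array(img.GetOrigin()),
        direction=direction,
    )


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or NRRD (.nrrd)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(v.spacing))
    img.SetOrigin(tuple(v.origin))
    img.SetDirection(tuple(v.direction.ravel()))
    sitk.WriteImage(img, str(path))


def downsample_half(v: Volume) -> Volume:
    """Halve the grid resolution by per-axis linear interpolation.

    New voxel ``j`` on each axis is sampled at old continuous index
    ``2 j + 0.5`` (the center of the pair of old cells it covers), so the
    world extent is preserved within one voxel. Spacing doubles; the origin
    moves to the old half-voxel position.
    """
    old_shape = np.array(v.shape)
    if np.any(old_shape < 2):
        raise ValueError("each axis needs at least 2 voxels to downsample")
    new_shape = old_shape // 2
    axes = [2.0 * np.arange(n) + 0.5 for n in new_shape]
    coords = np.meshgrid(*axes, indexing="ij")
    sampled = map_coordinates(v.data.astype(float), np.stack(coords), order=1, mode="nearest")
    return Volume(
        data=sampled,
        spacing=v.spacing * 2.0,
        origin=v.voxel_to_world(np.array([0.5, 0.5, 0.5])),
        direction=v.direction.copy(),
    )
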