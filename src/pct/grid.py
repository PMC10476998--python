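"""Voxel lattice and RSP volume containers.

The reconstruction unknown is a 3-D map of relative stopping power (RSP,
dimensionless) sampled on a regular isotropic voxel lattice.  Coordinates are
millimetres in the fixed object frame; the vertical axis is ``y`` (the object
rotates about it during a scan) and protons travel nominally along ``+z`` in
the gantry frame.

Voxel ``(i, j, k)`` (0-based, axes x, y, z) occupies the half-open box
``[origin + i*h, origin + (i+1)*h)`` per axis, where ``h`` is the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "RSPVolume"]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular isotropic voxel lattice.

    Parameters
    ----------
    shape
        Voxel counts ``(n_x, n_y, n_z)``.
    voxel_size
        Isotropic voxel edge length in mm.
    origin
        Object-frame coordinates (mm) of the low corner of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"voxel counts must be >= 1, got {self.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "voxel_size", float(self.voxel_size))

    @classmethod
    def centered(cls, shape: tuple[int, int, int], voxel_size: float = 1.0) -> "VoxelGrid":
        """Grid whose geometric center is the object-frame origin (isocenter)."""
        origin = tuple(-n * voxel_size / 2.0 for n in shape)
        return cls(shape=shape, voxel_size=voxel_size, origin=origin)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(low corner, high corner) of the lattice bounding box, mm."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + np.asarray(self.shape, dtype=float) * self.voxel_size
        return lo, hi

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (0=x, 1=y, 2=z), mm."""
        n = self.shape[axis]
        o = self.origin[axis]
        return o + (np.arange(n) + 0.5) * self.voxel_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable voxel-center coordinate arrays (x, y, z)."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def flat_index(self, i, j, k):
        """C-order flat voxel index for (i, j, k)."""
        nx, ny, nz = self.shape
        return (np.asarray(i) * ny + np.asarray(j)) * nz + np.asarray(k)

    def contains_box(self, lo, hi) -> bool:
        glo, ghi = self.extent
        return bool(np.all(np.asarray(lo) >= glo - 1e-9) and np.all(np.asarray(hi) <= ghi + 1e-9))


@dataclass
class RSPVolume:
    """An RSP map on a :class:`VoxelGrid`.

    ``data`` has shape ``grid.shape`` (x, y, z) and is dimensionless RSP.
    """

    grid: VoxelGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )

    @classmethod
    def zeros(cls, grid: VoxelGrid) -> "RSPVolume":
        return cls(grid=grid, data=np.zeros(grid.shape))

    def copy(self) -> "RSPVolume":
        return RSPVolume(grid=self.grid, data=self.data.copy())
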