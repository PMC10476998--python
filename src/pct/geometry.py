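"""Sparse chord-length system matrix.

The linear model of list-mode proton CT is ``A x = b``: one row of ``A`` per
proton, one column per voxel, entry ``alpha_pv`` = chord length (mm) of the
proton's straight recorded trajectory through voxel ``v``; ``x`` is the RSP
map and ``b`` the measured WEPLs.  Alongside ``A`` we keep the per-voxel
chord sums ``s_v = sum_p alpha_pv`` (the diagonal of the weighting matrix
``V``), per-voxel proton counts, and the data-driven reconstructable mask
(voxels actually touched by at least one proton); untouched voxels stay at
RSP = 0 and are excluded from all statistics.

Trajectories are straight chords.  The trajectory model is pluggable in
principle — anything that yields per-voxel chords defines a valid ``A`` —
but only straight lines are provided; the solver algebra does not depend on
the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._tracing import trace_batch_csr
from .grid import VoxelGrid
from .simulate import ProtonList

__all__ = ["SystemMatrix", "trace_chords", "build_system_matrix"]


def trace_chords(point, direction, grid: VoxelGrid):
    """Chords of a straight ray through the grid.

    Returns ``(voxel_indices, chord_lengths)``: C-order flat voxel indices
    and intersection lengths (mm) for each voxel the forward ray traverses.
    The chord lengths sum to the length of the ray segment inside the grid.
    """
    d = np.asarray(direction, dtype=np.float64)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction vector must be nonzero")
    p = np.ascontiguousarray(np.asarray(point, dtype=np.float64).reshape(1, 3))
    u = np.ascontiguousarray((d / norm).reshape(1, 3))
    nx, ny, nz = grid.shape
    cap = nx + ny + nz + 3
    indptr = np.zeros(2, dtype=np.int64)
    indices = np.empty(cap, dtype=np.int64)
    lengths = np.empty(cap, dtype=np.float64)
    n = trace_batch_csr(p, u, grid.origin[0], grid.origin[1], grid.origin[2],
                        grid.voxel_size, nx, ny, nz, indptr, indices, lengths)
    return indices[:n].copy(), lengths[:n].copy()


@dataclass
class SystemMatrix:
    """Sparse chord matrix plus the per-voxel normalizers derived from it."""

    A: sp.csr_matrix = field(repr=False)
    grid: VoxelGrid
    chord_sums: np.ndarray = field(repr=False)     # s_v, mm
    proton_counts: np.ndarray = field(repr=False)  # protons touching voxel v
    mask: np.ndarray = field(repr=False)           # reconstructable voxels
    empty_rows: np.ndarray = field(repr=False)     # protons missing the grid
    npv_mean: float = 0.0                          # mean protons per masked voxel

    _AT: sp.spmatrix | None = field(default=None, repr=False)

    @property
    def n_protons(self) -> int:
        return self.A.shape[0]

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    @property
    def AT(self):
        """Transpose as a CSC view sharing A's arrays (no copy)."""
        if self._AT is None:
            self._AT = self.A.T
        return self._AT


def build_system_matrix(protons: ProtonList, grid: VoxelGrid) -> SystemMatrix:
    """Assemble ``A`` from recorded trajectories (entry point + direction).

    Rows of protons that miss the grid entirely are left empty and flagged
    in ``empty_rows``; if every proton misses, the geometry is rejected.
    """
    n = len(protons)
    if n == 0:
        raise ValueError("proton list is empty")
    nx, ny, nz = grid.shape
    cap_per_ray = nx + ny + nz + 3
    p = np.ascontiguousarray(protons.p_in)
    d = protons.d_in
    u = np.ascontiguousarray(d / np.linalg.norm(d, axis=1, keepdims=True))

    # trace in chunks so the worst-case per-ray buffers stay small
    chunk = max(1, min(n, 8_000_000 // cap_per_ray))
    idx_parts, len_parts, ptr_parts = [], [], [np.zeros(1, dtype=np.int64)]
    counts = np.zeros(grid.n_voxels, dtype=np.int64)
    chord_sums = np.zeros(grid.n_voxels)
    total = 0
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        indptr = np.zeros(m + 1, dtype=np.int64)
        indices = np.empty(m * cap_per_ray, dtype=np.int32)
        lengths = np.empty(m * cap_per_ray, dtype=np.float64)
        nnz = trace_batch_csr(p[lo:hi], u[lo:hi],
                              grid.origin[0], grid.origin[1], grid.origin[2],
                              grid.voxel_size, nx, ny, nz, indptr, indices, lengths)
        idx_parts.append(indices[:nnz].copy())
        len_parts.append(lengths[:nnz].copy())
        ptr_parts.append(indptr[1:] + total)
        counts += np.bincount(idx_parts[-1], minlength=grid.n_voxels)
        np.add.at(chord_sums, idx_parts[-1], len_parts[-1])
        total += nnz
    indptr = np.concatenate(ptr_parts)
    A = sp.csr_matrix(
        (np.concatenate(len_parts), np.concatenate(idx_parts), indptr),
        shape=(n, grid.n_voxels),
    )
    del idx_parts, len_parts
    empty_rows = np.diff(indptr) == 0
    if empty_rows.all():
        raise ValueError("every proton misses the voxel grid")
    mask = (counts >= 1) & (chord_sums > 0)
    npv_mean = float(counts[mask].mean())
    return SystemMatrix(A=A, grid=grid, chord_sums=chord_sums,
                        proton_counts=counts, mask=mask,
                        empty_rows=empty_rows, npv_mean=npv_mean)
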