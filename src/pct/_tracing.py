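"""Numba kernels for voxel traversal (Amanatides–Woo incremental ray walk).

All kernels parametrize a ray as ``p + t*u`` with ``u`` a unit vector and
``t`` a physical length in mm, walk the half-open voxel boxes
``[origin + i*h, origin + (i+1)*h)`` and emit per-voxel chord lengths.
Chords below ``CHORD_EPS`` (grazing intersections of measure ~0) are dropped.
"""

from __future__ import annotations

import numba as nb
import numpy as np

CHORD_EPS = 1e-6  # mm; grazing chords below this are dropped

_T_FAR = 1e18


@nb.njit(cache=True)
def _walk_ray(px, py, pz, ux, uy, uz, ox, oy, oz, h, nx, ny, nz,
              indices, lengths, pos):  # pragma: no cover - exercised via wrappers
    """Walk one ray from t=0 forward; append (flat voxel, chord) at ``pos``.

    Returns the new write position.  ``indices``/``lengths`` must have room
    for nx+ny+nz+3 more entries.
    """
    tmin = 0.0
    tmax = _T_FAR
    # slab clipping against the grid bounding box
    for axis in range(3):
        if axis == 0:
            p, u, lo, hi = px, ux, ox, ox + nx * h
        elif axis == 1:
            p, u, lo, hi = py, uy, oy, oy + ny * h
        else:
            p, u, lo, hi = pz, uz, oz, oz + nz * h
        if u != 0.0:
            t1 = (lo - p) / u
            t2 = (hi - p) / u
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
        elif p < lo or p >= hi:
            return pos  # parallel outside: miss
    if tmax - tmin <= CHORD_EPS:
        return pos

    # entry voxel (nudge inside to avoid landing exactly on a face)
    t0 = tmin + 1e-12 * (abs(tmin) + 1.0)
    qx = px + t0 * ux
    qy = py + t0 * uy
    qz = pz + t0 * uz
    i = int(np.floor((qx - ox) / h))
    j = int(np.floor((qy - oy) / h))
    k = int(np.floor((qz - oz) / h))
    if i < 0:
        i = 0
    elif i > nx - 1:
        i = nx - 1
    if j < 0:
        j = 0
    elif j > ny - 1:
        j = ny - 1
    if k < 0:
        k = 0
    elif k > nz - 1:
        k = nz - 1

    # per-axis crossing schedule
    if ux > 0.0:
        step_x, t_delta_x = 1, h / ux
        t_max_x = ((ox + (i + 1) * h) - px) / ux
    elif ux < 0.0:
        step_x, t_delta_x = -1, -h / ux
        t_max_x = ((ox + i * h) - px) / ux
    else:
        step_x, t_delta_x, t_max_x = 0, _T_FAR, _T_FAR
    if uy > 0.0:
        step_y, t_delta_y = 1, h / uy
        t_max_y = ((oy + (j + 1) * h) - py) / uy
    elif uy < 0.0:
        step_y, t_delta_y = -1, -h / uy
        t_max_y = ((oy + j * h) - py) / uy
    else:
        step_y, t_delta_y, t_max_y = 0, _T_FAR, _T_FAR
    if uz > 0.0:
        step_z, t_delta_z = 1, h / uz
        t_max_z = ((oz + (k + 1) * h) - pz) / uz
    elif uz < 0.0:
        step_z, t_delta_z = -1, -h / uz
        t_max_z = ((oz + k * h) - pz) / uz
    else:
        step_z, t_delta_z, t_max_z = 0, _T_FAR, _T_FAR

    t_cur = tmin
    while t_cur < tmax - CHORD_EPS:
        # next face crossing
        t_next = t_max_x
        axis = 0
        if t_max_y < t_next:
            t_next = t_max_y
            axis = 1
        if t_max_z < t_next:
            t_next = t_max_z
            axis = 2
        if t_next > tmax:
            t_next = tmax
        chord = t_next - t_cur
        if chord > CHORD_EPS:
            indices[pos] = (i * ny + j) * nz + k
            lengths[pos] = chord
            pos += 1
        t_cur = t_next
        if t_cur >= tmax - CHORD_EPS:
            break
        if axis == 0:
            i += step_x
            if i < 0 or i >= nx:
                break
            t_max_x += t_delta_x
        elif axis == 1:
            j += step_y
            if j < 0 or j >= ny:
                break
            t_max_y += t_delta_y
        else:
            k += step_z
            if k < 0 or k >= nz:
                break
            t_max_z += t_delta_z
    return pos


@nb.njit(cache=True)
def trace_batch_csr(points, dirs, ox, oy, oz, h, nx, ny, nz,
                    indptr, indices, lengths):  # pragma: no cover
    """Trace many rays, filling CSR arrays.  Returns total entry count."""
    pos = 0
    for r in range(points.shape[0]):
        pos = _walk_ray(points[r, 0], points[r, 1], points[r, 2],
                        dirs[r, 0], dirs[r, 1], dirs[r, 2],
                        ox, oy, oz, h, nx, ny, nz, indices, lengths, pos)
        indptr[r + 1] = pos
    return pos


@nb.njit(cache=True)
def line_integral_batch(points, dirs, values, ox, oy, oz, h,
                        out):  # pragma: no cover
    """Per-ray line integral  sum(chord * value)  through a 3-D field."""
    nx, ny, nz = values.shape
    max_steps = nx + ny + nz + 3
    indices = np.empty(max_steps, dtype=np.int64)
    lengths = np.empty(max_steps, dtype=np.float64)
    flat = values.reshape(nx * ny * nz)
    for r in range(points.shape[0]):
        n = _walk_ray(points[r, 0], points[r, 1], points[r, 2],
                      dirs[r, 0], dirs[r, 1], dirs[r, 2],
                      ox, oy, oz, h, nx, ny, nz, indices, lengths, 0)
        acc = 0.0
        for m in range(n):
            acc += lengths[m] * flat[indices[m]]
        out[r] = acc
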