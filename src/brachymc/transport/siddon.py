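"""Exact ray traversal of a regular voxel grid (Amanatides-Woo stepping).

The chords returned partition the in-grid segment of the ray exactly:
their sum equals the geometric path length of the ray inside the grid
box to ~1e-9 cm, which is what the track-length kerma estimator needs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["trace_voxels"]

_EPS = 1e-12


@njit(cache=True)
def _trace_kernel(px, py, pz, dx, dy, dz, ox, oy, oz, sx, sy, sz, nx, ny, nz,
                  out_idx, out_chord):
    """Walk the grid; fill voxel flat indices and chords; return count.

    Start point (px..), direction (dx.., normalized), grid corner (ox..),
    spacing (sx.. in cm), shape (nx..).  ``out_*`` must be sized for the
    worst case (nx+ny+nz+3 crossings).
    """
    # ray-box clip
    tmin = 0.0
    tmax = 1.0e30
    p = (px, py, pz)
    d = (dx, dy, dz)
    o = (ox, oy, oz)
    s = (sx, sy, sz)
    n = (nx, ny, nz)
    for a in range(3):
        lo = o[a]
        hi = o[a] + s[a] * n[a]
        if abs(d[a]) < _EPS:
            if p[a] <= lo or p[a] >= hi:
                return 0
        else:
            t1 = (lo - p[a]) / d[a]
            t2 = (hi - p[a]) / d[a]
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax <= tmin:
        return 0

    # entry voxel
    ex = px + (tmin + 1e-12) * dx
    ey = py + (tmin + 1e-12) * dy
    ez = pz + (tmin + 1e-12) * dz
    ix = int(np.floor((ex - ox) / sx))
    iy = int(np.floor((ey - oy) / sy))
    iz = int(np.floor((ez - oz) / sz))
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= nx:
        ix = nx - 1
    if iy >= ny:
        iy = ny - 1
    if iz >= nz:
        iz = nz - 1

    stepx = 1 if dx > 0 else (-1 if dx < 0 else 0)
    stepy = 1 if dy > 0 else (-1 if dy < 0 else 0)
    stepz = 1 if dz > 0 else (-1 if dz < 0 else 0)

    big = 1.0e30
    if stepx != 0:
        nxt = ox + (ix + (1 if stepx > 0 else 0)) * sx
        tx = (nxt - px) / dx
        dtx = sx / abs(dx)
    else:
        tx = big
        dtx = big
    if stepy != 0:
        nyt = oy + (iy + (1 if stepy > 0 else 0)) * sy
        ty = (nyt - py) / dy
        dty = sy / abs(dy)
    else:
        ty = big
        dty = big
    if stepz != 0:
        nzt = oz + (iz + (1 if stepz > 0 else 0)) * sz
        tz = (nzt - pz) / dz
        dtz = sz / abs(dz)
    else:
        tz = big
        dtz = big

    t = tmin
    count = 0
    while t < tmax - _EPS:
        if tx <= ty and tx <= tz:
            tnext = tx
        elif ty <= tz:
            tnext = ty
        else:
            tnext = tz
        if tnext > tmax:
            tnext = tmax
        chord = tnext - t
        if chord > _EPS:
            out_idx[count] = (ix * ny + iy) * nz + iz
            out_chord[count] = chord
            count += 1
        t = tnext
        if t >= tmax - _EPS:
            break
        if tx <= ty and tx <= tz:
            ix += stepx
            tx += dtx
            if ix < 0 or ix >= nx:
                break
        elif ty <= tz:
            iy += stepy
            ty += dty
            if iy < 0 or iy >= ny:
                break
        else:
            iz += stepz
            tz += dtz
            if iz < 0 or iz >= nz:
                break
    return count


def trace_voxels(start_cm, direction, phantom):
    """Ordered ``[(voxel index triple, chord cm), ...]`` of a ray through
    ``phantom`` (a `VoxelPhantom`).  Rays that miss the grid return ``[]``.

    The direction must be normalized; chords partition the in-grid
    segment exactly (sum equals the analytic box-intersection length).
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if abs(norm - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    p = np.asarray(start_cm, dtype=float)
    nx, ny, nz = phantom.shape
    cap = nx + ny + nz + 3
    out_idx = np.empty(cap, dtype=np.int64)
    out_chord = np.empty(cap, dtype=np.float64)
    sx, sy, sz = phantom.spacing_cm
    ox, oy, oz = phantom.origin_cm
    cnt = _trace_kernel(p[0], p[1], p[2], d[0], d[1], d[2],
                        ox, oy, oz, sx, sy, sz, nx, ny, nz, out_idx, out_chord)
    result = []
    for k in range(cnt):
        flat = out_idx[k]
        i = flat // (ny * nz)
        j = (flat // nz) % ny
        l = flat % nz
        result.append(((int(i), int(j), int(l)), float(out_chord[k])))
    return result
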