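"""Radiological path length by exact voxel traversal.

The radiological depth of a point is the density-scaled length of the
straight line from the beam source to that point, in soft-tissue-equivalent
cm: the line integral of (density / rho_soft_tissue) over the segment, which
starts accumulating where the line enters the body (density is zero outside
the body mask, so the integral over the whole segment is identical).

The traversal is Siddon-style: the segment is clipped to the grid and
stepped voxel face to voxel face, so each voxel contributes its density
times the exact intersected length.  A fine-step numerical integrator used
to validate this routine lives in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

SOFT_TISSUE_DENSITY = 1.0  # g/cm^3; reference for soft-tissue-equivalent depth


class OutsideGridError(ValueError):
    """The query point lies outside the phantom grid bounds."""


@njit(cache=True)
def _trace_one(p0x, p0y, p0z, p1x, p1y, p1z, lox, loy, loz,
               dx, dy, dz, dens):  # pragma: no cover - numba kernel
    """Line integral of dens along the segment p0 -> p1, clipped to the grid."""
    nx, ny, nz = dens.shape
    rx = p1x - p0x
    ry = p1y - p0y
    rz = p1z - p0z
    seg_len = (rx * rx + ry * ry + rz * rz) ** 0.5
    if seg_len == 0.0:
        return 0.0

    # slab-clip the parameter range [t0, t1] to the grid box
    t0 = 0.0
    t1 = 1.0
    for axis in range(3):
        if axis == 0:
            p, r, lo, hi = p0x, rx, lox, lox + nx * dx
        elif axis == 1:
            p, r, lo, hi = p0y, ry, loy, loy + ny * dy
        else:
            p, r, lo, hi = p0z, rz, loz, loz + nz * dz
        if r == 0.0:
            if p < lo or p >= hi:
                return 0.0
        else:
            ta = (lo - p) / r
            tb = (hi - p) / r
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t0 >= t1:
        return 0.0

    # entry voxel
    ex = p0x + t0 * rx
    ey = p0y + t0 * ry
    ez = p0z + t0 * rz
    ix = int((ex - lox) / dx)
    iy = int((ey - loy) / dy)
    iz = int((ez - loz) / dz)
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix > nx - 1:
        ix = nx - 1
    if iy > ny - 1:
        iy = ny - 1
    if iz > nz - 1:
        iz = nz - 1

    # parametric step per axis and parameter of next face crossing
    big = 1e30
    if rx > 0.0:
        tdx = dx / rx
        tmx = t0 + ((lox + (ix + 1) * dx) - ex) / rx
        sx = 1
    elif rx < 0.0:
        tdx = -dx / rx
        tmx = t0 + ((lox + ix * dx) - ex) / rx
        sx = -1
    else:
        tdx = big
        tmx = big
        sx = 0
    if ry > 0.0:
        tdy = dy / ry
        tmy = t0 + ((loy + (iy + 1) * dy) - ey) / ry
        sy = 1
    elif ry < 0.0:
        tdy = -dy / ry
        tmy = t0 + ((loy + iy * dy) - ey) / ry
        sy = -1
    else:
        tdy = big
        tmy = big
        sy = 0
    if rz > 0.0:
        tdz = dz / rz
        tmz = t0 + ((loz + (iz + 1) * dz) - ez) / rz
        sz = 1
    elif rz < 0.0:
        tdz = -dz / rz
        tmz = t0 + ((loz + iz * dz) - ez) / rz
        sz = -1
    else:
        tdz = big
        tmz = big
        sz = 0

    total = 0.0
    t = t0
    while t < t1:
        tn = tmx
        if tmy < tn:
            tn = tmy
        if tmz < tn:
            tn = tmz
        if tn > t1:
            tn = t1
        total += dens[ix, iy, iz] * (tn - t)
        t = tn
        if t >= t1:
            break
        if tn == tmx:
            ix += sx
            tmx += tdx
            if ix < 0 or ix >= nx:
                break
        elif tn == tmy:
            iy += sy
            tmy += tdy
            if iy < 0 or iy >= ny:
                break
        else:
            iz += sz
            tmz += tdz
            if iz < 0 or iz >= nz:
                break
    return total * seg_len


@njit(parallel=True, cache=True)
def _trace_many(src, pts, lox, loy, loz, dx, dy, dz, dens, out):  # pragma: no cover
    for i in prange(pts.shape[0]):
        out[i] = _trace_one(
            src[0], src[1], src[2],
            pts[i, 0], pts[i, 1], pts[i, 2],
            lox, loy, loz, dx, dy, dz, dens,
        )


def path_integral(source, points, density: np.ndarray, spacing, origin) -> np.ndarray:
    """Density line integrals from ``source`` to each of ``points`` (g/cm^2).

    ``density`` is indexed (x, y, z); voxel centers at
    ``origin + i * spacing``, half-open voxel extents.
    """
    src = np.asarray(source, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dens = np.ascontiguousarray(density, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    lo = np.asarray(origin, dtype=float) - 0.5 * sp
    out = np.empty(pts.shape[0])
    _trace_many(src, pts, lo[0], lo[1], lo[2], sp[0], sp[1], sp[2], dens, out)
    return out
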