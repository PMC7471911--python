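"""Fast point-vs-triangle-mesh queries (inside test, surface distance).

The volumetric stage needs two primitives on closed triangle meshes: an
inside/outside test and the unsigned distance from a point to the surface.
Both are implemented as numba-compiled kernels over the raw triangle array:

* inside test — generalized winding number (sum of signed solid angles of
  all triangles, van Oosterom–Strackee formula); robust for watertight
  meshes, |w| > 1/2 means inside.
* distance — exact minimum point-to-triangle distance (barycentric clamping
  to face / edges / vertices).
"""

from __future__ import annotations

import numpy as np
import trimesh
from numba import njit

from .errors import ValidationError

TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=True)
def _winding_numbers(points, tri):  # pragma: no cover - compiled
    n = points.shape[0]
    T = tri.shape[0]
    out = np.empty(n)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        total = 0.0
        for t in range(T):
            ax = tri[t, 0, 0] - px; ay = tri[t, 0, 1] - py; az = tri[t, 0, 2] - pz
            bx = tri[t, 1, 0] - px; by = tri[t, 1, 1] - py; bz = tri[t, 1, 2] - pz
            cx = tri[t, 2, 0] - px; cy = tri[t, 2, 1] - py; cz = tri[t, 2, 2] - pz
            la = (ax * ax + ay * ay + az * az) ** 0.5
            lb = (bx * bx + by * by + bz * bz) ** 0.5
            lc = (cx * cx + cy * cy + cz * cz) ** 0.5
            num = (ax * (by * cz - bz * cy)
                   + ay * (bz * cx - bx * cz)
                   + az * (bx * cy - by * cx))
            den = (la * lb * lc
                   + (ax * bx + ay * by + az * bz) * lc
                   + (bx * cx + by * cy + bz * cz) * la
                   + (ax * cx + ay * cy + az * cz) * lb)
            total += np.arctan2(num, den)
        out[i] = total / TWO_PI
    return out


@njit(cache=True, fastmath=True)
def _point_triangle_sq(px, py, pz, tri, t):  # pragma: no cover - compiled
    """Squared distance from one point to triangle ``t`` (Ericson's method)."""
    ax, ay, az = tri[t, 0, 0], tri[t, 0, 1], tri[t, 0, 2]
    bx, by, bz = tri[t, 1, 0], tri[t, 1, 1], tri[t, 1, 2]
    cx, cy, cz = tri[t, 2, 0], tri[t, 2, 1], tri[t, 2, 2]
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return apx * apx + apy * apy + apz * apz
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bpx * bpx + bpy * bpy + bpz * bpz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        qx, qy, qz = apx - v * abx, apy - v * aby, apz - v * abz
        return qx * qx + qy * qy + qz * qz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cpx * cpx + cpy * cpy + cpz * cpz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        qx, qy, qz = apx - w * acx, apy - w * acy, apz - w * acz
        return qx * qx + qy * qy + qz * qz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        qx = bpx - w * (cx - bx)
        qy = bpy - w * (cy - by)
        qz = bpz - w * (cz - bz)
        return qx * qx + qy * qy + qz * qz
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    qx = apx - v * abx - w * acx
    qy = apy - v * aby - w * acy
    qz = apz - v * abz - w * acz
    return qx * qx + qy * qy + qz * qz


@njit(cache=True, fastmath=True)
def _surface_distances(points, tri):  # pragma: no cover - compiled
    n = points.shape[0]
    out = np.empty(n)
    for i in range(n):
        best = 1e300
        for t in range(tri.shape[0]):
            sq = _point_triangle_sq(points[i, 0], points[i, 1], points[i, 2], tri, t)
            if sq < best:
                best = sq
        out[i] = best ** 0.5
    return out


class MeshQuery:
    """Inside/distance oracle for one watertight mesh."""

    def __init__(self, mesh: trimesh.Trimesh):
        if not mesh.is_watertight:
            raise ValidationError("mesh must be watertight (closed surface)")
        self.mesh = mesh
        self._tri = np.ascontiguousarray(mesh.triangles, dtype=float)

    def contains(self, points) -> np.ndarray:
        """True for points strictly inside the mesh (winding number test)."""
        pts = np.ascontiguousarray(np.atleast_2d(points), dtype=float)
        return np.abs(_winding_numbers(pts, self._tri)) > 0.5

    def surface_distance(self, points) -> np.ndarray:
        """Exact unsigned distance from each point to the mesh surface."""
        pts = np.ascontiguousarray(np.atleast_2d(points), dtype=float)
        return _surface_distances(pts, self._tri)

    def signed_distance(self, points) -> np.ndarray:
        """Positive inside, negative outside."""
        d = self.surface_distance(points)
        sign = np.where(self.contains(points), 1.0, -1.0)
        return sign * d
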