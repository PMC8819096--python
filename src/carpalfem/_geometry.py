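"""Low-level vectorized geometry kernels.

Point-in-solid queries and point-to-triangle projections are needed all over
the pipeline (tet filtering, landmark snapping, tie/contact pair search).
They are implemented here directly on (n, 3) arrays so the rest of the code
never loops over triangles in Python.
"""

from __future__ import annotations

import numpy as np

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# Fixed, deliberately irrational-looking ray directions: axis-aligned rays hit
# mesh edges/vertices far too often on parametric geometry.
RAY_DIRECTION = _unit(np.array([0.2987624581, 0.5432178123, 0.7893215241]))
_RAY_DIRECTION_ALT = _unit(np.array([-0.6412873511, 0.2871236411, 0.7113529833]))


def ray_hits(origins: np.ndarray, direction: np.ndarray, tri: np.ndarray,
             eps: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Count ray/triangle intersections per origin (Moller-Trumbore, batched).

    Parameters
    ----------
    origins : (n, 3) ray origins.
    direction : (3,) shared ray direction.
    tri : (m, 3, 3) triangle vertices.

    Returns
    -------
    counts : (n,) int intersection counts (t > 0 only).
    suspect : (n,) bool, True where some hit was numerically marginal
        (barycentric coordinate or t near zero) and the parity is unreliable.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    n = origins.shape[0]
    v0 = tri[:, 0]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(np.broadcast_to(direction, e1.shape), e2)
    a = np.einsum("mj,mj->m", e1, h)  # (m,)
    ok = np.abs(a) > eps
    counts = np.zeros(n, dtype=int)
    suspect = np.zeros(n, dtype=bool)
    if not ok.any():
        return counts, suspect
    v0, e1, e2, h, a = v0[ok], e1[ok], e2[ok], h[ok], a[ok]
    inv_a = 1.0 / a
    # chunk origins to bound memory at ~ chunk * m
    m = v0.shape[0]
    chunk = max(1, int(4e6 // max(m, 1)))
    margin = 1e-9
    for lo in range(0, n, chunk):
        o = origins[lo:lo + chunk]  # (c,3)
        s = o[:, None, :] - v0[None, :, :]          # (c,m,3)
        u = np.einsum("cmj,mj->cm", s, h) * inv_a
        q = np.cross(s, np.broadcast_to(e1, s.shape))
        v = np.einsum("cmj,j->cm", q, direction) * inv_a
        t = np.einsum("cmj,mj->cm", q, e2) * inv_a
        hit = (u >= -margin) & (v >= -margin) & (u + v <= 1.0 + margin) & (t > margin)
        near_edge = hit & ((np.abs(u) < margin) | (np.abs(v) < margin)
                           | (np.abs(1.0 - u - v) < margin) | (np.abs(t) < 10 * margin))
        counts[lo:lo + chunk] = hit.sum(axis=1)
        suspect[lo:lo + chunk] = near_edge.any(axis=1)
    return counts, suspect


def points_in_surface(points: np.ndarray, vertices: np.ndarray,
                      faces: np.ndarray) -> np.ndarray:
    """Generalized-winding-number inside test for a closed surface.

    Sums the signed solid angle subtended by every (outward-wound) triangle
    (Van Oosterom-Strackee); for a watertight, consistently oriented mesh
    the total is ~4*pi inside and ~0 outside.  Robust where ray-parity
    tests fail (rays grazing edges/vertices of structured meshes).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(vertices, dtype=float)[np.asarray(faces, dtype=int)]
    n = points.shape[0]
    m = tri.shape[0]
    winding = np.empty(n)
    chunk = max(1, int(2e6 // max(m, 1)))
    for lo in range(0, n, chunk):
        p = points[lo:lo + chunk][:, None, :]       # (c,1,3)
        a = tri[None, :, 0, :] - p                  # (c,m,3)
        b = tri[None, :, 1, :] - p
        c = tri[None, :, 2, :] - p
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        num = np.einsum("cmj,cmj->cm", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("cmj,cmj->cm", a, b) * lc
               + np.einsum("cmj,cmj->cm", b, c) * la
               + np.einsum("cmj,cmj->cm", c, a) * lb)
        omega = 2.0 * np.arctan2(num, den)
        winding[lo:lo + chunk] = omega.sum(axis=1)
    return winding > 2.0 * np.pi


def ray_exit_distances(origin: np.ndarray, directions: np.ndarray,
                       tri: np.ndarray) -> np.ndarray:
    """Farthest ray/triangle hit distance per direction (0 if no hit).

    Used to build star-shaped union envelopes: casting from an interior
    point of one solid against another solid's surface gives the union's
    radial extent along each direction.
    """
    origin = np.asarray(origin, dtype=float)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    v0 = tri[:, 0]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    out = np.zeros(len(directions))
    s = origin - v0                                   # (m,3)
    chunk = max(1, int(4e6 // max(len(tri), 1)))
    margin = 1e-9
    for lo in range(0, len(directions), chunk):
        d = directions[lo:lo + chunk]                 # (c,3)
        h = np.cross(d[:, None, :], e2[None, :, :])   # (c,m,3)
        a = np.einsum("cmj,mj->cm", h, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_a = np.where(np.abs(a) > 1e-12, 1.0 / a, 0.0)
        u = np.einsum("mj,cmj->cm", s, h) * inv_a
        q = np.cross(s, e1)                           # (m,3)
        v = np.einsum("cj,mj->cm", d, q) * inv_a
        t = np.einsum("mj,mj->m", q, e2)[None, :] * inv_a
        hit = ((np.abs(a) > 1e-12) & (u >= -margin) & (v >= -margin)
               & (u + v <= 1 + margin) & (t > 0))
        tvals = np.where(hit, t, 0.0)
        out[lo:lo + chunk] = tvals.max(axis=1)
    return out


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray,
                               chunk: int = 512):
    """Closest point on a triangle soup for each query point.

    Implements the standard region-classification projection (Ericson)
    vectorized over (points x triangles).

    Returns
    -------
    dist : (n,) distances.
    closest : (n, 3) closest points.
    index : (n,) triangle index attaining the minimum.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = np.asarray(tri, dtype=float)
    n = points.shape[0]
    m = tri.shape[0]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    dist = np.empty(n)
    closest = np.empty((n, 3))
    index = np.empty(n, dtype=int)
    step = max(1, int(2e6 // max(m, 1)))
    for lo in range(0, n, step):
        p = points[lo:lo + step][:, None, :]  # (c,1,3)
        ap = p - a
        d1 = np.einsum("mj,cmj->cm", ab, ap)
        d2 = np.einsum("mj,cmj->cm", ac, ap)
        bp = p - b
        d3 = np.einsum("mj,cmj->cm", ab, bp)
        d4 = np.einsum("mj,cmj->cm", ac, bp)
        cp = p - c
        d5 = np.einsum("mj,cmj->cm", ab, cp)
        d6 = np.einsum("mj,cmj->cm", ac, cp)

        va = d3 * d6 - d5 * d4
        vb = d5 * d2 - d1 * d6
        vc = d1 * d4 - d3 * d2

        with np.errstate(divide="ignore", invalid="ignore"):
            denom = va + vb + vc
            v = np.where(denom != 0, vb / denom, 0.0)
            w = np.where(denom != 0, vc / denom, 0.0)
            t_ab = np.clip(np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0), 0, 1)
            t_ac = np.clip(np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0), 0, 1)
            dd = (d4 - d3) + (d5 - d6)
            t_bc = np.clip(np.where(dd != 0, (d4 - d3) / dd, 0.0), 0, 1)

        cand_int = a + v[..., None] * ab + w[..., None] * ac
        cand_ab = a + t_ab[..., None] * ab
        cand_ac = a + t_ac[..., None] * ac
        cand_bc = b + t_bc[..., None] * (c - b)

        # Ericson's region tests, first match wins
        conds = [
            (d1 <= 0) & (d2 <= 0),               # vertex A
            (d3 >= 0) & (d4 <= d3),              # vertex B
            (d6 >= 0) & (d5 <= d6),              # vertex C
            (vc <= 0) & (d1 >= 0) & (d3 <= 0),   # edge AB
            (vb <= 0) & (d2 >= 0) & (d6 <= 0),   # edge AC
            (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),  # edge BC
        ]
        shape = cand_int.shape
        choices = [np.broadcast_to(a, shape), np.broadcast_to(b, shape),
                   np.broadcast_to(c, shape), cand_ab, cand_ac, cand_bc]
        cand = np.select([cnd[..., None] for cnd in conds], choices, cand_int)

        d2all = np.einsum("cmj,cmj->cm", p - cand, p - cand)
        best = np.argmin(d2all, axis=1)
        rows = np.arange(d2all.shape[0])
        dist[lo:lo + step] = np.sqrt(d2all[rows, best])
        closest[lo:lo + step] = cand[rows, best]
        index[lo:lo + step] = best
    return dist, closest, index


def closest_point_on_surface(points, vertices, faces):
    """Convenience wrapper taking (vertices, faces) instead of a soup."""
    tri = np.asarray(vertices, dtype=float)[np.asarray(faces, dtype=int)]
    return closest_point_on_triangles(points, tri)
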