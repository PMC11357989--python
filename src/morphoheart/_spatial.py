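"""Vectorised closest-point and ray queries against triangle soups.

A k-d tree over triangle centroids prunes candidates; exact point-triangle
distances (Ericson's region test) and Moller-Trumbore ray-triangle
intersections are then evaluated on the candidate set only, with a brute
force fallback whenever the pruning bound cannot certify the result.
Ties between equidistant triangles are broken toward the lowest face index.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SurfaceQuery", "closest_point_on_triangles"]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle j to point j, row-wise.

    points: (N, 3); triangles: (N, 3, 3).  Returns (N, 3).
    """
    p = np.asarray(points, dtype=np.float64)
    tri = np.asarray(triangles, dtype=np.float64)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    result[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    result[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    result[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = np.where(d1 - d3 != 0, d1 - d3, 1.0)
    v = (d1 / denom)[:, None]
    result[m] = (a + v * ab)[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = np.where(d2 - d6 != 0, d2 - d6, 1.0)
    w = (d2 / denom)[:, None]
    result[m] = (a + w * ac)[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    denom = np.where(denom != 0, denom, 1.0)
    w = ((d4 - d3) / denom)[:, None]
    result[m] = (b + w * (c - b))[m]
    done |= m

    # interior
    m = ~done
    denom = va + vb + vc
    denom = np.where(denom != 0, denom, 1.0)
    v = (vb / denom)[:, None]
    w = (vc / denom)[:, None]
    result[m] = (a + v * ab + w * ac)[m]
    return result


class SurfaceQuery:
    """Closest-point and first-hit ray queries against one triangle mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=np.float64)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.triangles = self.vertices[self.faces]  # (F, 3, 3)
        self.centroids = self.triangles.mean(axis=1)
        # circumscribing radius bound per triangle around its centroid
        self.radii = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2).max(axis=1)
        self.max_radius = float(self.radii.max()) if len(self.radii) else 0.0
        self.tree = cKDTree(self.centroids)

    # -- closest point -----------------------------------------------------
    def closest(self, points: np.ndarray, k: int = 32):
        """Returns (closest points (N,3), distances (N,), face indices (N,))."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        nf = len(self.faces)
        k = min(k, nf)
        dc, idx = self.tree.query(pts, k=k)
        if k == 1:
            dc, idx = dc[:, None], idx[:, None]
        best_pt = np.zeros_like(pts)
        best_d = np.full(len(pts), np.inf)
        best_f = np.zeros(len(pts), dtype=np.int64)
        self._reduce_candidates(pts, idx, best_pt, best_d, best_f)
        # certification: if another centroid beyond the k-th could still hide
        # a closer triangle, fall back to brute force for those points
        if k < nf:
            uncertain = best_d > dc[:, -1] - self.max_radius
            if uncertain.any():
                allf = np.arange(nf)
                for i in np.nonzero(uncertain)[0]:
                    self._reduce_candidates(pts[i:i + 1], allf[None, :],
                                            best_pt[i:i + 1], best_d[i:i + 1],
                                            best_f[i:i + 1])
        return best_pt, best_d, best_f

    def _reduce_candidates(self, pts, cand, best_pt, best_d, best_f):
        n, k = cand.shape
        flat_pts = np.repeat(pts, k, axis=0)
        flat_tris = self.triangles[cand.ravel()]
        cp = closest_point_on_triangles(flat_pts, flat_tris).reshape(n, k, 3)
        d = np.linalg.norm(cp - pts[:, None, :], axis=2)
        # deterministic tie-break: among near-equal minima take lowest face id
        dmin = d.min(axis=1)
        for i in range(n):
            ties = np.nonzero(d[i] <= dmin[i] + 1e-12)[0]
            j = ties[np.argmin(cand[i][ties])]
            if d[i, j] < best_d[i]:
                best_d[i] = d[i, j]
                best_pt[i] = cp[i, j]
                best_f[i] = cand[i, j]

    # -- rays --------------------------------------------------------------
    def ray_first(self, origins: np.ndarray, directions: np.ndarray,
                  t_min: float = 0.0, t_max: float = np.inf,
                  exclude_faces: np.ndarray | None = None,
                  facing_only: bool = False):
        """First intersection of each ray with the surface.

        Returns (t (N,), face (N,)); t = inf / face = -1 where no hit occurs
        in (t_min, t_max].  ``exclude_faces[i]`` may list faces to ignore for
        ray i (e.g. the faces incident to the ray's source vertex).  With
        ``facing_only`` hits are restricted to triangles whose oriented
        normal faces the incoming ray head-on (dot(normal, dir) > 0.5),
        e.g. the opposing wall of a thin shell rather than a grazing sheet.
        """
        o = np.atleast_2d(np.asarray(origins, dtype=np.float64))
        d = np.atleast_2d(np.asarray(directions, dtype=np.float64))
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        n = len(o)
        t_out = np.full(n, np.inf)
        f_out = np.full(n, -1, dtype=np.int64)
        if not np.isfinite(t_max):
            span = float(np.linalg.norm(np.ptp(self.vertices, axis=0))) or 1.0
            t_max = 2.0 * span
        mids = o + 0.5 * t_max * d
        radius = 0.5 * t_max + self.max_radius + 1e-9
        groups = self.tree.query_ball_point(mids, r=radius)
        if facing_only:
            e1 = self.triangles[:, 1] - self.triangles[:, 0]
            e2 = self.triangles[:, 2] - self.triangles[:, 0]
            fn = np.cross(e1, e2)
            fn = fn / np.maximum(np.linalg.norm(fn, axis=1, keepdims=True), 1e-300)
        for i in range(n):
            cand = np.asarray(groups[i], dtype=np.int64)
            if cand.size == 0:
                continue
            if exclude_faces is not None and len(exclude_faces[i]):
                cand = cand[~np.isin(cand, exclude_faces[i])]
                if cand.size == 0:
                    continue
            if facing_only:
                cand = cand[fn[cand] @ d[i] > 0.5]
                if cand.size == 0:
                    continue
            t = _ray_tri(o[i], d[i], self.triangles[cand])
            ok = (t > t_min) & (t <= t_max)
            if ok.any():
                j = np.argmin(np.where(ok, t, np.inf))
                t_out[i] = t[j]
                f_out[i] = cand[j]
        return t_out, f_out


def _ray_tri(origin: np.ndarray, direction: np.ndarray, tris: np.ndarray) -> np.ndarray:
    """Moller-Trumbore: hit parameter t for one ray against many triangles
    (inf where the ray misses)."""
    eps = 1e-12
    v0, v1, v2 = tris[:, 0], tris[:, 1], tris[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(np.broadcast_to(direction, e2.shape), e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > eps
    f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", e2, q)
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol)
    return np.where(hit, t, np.inf)
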