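"""Point-to-triangle-mesh proximity queries.

Closest-point queries against a triangle soup: a cKDTree over triangle
centroids proposes candidate triangles, and an exact vectorized
point-to-triangle projection picks the winner.  Exactness holds as long as
the true nearest triangle is among the k candidates; k=16 with a fallback
radius re-query is ample for the densely, uniformly triangulated marching-
cubes surfaces used here.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SurfaceDistance", "closest_point_on_triangles"]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle i to point i, vectorized over i.

    ``points``: (n, 3); ``triangles``: (n, 3, 3).  Standard barycentric
    region classification (Ericson).
    """
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]
    ab = b - a
    ac = c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    if np.any(m):
        v = d1[m] / (d1[m] - d3[m])
        out[m] = a[m] + v[:, None] * ab[m]
        done |= m
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    if np.any(m):
        w = d2[m] / (d2[m] - d6[m])
        out[m] = a[m] + w[:, None] * ac[m]
        done |= m
    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    if np.any(m):
        w = (d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m]))
        out[m] = b[m] + w[:, None] * (c[m] - b[m])
        done |= m

    # interior
    m = ~done
    if np.any(m):
        denom = va[m] + vb[m] + vc[m]
        # degenerate (zero-area) triangles fall back to vertex a
        safe = denom != 0
        v = np.where(safe, vb[m] / np.where(safe, denom, 1.0), 0.0)
        w = np.where(safe, vc[m] / np.where(safe, denom, 1.0), 0.0)
        out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


class SurfaceDistance:
    """Nearest-surface-point queries against one triangle mesh."""

    def __init__(self, mesh, k: int = 16):
        self._tri = np.asarray(mesh.triangles, dtype=float)  # (m, 3, 3)
        self._centroids = self._tri.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        # triangle circumscribing radius bounds the candidate-search slack
        self._max_radius = float(
            np.sqrt(
                ((self._tri - self._centroids[:, None, :]) ** 2).sum(axis=2).max()
            )
        )
        self._k = min(k, len(self._tri))

    def query(self, points) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (distances, closest surface points, triangle indices)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, idx = self._tree.query(pts, k=self._k)
        idx = np.atleast_2d(idx)
        n, k = idx.shape
        flat_pts = np.repeat(pts, k, axis=0)
        cand = closest_point_on_triangles(flat_pts, self._tri[idx.ravel()])
        d2 = ((cand - flat_pts) ** 2).sum(axis=1).reshape(n, k)
        best = d2.argmin(axis=1)
        rows = np.arange(n)
        dist = np.sqrt(d2[rows, best])
        closest = cand.reshape(n, k, 3)[rows, best]
        tri_idx = idx[rows, best]

        # A centroid further than dist + max_radius cannot host a closer
        # triangle, so re-query only points whose k-th candidate violates that.
        kth_centroid_d = np.sqrt(((self._centroids[idx[:, -1]] - pts) ** 2).sum(axis=1))
        suspect = kth_centroid_d < dist + self._max_radius
        if self._k < len(self._tri) and np.any(suspect):
            for i in np.flatnonzero(suspect):
                near = self._tree.query_ball_point(pts[i], dist[i] + self._max_radius)
                cand_i = closest_point_on_triangles(
                    np.broadcast_to(pts[i], (len(near), 3)).copy(),
                    self._tri[np.asarray(near)],
                )
                d2_i = ((cand_i - pts[i]) ** 2).sum(axis=1)
                j = int(d2_i.argmin())
                if d2_i[j] < dist[i] ** 2:
                    dist[i] = np.sqrt(d2_i[j])
                    closest[i] = cand_i[j]
                    tri_idx[i] = near[j]
        return dist, closest, tri_idx

    def project(self, points) -> np.ndarray:
        """Closest surface points (same shape as input)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        _, closest, _ = self.query(pts)
        return closest[0] if single else closest
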