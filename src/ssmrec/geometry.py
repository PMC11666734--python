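"""Low-level geometric queries shared across the pipeline.

Closest-point-on-surface queries are the workhorse of both the isotropic
remesher (projection back onto the reference surface) and the non-rigid ICP
(correspondence search).  The implementation is fully vectorised: a KD-tree
over triangle centroids proposes candidate triangles, and the exact
point-to-triangle projection is evaluated for all candidates at once.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceQuery",
    "closest_point_on_triangles",
    "vertex_normals",
    "fit_plane",
    "CircleFit",
    "fit_circle_3d",
]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Exact closest point on each triangle for each paired query point.

    Parameters
    ----------
    points : (n, 3) query points.
    triangles : (n, 3, 3) triangle vertices paired with the query points.

    Returns
    -------
    (n, 3) closest points (Ericson's region classification, vectorised).
    """
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]
    p = points

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    result = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex region A
    mask = (d1 <= 0) & (d2 <= 0)
    result[mask] = a[mask]
    done |= mask

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    mask = ~done & (d3 >= 0) & (d4 <= d3)
    result[mask] = b[mask]
    done |= mask

    vc = d1 * d4 - d3 * d2
    mask = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1 - d3
    v = np.where(denom != 0, d1 / np.where(denom == 0, 1.0, denom), 0.0)
    result[mask] = a[mask] + v[mask, None] * ab[mask]
    done |= mask

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    mask = ~done & (d6 >= 0) & (d5 <= d6)
    result[mask] = c[mask]
    done |= mask

    vb = d5 * d2 - d1 * d6
    mask = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2 - d6
    w = np.where(denom != 0, d2 / np.where(denom == 0, 1.0, denom), 0.0)
    result[mask] = a[mask] + w[mask, None] * ac[mask]
    done |= mask

    va = d3 * d6 - d5 * d4
    mask = ~done & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1.0, denom), 0.0)
    result[mask] = b[mask] + w[mask, None] * (c[mask] - b[mask])
    done |= mask

    # interior
    mask = ~done
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    result[mask] = a[mask] + v[mask, None] * ab[mask] + w[mask, None] * ac[mask]
    return result


class SurfaceQuery:
    """Closest-point queries against a fixed triangulated surface."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=np.float64)
        self.faces = np.asarray(faces, dtype=np.int64)
        self._tri = self.vertices[self.faces]  # (F, 3, 3)
        self._centroids = self._tri.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        # conservative candidate radius: longest triangle edge
        e = self._tri - np.roll(self._tri, 1, axis=1)
        self._max_edge = float(np.sqrt((e**2).sum(-1)).max()) if len(faces) else 0.0
        n = np.cross(self._tri[:, 1] - self._tri[:, 0], self._tri[:, 2] - self._tri[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        self.face_normals = n / norm
        # faces touching an open boundary (edges with a single incident face)
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        uniq, inv, counts = np.unique(edges, axis=0, return_inverse=True, return_counts=True)
        boundary_edge = counts[inv] == 1  # per (face, local-edge) entry
        self.face_on_boundary = boundary_edge.reshape(-1, 3).any(axis=1)

    def closest(self, points: np.ndarray, k: int = 8):
        """Closest surface point for each query.

        Returns ``(closest_points, distances, face_indices)``.  Exact as long
        as the true nearest triangle is among the ``k`` nearest centroids
        (guaranteed for well-shaped meshes; ``k`` trades cost for robustness).
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        k = min(k, len(self.faces))
        _, idx = self._tree.query(points, k=k)
        idx = np.atleast_2d(idx)
        n, kk = idx.shape
        flat_idx = idx.reshape(-1)
        rep_pts = np.repeat(points, kk, axis=0)
        cand = closest_point_on_triangles(rep_pts, self._tri[flat_idx])
        d2 = ((cand - rep_pts) ** 2).sum(-1).reshape(n, kk)
        best = d2.argmin(axis=1)
        rows = np.arange(n)
        closest = cand.reshape(n, kk, 3)[rows, best]
        faces = idx[rows, best]
        return closest, np.sqrt(d2[rows, best]), faces


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted vertex normals (unit length; zero rows left as +z)."""
    tri = vertices[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area weighted
    vn = np.zeros_like(vertices)
    for i in range(3):
        np.add.at(vn, faces[:, i], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    degenerate = norm[:, 0] < 1e-300
    norm[degenerate] = 1.0
    vn = vn / norm
    vn[degenerate] = (0.0, 0.0, 1.0)
    return vn


def fit_plane(points: np.ndarray):
    """Total-least-squares plane through points.

    Returns ``(centroid, unit_normal)``; the normal is the singular vector of
    the smallest singular value of the centred point cloud.
    """
    points = np.asarray(points, dtype=np.float64)
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid, full_matrices=False)
    return centroid, vt[-1]


class CircleFit:
    """Result of a 3D circle fit: radius (mm), centre, plane normal."""

    __slots__ = ("radius", "center", "normal")

    def __init__(self, radius: float, center: np.ndarray, normal: np.ndarray):
        self.radius = float(radius)
        self.center = np.asarray(center, dtype=np.float64)
        self.normal = np.asarray(normal, dtype=np.float64)


def fit_circle_3d(points: np.ndarray, max_gn_iters: int = 20) -> CircleFit:
    """Least-squares circle through 3D points.

    The points are projected onto their total-least-squares plane, an
    algebraic (Kasa) fit provides the initial centre/radius, and a geometric
    Gauss-Newton refinement minimises the sum of squared radial residuals.

    Raises
    ------
    ValueError
        For fewer than 3 points or (near-)collinear input, where the radius
        diverges.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[0] < 3 or points.shape[1] != 3:
        raise ValueError("circle fit requires at least 3 points in 3D")
    centroid, normal = fit_plane(points)
    # orthonormal in-plane frame
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    xy = np.column_stack([(points - centroid) @ u, (points - centroid) @ v])

    spread = np.linalg.norm(xy - xy.mean(axis=0), axis=1).max()
    # Kasa: x^2 + y^2 = 2 a x + 2 b y + c
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    rhs = (xy**2).sum(axis=1)
    sol, _, rank, sv = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3 or (sv[-1] / sv[0]) < 1e-12:
        raise ValueError("points are collinear; circle radius is infinite")
    a, b, c = sol
    r = np.sqrt(max(c + a * a + b * b, 0.0))
    if not np.isfinite(r) or r > 1e8 * max(spread, 1e-30):
        raise ValueError("points are collinear; circle radius is infinite")

    # Gauss-Newton on (a, b, r): residual_i = |p_i - (a,b)| - r
    center = np.array([a, b])
    for _ in range(max_gn_iters):
        d = xy - center
        rho = np.linalg.norm(d, axis=1)
        if np.any(rho < 1e-12):
            break
        res = rho - r
        J = np.column_stack([-d[:, 0] / rho, -d[:, 1] / rho, -np.ones(len(xy))])
        step, *_ = np.linalg.lstsq(J, -res, rcond=None)
        center = center + step[:2]
        r = r + step[2]
        if np.linalg.norm(step) < 1e-12 * max(r, 1.0):
            break
    center3d = centroid + center[0] * u + center[1] * v
    return CircleFit(abs(r), center3d, normal)
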