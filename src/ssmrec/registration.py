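"""Rigid and non-rigid surface registration.

The non-rigid ICP deforms a *template* mesh onto a *target* surface under a
graph-Laplacian smoothness prior with an annealed stiffness schedule.  The
direction matters: the template deforms onto the data, so where the target
has no surface (missing fracture fragments, holes) the corresponding
template vertices are carried by regularisation alone and flagged invalid.
This is precisely what makes statistical-shape-model fitting of partial
shapes possible.

The whole pipeline is deterministic: KD-tree queries and sparse linear
solves only, no randomness.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import SurfaceQuery, vertex_normals
from .mesh import EmptyMeshError, TriangleMesh

__all__ = [
    "RigidTransform",
    "NonRigidParams",
    "CorrespondedShape",
    "rigid_icp",
    "nonrigid_icp",
    "apply_transform",
    "save_corresponded",
    "load_corresponded",
]


@dataclasses.dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclasses.dataclass
class NonRigidParams:
    """Knobs of the non-rigid ICP.

    stiffness_schedule : strictly descending Laplacian weights; high values
        allow only near-rigid motion, low values let the template conform to
        local detail (annealing).
    inner_iterations : correspondence/solve rounds per stiffness level.
    max_corr_dist : correspondences farther than this (mm) are rejected —
        fragments displaced beyond it should not drag the template.
    max_normal_angle : reject correspondences whose surface normals disagree
        by more than this (degrees).
    smoothing_weight : global multiplier on the Laplacian prior.
    """

    stiffness_schedule: Sequence[float] = (100.0, 50.0, 20.0, 10.0, 5.0, 2.0)
    inner_iterations: int = 10
    max_corr_dist: float = 10.0
    max_normal_angle: float = 60.0
    smoothing_weight: float = 1.0
    outer_iterations: Optional[int] = None  # defaults to len(stiffness_schedule)

    def __post_init__(self):
        sched = tuple(float(s) for s in self.stiffness_schedule)
        if not sched:
            raise ValueError("stiffness_schedule must be non-empty")
        if any(b >= a for a, b in zip(sched, sched[1:])):
            raise ValueError("stiffness_schedule must be strictly descending")
        if any(s <= 0 for s in sched):
            raise ValueError("stiffness values must be positive")
        if self.max_corr_dist <= 0:
            raise ValueError("max_corr_dist must be positive")
        if self.outer_iterations is not None:
            sched = sched[: int(self.outer_iterations)]
        self.stiffness_schedule = sched


@dataclasses.dataclass
class CorrespondedShape:
    """Fixed-topology point set in template vertex order.

    ``valid_mask[i]`` is true where template vertex ``i`` found supporting
    data on the target surface.
    """

    coordinates: np.ndarray
    template_id: str = ""
    valid_mask: np.ndarray = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("corresponded coordinates must be finite")
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.coordinates), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool).reshape(-1)
        if len(self.valid_mask) != len(self.coordinates):
            raise ValueError("valid_mask length mismatch")

    @property
    def n_vertices(self) -> int:
        return len(self.coordinates)

    def flat(self) -> np.ndarray:
        return self.coordinates.reshape(-1)


# ---------------------------------------------------------------------------
# Rigid ICP
# ---------------------------------------------------------------------------

def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    cs, cd = src.mean(0), dst.mean(0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cd - R @ cs)


def rigid_icp(
    source: TriangleMesh,
    target: TriangleMesh,
    max_iters: int = 60,
    tol: float = 1e-6,
) -> RigidTransform:
    """Rigid ICP aligning ``source`` onto ``target`` (no scaling).

    Centroid initialisation, two point-to-point (Kabsch) warm-up rounds,
    then point-to-plane Gauss-Newton steps, which converge far faster on
    smooth sliding surfaces.  Stops when the update drops below ``tol``.
    """
    if source.n_vertices == 0 or target.n_vertices == 0:
        raise EmptyMeshError("rigid_icp requires non-empty meshes")
    query = SurfaceQuery(target.vertices, target.faces)
    t = RigidTransform(np.eye(3), target.vertices.mean(0) - source.vertices.mean(0))
    pts = source.vertices
    for _ in range(2):
        closest, _, _ = query.closest(t.apply(pts))
        t = _kabsch(pts, closest)
    for _ in range(max_iters):
        moved = t.apply(pts)
        closest, _, tri = query.closest(moved)
        n = query.face_normals[tri]
        r = np.einsum("ij,ij->i", moved - closest, n)
        # J_i = [ (p_i x n_i), n_i ] for the increment (omega, dt)
        J = np.hstack([np.cross(moved, n), n])
        JtJ = J.T @ J
        Jtr = J.T @ r
        try:
            x = np.linalg.solve(JtJ + 1e-12 * np.eye(6), -Jtr)
        except np.linalg.LinAlgError:
            break
        omega, dt = x[:3], x[3:]
        angle = np.linalg.norm(omega)
        if angle > 0:
            axis = omega / angle
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            dR = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        else:
            dR = np.eye(3)
        t = RigidTransform(dR, dt).compose(t)
        if angle < tol and np.linalg.norm(dt) < tol:
            break
    return t


def apply_transform(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    return TriangleMesh(t.apply(mesh.vertices), mesh.faces.copy(), mesh.name)


# ---------------------------------------------------------------------------
# Non-rigid ICP
# ---------------------------------------------------------------------------

def _graph_laplacian(n: int, edges: np.ndarray) -> sp.csr_matrix:
    """Uniform (combinatorial) graph Laplacian, degree-normalised rows."""
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.ones(len(i))
    A = sp.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    Dinv = sp.diags(1.0 / deg)
    return (sp.eye(n) - Dinv @ A).tocsr()


def nonrigid_icp(
    template: TriangleMesh,
    target: TriangleMesh,
    params: Optional[NonRigidParams] = None,
    rigid_prealign: bool = True,
    return_info: bool = False,
) -> CorrespondedShape:
    """Register ``template`` to ``target``, producing dense correspondence.

    The target is first brought into the template frame by rigid ICP (so the
    output lives in template/model space).  Then, for each stiffness level
    ``alpha``, the per-vertex displacement field ``d`` minimises

        sum_i w_i |d_i - delta_i|^2  +  alpha * |L d|^2

    where ``delta_i`` is the current closest-point offset, ``w_i`` gates
    invalid correspondences (too far, normal mismatch, or landing on an open
    target boundary) and ``L`` is the template's graph Laplacian.
    """
    if params is None:
        params = NonRigidParams()
    if target.n_vertices == 0 or target.n_faces == 0:
        raise EmptyMeshError("nonrigid_icp requires a non-empty target")

    if rigid_prealign:
        t_align = rigid_icp(target, template)
        tgt_vertices = t_align.apply(target.vertices)
    else:
        tgt_vertices = target.vertices
    query = SurfaceQuery(tgt_vertices, target.faces)
    # smoothed per-face normals (mean of the face's vertex normals): less
    # sensitive to single-triangle orientation than raw face normals
    tgt_vn = vertex_normals(tgt_vertices, target.faces)
    face_vn = tgt_vn[target.faces].mean(axis=1)
    face_vn /= np.maximum(np.linalg.norm(face_vn, axis=1, keepdims=True), 1e-300)

    X0 = template.vertices
    n = len(X0)
    L = _graph_laplacian(n, template.edges_unique()) * params.smoothing_weight
    LtL = (L.T @ L).tocsc()
    cos_limit = np.cos(np.deg2rad(params.max_normal_angle))

    d = np.zeros_like(X0)
    history = []
    solve = None
    prev_key = None
    for alpha in params.stiffness_schedule:
        level_obj = []
        for _ in range(params.inner_iterations):
            X = X0 + d
            closest, dist, tri = query.closest(X)
            vn = vertex_normals(X, template.faces)
            valid = (
                (dist <= params.max_corr_dist)
                & (np.einsum("ij,ij->i", vn, face_vn[tri]) >= cos_limit)
                & ~query.face_on_boundary[tri]
            )
            w = valid.astype(np.float64)
            delta = closest - X0
            A = (sp.diags(w) + alpha * LtL + 1e-9 * sp.eye(n)).tocsc()
            # direct factorisation is the dominant cost; refactorise only when
            # the matrix changed substantially, else reuse the last
            # factorisation as a CG preconditioner (the difference is a
            # low-rank +/-1 diagonal update, so CG converges in a few steps)
            if (
                solve is None
                or prev_key[0] != alpha
                or (valid ^ prev_key[1]).sum() > max(20, n // 20)
            ):
                solve = spla.factorized(A)
                prev_key = (alpha, valid)
                exact = True
            else:
                exact = valid is prev_key[1] or bool(np.array_equal(valid, prev_key[1]))
            rhs = w[:, None] * delta
            if exact:
                d_new = np.column_stack([solve(rhs[:, k]) for k in range(3)])
            else:
                M = spla.LinearOperator((n, n), matvec=solve)
                cols = []
                for k in range(3):
                    xk, _ = spla.cg(A, rhs[:, k], x0=d[:, k], rtol=1e-10, atol=0.0, M=M)
                    cols.append(xk)
                d_new = np.column_stack(cols)
            obj = float(
                (w * ((d_new - delta) ** 2).sum(1)).sum()
                + alpha * ((L @ d_new) ** 2).sum()
            )
            level_obj.append(obj)
            if np.abs(d_new - d).max() < 1e-6:
                d = d_new
                break
            d = d_new
        history.append(level_obj)

    X = X0 + d
    closest, dist, tri = query.closest(X)
    vn = vertex_normals(X, template.faces)
    valid = (
        (dist <= params.max_corr_dist)
        & (np.einsum("ij,ij->i", vn, face_vn[tri]) >= cos_limit)
        & ~query.face_on_boundary[tri]
    )
    shape = CorrespondedShape(X, template_id=template.name, valid_mask=valid)
    if return_info:
        return shape, {"objective_history": history, "final_distances": dist}
    return shape


def save_corresponded(shape: CorrespondedShape, path) -> None:
    """Persist a corresponded shape as a single .npz container."""
    np.savez_compressed(
        path,
        coordinates=shape.coordinates,
        valid_mask=shape.valid_mask,
        template_id=np.frombuffer(shape.template_id.encode(), dtype=np.uint8),
    )


def load_corresponded(path) -> CorrespondedShape:
    with np.load(path) as z:
        return CorrespondedShape(
            coordinates=z["coordinates"],
            valid_mask=z["valid_mask"],
            template_id=bytes(z["template_id"]).decode(),
        )
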