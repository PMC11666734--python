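"""Triangle-mesh container, standard-format I/O and preprocessing operators.

All coordinates are millimetres.  STL/PLY/OBJ files carry no unit metadata,
so readers accept a multiplicative ``units_scale`` for inputs saved in other
units.

Preprocessing mirrors what is done to CT bone segmentations before shape
modelling: isotropic remeshing to equalise vertex density, closing of open
fragment surfaces ("wrapping"), merging of fracture fragments into a single
segmentation, and sagittal mirroring so every hemipelvis is expressed as a
left side.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import trimesh as _tm

from .geometry import SurfaceQuery, vertex_normals

__all__ = [
    "TriangleMesh",
    "MeshQualityReport",
    "MeshFormatError",
    "EmptyMeshError",
    "read_mesh",
    "write_mesh",
    "remesh_isotropic",
    "make_watertight",
    "wrap_fragment",
    "merge_fragments",
    "mirror_sagittal",
    "quality_report",
    "taubin_smooth",
]

_SUPPORTED = {".stl", ".ply", ".obj"}


class MeshFormatError(RuntimeError):
    """Raised when a mesh file cannot be parsed."""


class EmptyMeshError(ValueError):
    """Raised when an operation receives or produces an empty mesh."""


@dataclasses.dataclass
class TriangleMesh:
    """A triangulated surface: vertices in mm, faces as vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh has non-finite vertex coordinates")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            if np.any(
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            ):
                raise ValueError("mesh contains degenerate faces")

    # -- basic queries -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def edges_unique(self) -> np.ndarray:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges_unique()
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def to_trimesh(self) -> _tm.Trimesh:
        return _tm.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, m: _tm.Trimesh, name: str = "") -> "TriangleMesh":
        return cls(np.asarray(m.vertices), np.asarray(m.faces), name)

    @property
    def area(self) -> float:
        tri = self.vertices[self.faces]
        return float(
            0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum()
        )

    @property
    def is_watertight(self) -> bool:
        if not len(self.faces):
            return False
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def n_connected_components(self) -> int:
        if not len(self.faces):
            return 0
        return len(self.to_trimesh().split(only_watertight=False))

    def signed_volume(self) -> float:
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    def bbox_diagonal(self) -> float:
        if not len(self.vertices):
            return 0.0
        return float(np.linalg.norm(self.vertices.max(0) - self.vertices.min(0)))


@dataclasses.dataclass
class MeshQualityReport:
    n_vertices: int
    n_faces: int
    mean_edge_length: float
    edge_length_cv: float
    is_watertight: bool
    n_connected_components: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def quality_report(mesh: TriangleMesh) -> MeshQualityReport:
    lengths = mesh.edge_lengths() if mesh.n_faces else np.array([])
    mean = float(lengths.mean()) if len(lengths) else 0.0
    cv = float(lengths.std() / mean) if mean > 0 else 0.0
    return MeshQualityReport(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        mean_edge_length=mean,
        edge_length_cv=cv,
        is_watertight=mesh.is_watertight,
        n_connected_components=mesh.n_connected_components(),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mesh(path, units_scale: float = 1.0) -> TriangleMesh:
    """Read an STL/PLY/OBJ surface; duplicate vertices are merged.

    STL stores three independent vertices per facet, so merging (tolerance
    1e-9 mm via coordinate hashing) restores shared connectivity.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _SUPPORTED:
        raise MeshFormatError(f"unsupported mesh format '{suffix}' for {path}")
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyMeshError(f"{path} is empty (0 bytes)")
    try:
        m = _tm.load_mesh(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise MeshFormatError(f"could not parse {path} as {suffix[1:]}: {exc}") from exc
    if isinstance(m, _tm.Scene):
        geoms = list(m.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"{path} contains no geometry")
        m = _tm.util.concatenate(geoms)
    verts = np.asarray(m.vertices, dtype=np.float64)
    faces = np.asarray(m.faces, dtype=np.int64)
    if len(verts) == 0 or len(faces) == 0:
        raise EmptyMeshError(f"{path} contains no triangles")
    verts, faces = _merge_duplicate_vertices(verts, faces)
    verts = verts * float(units_scale)
    return TriangleMesh(verts, faces, name=path.stem)


def _merge_duplicate_vertices(verts: np.ndarray, faces: np.ndarray, tol: float = 1e-9):
    keys = np.round(verts / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    verts = verts[first]
    faces = inverse[faces]
    keep = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    return verts, faces[keep]


def write_mesh(mesh: TriangleMesh, path, allow_point_clouds: bool = False) -> None:
    """Write a mesh in the format implied by the file extension.

    PLY is written in binary with double-precision vertices, so PLY round
    trips are exact to well below 1e-6 mm.  Binary STL stores float32 by
    format definition; its round-trip precision is limited accordingly.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED:
        raise MeshFormatError(f"unsupported mesh format '{path.suffix}'")
    if mesh.n_faces == 0 and not allow_point_clouds:
        raise EmptyMeshError("refusing to write a mesh with no faces (allow_point_clouds=False)")
    if path.suffix.lower() == ".ply":
        path.write_bytes(_export_ply_double(mesh))
    else:
        mesh.to_trimesh().export(str(path))


def _export_ply_double(mesh: TriangleMesh) -> bytes:
    """Binary little-endian PLY with float64 vertex coordinates."""
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property double x\nproperty double y\nproperty double z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\n"
        "end_header\n"
    ).encode("ascii")
    verts = np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes()
    face_rec = np.empty(
        mesh.n_faces, dtype=[("count", "<u1"), ("index", "<i4", (3,))]
    )
    face_rec["count"] = 3
    face_rec["index"] = mesh.faces
    return header + verts + face_rec.tobytes()


# ---------------------------------------------------------------------------
# Isotropic remeshing (edge split / collapse / flip + tangential relaxation)
# ---------------------------------------------------------------------------

def remesh_isotropic(mesh: TriangleMesh, target_edge: float, n_iterations: int = 4) -> TriangleMesh:
    """Remesh towards a uniform target edge length.

    Classic incremental scheme: per iteration, split edges longer than 4/3 of
    the target, collapse edges shorter than 4/5 (guarded by a manifold link
    condition), flip edges towards valence 6, then relax vertices
    tangentially and project them back onto the *original* surface.
    Deterministic: edges are processed in sorted index order.
    """
    if mesh.n_faces == 0:
        raise EmptyMeshError("cannot remesh an empty mesh")
    if target_edge <= 0:
        raise ValueError("target_edge must be positive")
    if target_edge > mesh.bbox_diagonal():
        raise ValueError("target_edge exceeds the mesh bounding-box diagonal")

    ref = SurfaceQuery(mesh.vertices, mesh.faces)
    verts = [v for v in mesh.vertices]
    faces = [tuple(f) for f in mesh.faces]
    high = 4.0 / 3.0 * target_edge
    low = 4.0 / 5.0 * target_edge

    for _ in range(n_iterations):
        verts, faces = _split_long_edges(verts, faces, high)
        verts, faces = _collapse_short_edges(verts, faces, low, high)
        faces = _flip_for_valence(verts, faces)
        verts = _relax_and_project(verts, faces, ref)

    v, f = _compact(np.asarray(verts), np.asarray(faces, dtype=np.int64))
    return TriangleMesh(v, f, name=mesh.name)


def _edge_map(faces):
    """edge (a<b) -> list of (face_index, opposite_vertex)."""
    em = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v, w in ((a, b, c), (b, c, a), (c, a, b)):
            key = (u, v) if u < v else (v, u)
            em.setdefault(key, []).append((fi, w))
    return em


def _split_long_edges(verts, faces, high):
    for _ in range(10):
        em = _edge_map(faces)
        long_edges = sorted(
            e for e in em if np.linalg.norm(verts[e[0]] - verts[e[1]]) > high
        )
        if not long_edges:
            break
        dead = set()
        new_faces = []
        for a, b in long_edges:
            adj = em[(a, b)]
            if any(fi in dead for fi, _ in adj):
                continue
            mid = len(verts)
            verts.append(0.5 * (verts[a] + verts[b]))
            for fi, w in adj:
                dead.add(fi)
                # children follow the parent's directed edge (a->b or b->a)
                if _has_directed_edge(faces[fi], a, b):
                    new_faces.append((a, mid, w))
                    new_faces.append((mid, b, w))
                else:
                    new_faces.append((b, mid, w))
                    new_faces.append((mid, a, w))
        faces = [f for fi, f in enumerate(faces) if fi not in dead] + new_faces
    return verts, faces


def _has_directed_edge(face, u, v):
    a, b, c = face
    return (a, b) == (u, v) or (b, c) == (u, v) or (c, a) == (u, v)


def _vertex_adjacency(faces, n_verts):
    adj = [set() for _ in range(n_verts)]
    for a, b, c in faces:
        adj[a].update((b, c))
        adj[b].update((a, c))
        adj[c].update((a, b))
    return adj


def _collapse_short_edges(verts, faces, low, high):
    # the touched-vertex guard freezes each collapse's neighbourhood for the
    # rest of a pass, so iterate passes until no admissible short edge remains
    for _ in range(10):
        verts, faces, changed = _collapse_pass(verts, faces, low, high)
        if not changed:
            break
    return verts, faces


def _collapse_pass(verts, faces, low, high):
    em = _edge_map(faces)
    boundary_verts = set()
    for (a, b), adj in em.items():
        if len(adj) == 1:
            boundary_verts.update((a, b))
    vadj = _vertex_adjacency(faces, len(verts))
    short = sorted(
        e for e in em if np.linalg.norm(verts[e[0]] - verts[e[1]]) < low
    )
    touched = set()
    remap = {}
    for a, b in short:
        if a in touched or b in touched or a in boundary_verts or b in boundary_verts:
            continue
        if len(em[(a, b)]) != 2:
            continue
        opposite = {w for _, w in em[(a, b)]}
        # link condition: shared neighbours must be exactly the two opposites
        if vadj[a] & vadj[b] != opposite:
            continue
        mid = 0.5 * (verts[a] + verts[b])
        # reject if the merged vertex would create an over-long edge
        nbrs = (vadj[a] | vadj[b]) - {a, b}
        if any(np.linalg.norm(mid - verts[n]) > high for n in nbrs):
            continue
        verts[a] = mid
        remap[b] = a
        touched.update({a, b} | nbrs)
    if remap:
        new_faces = []
        for f in faces:
            g = tuple(remap.get(x, x) for x in f)
            if g[0] != g[1] and g[1] != g[2] and g[0] != g[2]:
                new_faces.append(g)
        faces = new_faces
    return verts, faces, bool(remap)


def _flip_for_valence(verts, faces):
    em = _edge_map(faces)
    valence = {}
    for a, b, c in faces:
        for v in (a, b, c):
            valence[v] = valence.get(v, 0) + 1
    boundary = {v for (a, b), adj in em.items() if len(adj) == 1 for v in (a, b)}
    existing = set(em)
    dead = set()
    new_faces = []
    for (a, b) in sorted(em):
        adj = em[(a, b)]
        if len(adj) != 2 or a in boundary or b in boundary:
            continue
        (f1, c), (f2, d) = adj
        if f1 in dead or f2 in dead:
            continue
        key = (c, d) if c < d else (d, c)
        if key in existing:
            continue

        def dev(va, vb, vc, vd):
            return sum((valence.get(x, 0) - 6) ** 2 for x in (va, vb, vc, vd))

        before = dev(a, b, c, d)
        valence[a] -= 1
        valence[b] -= 1
        valence[c] = valence.get(c, 0) + 1
        valence[d] = valence.get(d, 0) + 1
        after = dev(a, b, c, d)
        if after >= before or not _flip_geometry_ok(verts, a, b, c, d):
            valence[a] += 1
            valence[b] += 1
            valence[c] -= 1
            valence[d] -= 1
            continue
        dead.update((f1, f2))
        # rebuild the two triangles around the new diagonal, keeping winding
        new_faces.append(_wind(verts, c, d, a, faces[f1], faces[f2]))
        new_faces.append(_wind(verts, d, c, b, faces[f1], faces[f2]))
        existing.add(key)
    faces = [f for fi, f in enumerate(faces) if fi not in dead] + new_faces
    return faces


def _wind(verts, u, v, w, ref1, ref2):
    """Orient triangle (u, v, w) to match the average normal of two parents."""
    def normal(f):
        p0, p1, p2 = verts[f[0]], verts[f[1]], verts[f[2]]
        return np.cross(p1 - p0, p2 - p0)

    ref = normal(ref1) + normal(ref2)
    if np.cross(verts[v] - verts[u], verts[w] - verts[u]) @ ref >= 0:
        return (u, v, w)
    return (u, w, v)


def _flip_geometry_ok(verts, a, b, c, d, min_cos=-0.5):
    """Reject flips that would produce inverted or needle triangles."""
    n1 = np.cross(verts[d] - verts[c], verts[a] - verts[c])
    n2 = np.cross(verts[c] - verts[d], verts[b] - verts[d])
    l1, l2 = np.linalg.norm(n1), np.linalg.norm(n2)
    if l1 < 1e-12 or l2 < 1e-12:
        return False
    return (n1 @ n2) / (l1 * l2) > min_cos


def _relax_and_project(verts, faces, ref: SurfaceQuery, lam: float = 0.6):
    V = np.asarray(verts)
    F = np.asarray(faces, dtype=np.int64)
    em = _edge_map(faces)
    boundary = {v for (a, b), adj in em.items() if len(adj) == 1 for v in (a, b)}
    acc = np.zeros_like(V)
    deg = np.zeros(len(V))
    for a, b in em:
        acc[a] += V[b]
        acc[b] += V[a]
        deg[a] += 1
        deg[b] += 1
    used = deg > 0
    centroid = np.where(used[:, None], acc / np.maximum(deg, 1)[:, None], V)
    normals = vertex_normals(V, F)
    delta = centroid - V
    # tangential component only, then snap back to the reference surface
    tangential = delta - normals * np.einsum("ij,ij->i", delta, normals)[:, None]
    moved = V + lam * tangential
    if boundary:
        bidx = np.fromiter(boundary, dtype=np.int64)
        moved[bidx] = V[bidx]
    projected, _, _ = ref.closest(moved)
    if boundary:
        projected[bidx] = V[bidx]
    return [p for p in projected]


def _compact(verts, faces):
    """Drop unreferenced vertices and reindex faces."""
    if len(faces) == 0:
        return verts[:0], faces
    used = np.unique(faces)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[faces]


# ---------------------------------------------------------------------------
# Watertight closing ("wrapping") and fragment handling
# ---------------------------------------------------------------------------

def make_watertight(mesh: TriangleMesh, hole_fill_max_perimeter: float = np.inf) -> TriangleMesh:
    """Close open boundary loops by centroid-fan triangulation.

    Only loops whose perimeter does not exceed ``hole_fill_max_perimeter``
    are filled; larger openings are left as-is (best effort, never raises).
    """
    if mesh.n_faces == 0:
        raise EmptyMeshError("cannot close an empty mesh")
    loops = _boundary_loops(mesh.faces)
    if not loops:
        return mesh.copy()
    verts = list(mesh.vertices)
    faces = list(map(tuple, mesh.faces))
    for loop in loops:
        pts = mesh.vertices[loop]
        perimeter = float(np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1).sum())
        if perimeter > hole_fill_max_perimeter:
            continue
        if len(loop) == 3:
            a, b, c = loop
            faces.append((a, c, b))  # reversed: boundary loop winds opposite the hole
            continue
        centre = len(verts)
        verts.append(pts.mean(axis=0))
        for i in range(len(loop)):
            a, b = loop[i], loop[(i + 1) % len(loop)]
            faces.append((b, a, centre))
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64), mesh.name)


def _boundary_loops(faces: np.ndarray):
    """Ordered open boundary loops, each a list of vertex indices.

    Boundary half-edges are traversed in their winding direction, so each
    returned loop winds opposite to the surrounding surface (suitable for
    filling with reversed orientation).
    """
    edge_count = {}
    directed = {}
    for a, b, c in faces:
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            edge_count[key] = edge_count.get(key, 0) + 1
            directed[(u, v)] = True
    boundary_next = {}
    for (u, v) in directed:
        key = (u, v) if u < v else (v, u)
        if edge_count[key] == 1:
            # the boundary half-edge is the *unpaired reverse* direction
            boundary_next[v] = u
    loops = []
    visited = set()
    for start in sorted(boundary_next):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        cur = boundary_next[start]
        while cur != start and cur not in visited:
            loop.append(cur)
            visited.add(cur)
            cur = boundary_next.get(cur)
            if cur is None:
                break
        if cur == start and len(loop) >= 3:
            loops.append(loop)
    return loops


def taubin_smooth(mesh: TriangleMesh, lam: float = 0.5, mu: float = -0.53, n_iters: int = 10) -> TriangleMesh:
    """Taubin lambda/mu smoothing (volume-preserving, unlike pure Laplacian)."""
    V = mesh.vertices.copy()
    e = mesh.edges_unique()
    n = len(V)
    for _ in range(n_iters):
        for factor in (lam, mu):
            acc = np.zeros_like(V)
            deg = np.zeros(n)
            np.add.at(acc, e[:, 0], V[e[:, 1]])
            np.add.at(acc, e[:, 1], V[e[:, 0]])
            np.add.at(deg, e[:, 0], 1)
            np.add.at(deg, e[:, 1], 1)
            used = deg > 0
            delta = np.where(used[:, None], acc / np.maximum(deg, 1)[:, None] - V, 0)
            V = V + factor * delta
    return TriangleMesh(V, mesh.faces.copy(), mesh.name)


def wrap_fragment(
    mesh: TriangleMesh,
    hole_fill_max_perimeter: float = np.inf,
    smooth_iters: int = 0,
) -> TriangleMesh:
    """Approximate segmentation wrapping: close holes, keep the largest
    connected component, optionally Taubin-smooth.

    This stands in for proprietary shrink-wrap operations in segmentation
    suites; it is a documented approximation, not an equivalent.
    """
    closed = make_watertight(mesh, hole_fill_max_perimeter)
    tm = closed.to_trimesh()
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        areas = [p.area for p in parts]
        closed = TriangleMesh.from_trimesh(parts[int(np.argmax(areas))], mesh.name)
    if smooth_iters > 0:
        closed = taubin_smooth(closed, n_iters=smooth_iters)
    return closed


def merge_fragments(fragments) -> TriangleMesh:
    """Concatenate fragment meshes into one segmentation (no welding)."""
    fragments = list(fragments)
    if not fragments:
        raise EmptyMeshError("no fragments to merge")
    if any(f.n_vertices == 0 for f in fragments):
        raise EmptyMeshError("cannot merge an empty fragment")
    verts = []
    faces = []
    offset = 0
    for f in fragments:
        verts.append(f.vertices)
        faces.append(f.faces + offset)
        offset += f.n_vertices
    name = fragments[0].name
    return TriangleMesh(np.vstack(verts), np.vstack(faces), name=name)


def mirror_sagittal(
    mesh: TriangleMesh,
    plane_normal=(1.0, 0.0, 0.0),
    plane_point=(0.0, 0.0, 0.0),
) -> TriangleMesh:
    """Reflect across a plane, reversing face winding to keep normals outward."""
    n = np.asarray(plane_normal, dtype=np.float64)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("plane normal must be non-zero")
    n = n / norm
    p0 = np.asarray(plane_point, dtype=np.float64)
    d = (mesh.vertices - p0) @ n
    verts = mesh.vertices - 2.0 * d[:, None] * n
    faces = mesh.faces[:, ::-1].copy()
    return TriangleMesh(verts, faces, name=mesh.name)
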