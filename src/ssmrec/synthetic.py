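"""Synthetic fixtures: template, training population, simulated fractures.

No patient data ships with the package.  Everything needed to exercise the
pipeline is generated here:

* a deterministic, stylised hemipelvis-like template (a bumpy anisotropic
  closed surface with a flared upper "wing", a lateral cup dent and a
  flattened medial patch) carrying 66 landmark vertices whose defining
  geometry — arc radii, circle diameter, plane tilt — is constructed
  exactly, so the clinical-parameter operators can be tested against known
  truth;
* a training population of smooth, statistically controlled deformations of
  the template (known orthogonal modes, known variances);
* simulated fractures: plane cuts, fragment deletion by surface area, and
  rigid fragment displacement, with the intact shape kept as ground truth.

The synthetic anatomy is stylised, not anatomically accurate.  Population
modes displace vertices along the template normal: variation of a bone
surface is predominantly a normal-direction effect, and purely tangential
variation is unobservable from surface geometry alone.
"""

from __future__ import annotations

import dataclasses
from typing import List, NamedTuple, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
import trimesh as _tm

from .evaluation import ClinicalParameters, LandmarkSet
from .geometry import vertex_normals
from .mesh import TriangleMesh
from .registration import CorrespondedShape

__all__ = [
    "PopulationSpec",
    "FractureSpec",
    "SyntheticTemplate",
    "PopulationSample",
    "FractureResult",
    "make_template",
    "generate_population",
    "simulate_fracture",
]


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------

class SyntheticTemplate(NamedTuple):
    mesh: TriangleMesh
    landmarks: LandmarkSet
    true_parameters: ClinicalParameters


# constructed geometry constants (mm / degrees)
_SEMI_AXES = np.array([40.0, 35.0, 45.0])
_Z_ILIOPECTINEAL, _R_ILIOPECTINEAL = 20.0, 36.0
_Z_ISCHIAL, _R_ISCHIAL = -25.0, 31.0
_Z_ACETABULAR, _R_ACETABULAR = 0.0, 37.0
_QUAD_SLOPE_DEG = 55.0
_REFERENCE_AXIS = np.array([0.0, 0.0, 1.0])


def _arc_points(z: float, radius: float, start_deg: float, span_deg: float, n: int) -> np.ndarray:
    theta = np.deg2rad(start_deg + np.linspace(0.0, span_deg, n))
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), np.full(n, z)])


def _arc_length(radius: float, span_deg: float, n: int) -> float:
    step = np.deg2rad(span_deg / (n - 1))
    return (n - 1) * 2.0 * radius * np.sin(step / 2.0)


def make_template(subdivisions: int = 3) -> SyntheticTemplate:
    """Deterministic closed template surface with 66 landmark vertices.

    ``subdivisions`` controls resolution (icosphere refinement one level
    above the argument; ``subdivisions=3`` gives 2562 vertices).  Landmark
    vertices are snapped exactly onto the constructed geometry, so the
    returned ``true_parameters`` hold to machine precision.
    """
    if subdivisions < 2:
        raise ValueError("subdivisions must be >= 2")
    ico = _tm.creation.icosphere(subdivisions=subdivisions + 1)
    U = np.asarray(ico.vertices)          # unit directions
    F = np.asarray(ico.faces)
    radial = np.ones(len(U))

    # feature bumps: fixed deterministic lobes make the surface feature-rich
    rng = np.random.default_rng(20240001)
    for _ in range(8):
        c = rng.normal(size=3)
        c /= np.linalg.norm(c)
        radial += 0.06 * np.exp(-6.0 * (1.0 - U @ c))
    # lateral cup dent (acetabulum-like)
    c_cup = np.array([0.9, 0.4, -0.45])
    c_cup /= np.linalg.norm(c_cup)
    radial -= 0.12 * np.exp(-8.0 * (1.0 - U @ c_cup))

    V = U * radial[:, None] * _SEMI_AXES
    # flared upper wing (iliac-like)
    flare = 1.0 + 0.22 / (1.0 + np.exp(-(V[:, 2] - 28.0) / 5.0))
    V[:, :2] *= flare[:, None]

    # circularise cross-sections so arcs of exact radius live on the surface
    for z0, R, w in (
        (_Z_ILIOPECTINEAL, _R_ILIOPECTINEAL, 3.0),
        (_Z_ISCHIAL, _R_ISCHIAL, 3.0),
        (_Z_ACETABULAR, _R_ACETABULAR, 4.0),
    ):
        r_xy = np.linalg.norm(V[:, :2], axis=1)
        blend = np.exp(-((V[:, 2] - z0) ** 2) / (2.0 * w * w))
        target = r_xy + blend * (R - r_xy)
        scale = np.where(r_xy > 1e-9, target / np.maximum(r_xy, 1e-9), 1.0)
        V[:, :2] *= scale[:, None]

    # flattened medial patch with a plane of known tilt (quadrilateral-like)
    # plane normal at _QUAD_SLOPE_DEG from the reference axis: the dihedral
    # angle to the axis-orthogonal plane (the reported slope) equals it
    tilt = np.deg2rad(_QUAD_SLOPE_DEG)
    n_q = np.array([-np.sin(tilt), 0.0, np.cos(tilt)])
    # place the patch where the ellipsoid's outward normal matches the plane
    # normal (normal at direction d is proportional to d / semi_axes^2), so
    # flattening barely distorts the surface and cannot fold triangles
    d_q = n_q * _SEMI_AXES**2
    d_q /= np.linalg.norm(d_q)
    # approximate surface point in direction d_q
    p_q = d_q * _SEMI_AXES * 0.98
    dist2 = ((V - p_q) ** 2).sum(axis=1)
    wgt = np.exp(-dist2 / (2.0 * 7.0**2))
    offset = (V - p_q) @ n_q
    V -= (wgt * offset)[:, None] * n_q

    # exact landmark coordinates on the constructed geometry
    ip_pts = _arc_points(_Z_ILIOPECTINEAL, _R_ILIOPECTINEAL, 30.0, 120.0, 12)
    is_pts = _arc_points(_Z_ISCHIAL, _R_ISCHIAL, 45.0, 84.0, 8)
    ac_pts = _arc_points(_Z_ACETABULAR, _R_ACETABULAR, 100.0, 180.0, 4)
    e1 = np.cross(n_q, _REFERENCE_AXIS)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n_q, e1)
    grid_u, grid_v = np.meshgrid((-3.75, -1.25, 1.25, 3.75), (-2.5, 0.0, 2.5))
    quad_pts = p_q + grid_u.reshape(-1, 1) * e1 + grid_v.reshape(-1, 1) * e2

    # dome region: vertices on a cap around an upper-lateral direction
    c_dome = np.array([0.35, 0.25, 0.9])
    c_dome /= np.linalg.norm(c_dome)
    phi = np.linspace(0.0, 4.0 * np.pi, 30)
    rr = np.linspace(2.0, 10.0, 30)
    t1 = np.cross(c_dome, np.array([1.0, 0.0, 0.0]))
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(c_dome, t1)
    dome_probe = c_dome * _SEMI_AXES + rr[:, None] * (
        np.cos(phi)[:, None] * t1 + np.sin(phi)[:, None] * t2
    )

    taken: set = set()

    def choose(points):
        idx = []
        for p in points:
            order = np.argsort(((V - p) ** 2).sum(axis=1))
            for j in order:
                if int(j) not in taken:
                    taken.add(int(j))
                    idx.append(int(j))
                    break
        return np.asarray(idx, dtype=np.int64)

    snap_targets = np.vstack([ip_pts, quad_pts, is_pts, ac_pts])
    snap_idx = np.concatenate(
        [choose(ip_pts), choose(quad_pts), choose(is_pts), choose(ac_pts)]
    )
    # carry each chosen vertex's neighbourhood smoothly toward its exact
    # target (Shepard blending, iterated), then snap exactly: the final
    # correction is tiny, so no spiky triangles appear around landmarks
    sigma = 2.0 * float(
        np.linalg.norm(V[F[:, 0]] - V[F[:, 1]], axis=1).mean()
    )
    for _ in range(4):
        residual = snap_targets - V[snap_idx]
        d2 = ((V[:, None, :] - V[snap_idx][None, :, :]) ** 2).sum(-1)
        w = np.exp(-d2 / (2.0 * sigma * sigma))
        V += (w @ residual) / (w.sum(axis=1, keepdims=True) + 1.0)
    V[snap_idx] = snap_targets

    regions = {
        "iliopectineal_line": snap_idx[:12],
        "quadrilateral_plate": snap_idx[12:24],
        "ischial_body_line": snap_idx[24:32],
        "acetabular_diameter": snap_idx[32:36],
        "weight_bearing_dome": choose(dome_probe),
    }
    mesh = TriangleMesh(V, F, name="synthetic_hemipelvis_template")
    landmarks = LandmarkSet(regions=regions, reference_axis=_REFERENCE_AXIS)
    truth = ClinicalParameters(
        iliopectineal_length=_arc_length(_R_ILIOPECTINEAL, 120.0, 12),
        iliopectineal_radius=_R_ILIOPECTINEAL,
        ischial_length=_arc_length(_R_ISCHIAL, 84.0, 8),
        ischial_radius=_R_ISCHIAL,
        acetabular_diameter=2.0 * _R_ACETABULAR,
        quadrilateral_slope=_QUAD_SLOPE_DEG,
    )
    return SyntheticTemplate(mesh, landmarks, truth)


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PopulationSpec:
    """Statistical recipe for the synthetic training cohort.

    ``mode_stddevs`` are per-mode standard deviations in mm of RMS vertex
    displacement; ``deformation_smoothness`` is the spatial wavelength (mm)
    of the band-limited deformation fields.  ``residual_stddev`` (mm RMS)
    adds an idiosyncratic smooth field to each shape — anatomy that no
    finite mode basis explains — so reconstructions degrade realistically as
    surface data goes missing; set it to 0 for an exactly low-rank cohort.
    """

    n_shapes: int = 40
    n_modes: int = 3
    mode_stddevs: Sequence[float] = (6.0, 3.0, 1.5)
    deformation_smoothness: float = 80.0
    residual_stddev: float = 1.0
    seed: int = 0

    def __post_init__(self):
        s = tuple(float(x) for x in self.mode_stddevs)
        if len(s) != self.n_modes:
            raise ValueError("mode_stddevs length must equal n_modes")
        if any(b > a for a, b in zip(s, s[1:])):
            raise ValueError("mode_stddevs must be descending")
        if self.n_shapes < self.n_modes + 1:
            raise ValueError("need n_shapes >= n_modes + 1")
        self.mode_stddevs = s


class PopulationSample(NamedTuple):
    meshes: List[TriangleMesh]
    mode_matrix: np.ndarray      # (n_modes, 3V), rows orthonormal * sqrt(V)
    coefficients: np.ndarray     # (n_shapes, n_modes) true mode scores (mm)
    true_variances: np.ndarray   # (n_modes,) PCA-scale variances (mm^2)

    def as_corresponded(self) -> List[CorrespondedShape]:
        return [
            CorrespondedShape(m.vertices.copy(), template_id=m.name)
            for m in self.meshes
        ]


def generate_population(
    template: TriangleMesh,
    spec: PopulationSpec,
    modes: Optional[np.ndarray] = None,
) -> PopulationSample:
    """Draw a population of smooth normal-direction deformations.

    Each mode is a band-limited scalar amplitude field (random low-frequency
    trigonometric features at wavelength ``deformation_smoothness``) applied
    along the template vertex normals; the flattened mode vectors are
    orthogonalised, so the population's exact covariance is known:
    ``true_variances[m] = mode_stddevs[m]^2 * V`` on the PCA (3V) scale.

    Pass ``modes`` (a previous sample's ``mode_matrix``) to draw held-out
    shapes from the *same* mode basis with fresh scores and residuals.
    """
    rng = np.random.default_rng(spec.seed)
    V = template.vertices
    nv = len(V)
    normals = vertex_normals(V, template.faces)
    k0 = 2.0 * np.pi / spec.deformation_smoothness

    if modes is None:
        fields = np.empty((spec.n_modes, 3 * nv))
        for m in range(spec.n_modes):
            g = np.zeros(nv)
            for _ in range(3):
                k = rng.normal(size=3)
                k *= k0 / np.linalg.norm(k)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                g += rng.normal() * np.sin(V @ k + phase)
            fields[m] = (g[:, None] * normals).reshape(-1)

        # orthonormalise, then scale so unit coefficient = 1 mm RMS displacement
        Q, _ = np.linalg.qr(fields.T)     # (3V, n_modes)
        modes = Q.T * np.sqrt(nv)
    else:
        modes = np.asarray(modes, dtype=np.float64)
        if modes.shape != (spec.n_modes, 3 * nv):
            raise ValueError("supplied modes do not match n_modes / template size")
    # variance-controlled draws: centre and orthogonalise the score columns,
    # then scale them, so the cohort's sample covariance over the modes is
    # exactly diag(mode_stddevs^2) — the population realises its nominal
    # statistics instead of carrying O(1/sqrt(n)) sampling error
    coeff = rng.normal(size=(spec.n_shapes, spec.n_modes))
    coeff -= coeff.mean(axis=0)
    Qc, Rc = np.linalg.qr(coeff)
    Qc *= np.sign(np.diag(Rc))  # keep each column correlated with its draw
    coeff = Qc * np.sqrt(spec.n_shapes - 1) * np.asarray(spec.mode_stddevs)
    coeff -= coeff.mean(axis=0)

    meshes = []
    for i in range(spec.n_shapes):
        disp = (coeff[i] @ modes).reshape(nv, 3)
        if spec.residual_stddev > 0:
            # per-shape idiosyncratic detail, outside the mode basis
            g = np.zeros(nv)
            for _ in range(3):
                k = rng.normal(size=3)
                k *= k0 / np.linalg.norm(k)
                g += rng.normal() * np.sin(V @ k + rng.uniform(0.0, 2.0 * np.pi))
            g *= spec.residual_stddev / max(np.sqrt((g**2).mean()), 1e-12)
            disp = disp + g[:, None] * normals
        meshes.append(
            TriangleMesh(V + disp, template.faces.copy(), name=f"synthetic_{i:03d}")
        )
    true_var = np.asarray(spec.mode_stddevs) ** 2 * nv
    return PopulationSample(meshes, modes, coeff, true_var)


# ---------------------------------------------------------------------------
# Fracture simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FractureSpec:
    """Plane-cut fracture recipe: cuts, deleted surface fraction, rigid
    per-fragment displacement bounds."""

    n_cut_planes: int = 2
    delete_fraction: float = 0.0
    displacement_mm: float = 0.0
    displacement_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.delete_fraction < 0.95):
            raise ValueError("delete_fraction must be in [0, 0.95)")
        if self.displacement_mm < 0 or self.displacement_deg < 0:
            raise ValueError("displacement bounds must be non-negative")
        if self.n_cut_planes < 1:
            raise ValueError("need at least one cut plane")


class FractureResult(NamedTuple):
    fragments: List[TriangleMesh]
    ground_truth: TriangleMesh
    achieved_delete_fraction: float


def simulate_fracture(shape: TriangleMesh, spec: FractureSpec) -> FractureResult:
    """Cut a closed shape with random planes, delete pieces totalling about
    ``delete_fraction`` of the surface area, rigidly displace the rest."""
    if not shape.is_watertight:
        raise ValueError("simulate_fracture requires a closed (watertight) shape")
    rng = np.random.default_rng(spec.seed)
    V, F = shape.vertices, shape.faces
    centroids = V[F].mean(axis=1)
    extent = V.max(0) - V.min(0)
    center = V.mean(0)

    # cell label from the sign pattern against each cut plane
    labels = np.zeros(len(F), dtype=np.int64)
    for p in range(spec.n_cut_planes):
        normal = rng.normal(size=3)
        normal /= np.linalg.norm(normal)
        point = center + rng.uniform(-0.25, 0.25, size=3) * extent
        labels |= ((centroids - point) @ normal > 0).astype(np.int64) << p

    # connected pieces within each cell via face adjacency
    tm = shape.to_trimesh()
    adj = tm.face_adjacency
    same = labels[adj[:, 0]] == labels[adj[:, 1]]
    pairs = adj[same]
    graph = sp.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(len(F), len(F))
    )
    n_pieces, piece_id = connected_components(graph, directed=False)

    tri = V[F]
    face_area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    piece_areas = np.bincount(piece_id, weights=face_area, minlength=n_pieces)
    total = piece_areas.sum()

    # greedy subset selection (largest first) toward the target deleted area
    deleted = np.zeros(n_pieces, dtype=bool)
    if spec.delete_fraction > 0:
        target = spec.delete_fraction * total
        acc = 0.0
        for pid in np.argsort(-piece_areas):
            if deleted.sum() >= n_pieces - 1:
                break
            if abs(acc + piece_areas[pid] - target) < abs(acc - target):
                deleted[pid] = True
                acc += piece_areas[pid]
    achieved = float(piece_areas[deleted].sum() / total)

    fragments = []
    for pid in range(n_pieces):
        if deleted[pid]:
            continue
        faces = F[piece_id == pid]
        used = np.unique(faces)
        remap = -np.ones(len(V), dtype=np.int64)
        remap[used] = np.arange(len(used))
        fv = V[used].copy()
        ff = remap[faces]
        if spec.displacement_mm > 0 or spec.displacement_deg > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            angle = np.deg2rad(rng.uniform(0.0, spec.displacement_deg))
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            t = rng.uniform(0.0, spec.displacement_mm) * direction
            c = fv.mean(0)
            fv = (fv - c) @ R.T + c + t
        fragments.append(TriangleMesh(fv, ff, name=f"{shape.name}_frag{pid}"))
    return FractureResult(fragments, shape.copy(), achieved)
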