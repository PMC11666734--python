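"""Reconstruction-quality metrics and clinical plate-fitting parameters.

Quality of a reconstruction is judged against the registered intact
contralateral shape: whole-surface RMSE over corresponded vertex pairs, a
per-vertex distance map, and six scalar measurements on clinically relevant
regions used when contouring fixation plates:

* iliopectineal line — length and curvature radius,
* ischial body line — length and curvature radius,
* acetabular rim — diameter of the best-fit circle,
* quadrilateral plate — inclination ("slope") of its best-fit plane
  relative to the plane orthogonal to the superior-inferior axis.

Regions are defined once as vertex indices on the template; point-to-point
correspondence transfers them to every reconstructed or contralateral shape,
so the measurements are fully automatic.  "Radius" of a bony line is defined
here as the curvature radius of the best-fit circle through its ordered
landmarks (the convention is documented, not claimed universal).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .geometry import fit_circle_3d, fit_plane
from .registration import CorrespondedShape

__all__ = [
    "EXPECTED_REGIONS",
    "LandmarkSet",
    "ClinicalParameters",
    "DistanceMap",
    "rmse",
    "distance_map",
    "polyline_length",
    "fit_circle_radius",
    "acetabular_diameter",
    "quadrilateral_slope",
    "clinical_parameters",
    "compare_parameters",
    "summarize",
    "mann_whitney_u",
]

# region name -> expected landmark count (66 in total)
EXPECTED_REGIONS = {
    "iliopectineal_line": 12,
    "quadrilateral_plate": 12,
    "ischial_body_line": 8,
    "acetabular_diameter": 4,
    "weight_bearing_dome": 30,
}


@dataclasses.dataclass
class LandmarkSet:
    """Named clinical regions as ordered template vertex-index lists."""

    regions: Dict[str, np.ndarray]
    reference_axis: np.ndarray = (0.0, 0.0, 1.0)
    template_hash: str = ""

    def __post_init__(self):
        self.regions = {k: np.asarray(v, dtype=np.int64).reshape(-1) for k, v in self.regions.items()}
        for name, count in EXPECTED_REGIONS.items():
            if name not in self.regions:
                raise ValueError(f"missing landmark region '{name}'")
            if len(self.regions[name]) != count:
                raise ValueError(
                    f"region '{name}' must have {count} landmarks, got {len(self.regions[name])}"
                )
        self.reference_axis = np.asarray(self.reference_axis, dtype=np.float64).reshape(3)
        n = np.linalg.norm(self.reference_axis)
        if n == 0:
            raise ValueError("reference_axis must be non-zero")
        self.reference_axis = self.reference_axis / n

    @property
    def all_indices(self) -> np.ndarray:
        return np.concatenate([self.regions[name] for name in EXPECTED_REGIONS])

    def validate_for(self, n_vertices: int) -> None:
        idx = self.all_indices
        if idx.min() < 0 or idx.max() >= n_vertices:
            raise ValueError("landmark index out of range for template")

    def to_json(self, path=None) -> str:
        payload = {
            "template_hash": self.template_hash,
            "reference_axis": self.reference_axis.tolist(),
            "regions": {k: v.tolist() for k, v in self.regions.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            regions=payload["regions"],
            reference_axis=payload.get("reference_axis", (0.0, 0.0, 1.0)),
            template_hash=payload.get("template_hash", ""),
        )


@dataclasses.dataclass
class ClinicalParameters:
    """The six scalar plate-fitting measurements for one shape."""

    iliopectineal_length: float
    iliopectineal_radius: float
    ischial_length: float
    ischial_radius: float
    acetabular_diameter: float
    quadrilateral_slope: float

    def as_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class DistanceMap:
    per_vertex_distance: np.ndarray
    rmse: float
    mean: float
    max: float


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def rmse(a: CorrespondedShape, b: CorrespondedShape, indices: Optional[Sequence[int]] = None) -> float:
    """Root mean square of corresponded point-pair distances (mm)."""
    if a.n_vertices != b.n_vertices:
        raise ValueError("shapes are not on the same template")
    pa, pb = a.coordinates, b.coordinates
    if indices is not None:
        indices = np.asarray(indices, dtype=np.int64)
        if len(indices) == 0:
            raise ValueError("empty index list")
        pa, pb = pa[indices], pb[indices]
    return float(np.sqrt(((pa - pb) ** 2).sum(axis=1).mean()))


def distance_map(a: CorrespondedShape, b: CorrespondedShape) -> DistanceMap:
    if a.n_vertices != b.n_vertices:
        raise ValueError("shapes are not on the same template")
    d = np.linalg.norm(a.coordinates - b.coordinates, axis=1)
    return DistanceMap(
        per_vertex_distance=d,
        rmse=float(np.sqrt((d**2).mean())),
        mean=float(d.mean()),
        max=float(d.max()),
    )


# ---------------------------------------------------------------------------
# Geometric parameters
# ---------------------------------------------------------------------------

def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 2:
        raise ValueError("polyline needs at least 2 points")
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def fit_circle_radius(points: np.ndarray) -> float:
    """Curvature radius of the best-fit 3D circle through the points."""
    return fit_circle_3d(points).radius


def acetabular_diameter(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=np.float64)
    if points.shape != (4, 3):
        raise ValueError("acetabular diameter needs exactly 4 points")
    return 2.0 * fit_circle_3d(points).radius


def quadrilateral_slope(points: np.ndarray, reference_axis: np.ndarray) -> float:
    """Angle (deg) between the landmarks' TLS plane and the plane orthogonal
    to ``reference_axis``, folded into [0, 90]."""
    points = np.asarray(points, dtype=np.float64)
    axis = np.asarray(reference_axis, dtype=np.float64).reshape(3)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("reference_axis must be non-zero")
    axis = axis / n
    centroid = points - points.mean(axis=0)
    svals = np.linalg.svd(centroid, compute_uv=False)
    if svals[1] < 1e-9 * max(svals[0], 1e-300):
        raise ValueError("landmarks are collinear; plane is degenerate")
    _, normal = fit_plane(points)
    cosang = np.clip(abs(normal @ axis), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def clinical_parameters(
    shape: CorrespondedShape,
    landmarks: LandmarkSet,
    reference_axis: Optional[np.ndarray] = None,
) -> ClinicalParameters:
    """Measure the six parameters on a corresponded shape.

    The weight-bearing dome contributes to the region RMSE only; it has no
    scalar parameter of its own.
    """
    landmarks.validate_for(shape.n_vertices)
    axis = landmarks.reference_axis if reference_axis is None else np.asarray(reference_axis)
    P = shape.coordinates
    ip = P[landmarks.regions["iliopectineal_line"]]
    isch = P[landmarks.regions["ischial_body_line"]]
    acet = P[landmarks.regions["acetabular_diameter"]]
    quad = P[landmarks.regions["quadrilateral_plate"]]
    return ClinicalParameters(
        iliopectineal_length=polyline_length(ip),
        iliopectineal_radius=fit_circle_radius(ip),
        ischial_length=polyline_length(isch),
        ischial_radius=fit_circle_radius(isch),
        acetabular_diameter=acetabular_diameter(acet),
        quadrilateral_slope=quadrilateral_slope(quad, axis),
    )


def compare_parameters(a: ClinicalParameters, b: ClinicalParameters) -> Dict[str, float]:
    """Element-wise absolute differences (mm; slope in degrees)."""
    da, db = a.as_dict(), b.as_dict()
    return {k: abs(da[k] - db[k]) for k in da}


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def summarize(values: Sequence[float]):
    """Median with IQR (25th/75th percentile, linear interpolation)."""
    values = np.asarray(list(values), dtype=np.float64)
    if len(values) == 0:
        raise ValueError("cannot summarize an empty list")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "q25": float(q25), "q75": float(q75)}


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]):
    """Mann-Whitney U test, two-sided.

    Exact null distribution when the pooled sample is small (n_a + n_b <= 12)
    and tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Returns ``(U, p)`` with U computed for ``group_a``.
    """
    a = np.asarray(list(group_a), dtype=np.float64)
    b = np.asarray(list(group_b), dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 12 and not has_ties) else "asymptotic"
    res = _stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))
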