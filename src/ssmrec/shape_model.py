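"""PCA statistical shape model (point-distribution model).

The model is built from corresponded training shapes — fixed-topology vertex
arrays sharing the template's vertex ordering — by a thin SVD of the centred
``n x 3V`` data matrix (the ``3V x 3V`` covariance is never formed).  Shapes
keep their absolute size in millimetres: no Procrustes scale normalisation,
because downstream plate-fitting measurements need true dimensions.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np

from .mesh import TriangleMesh
from .registration import CorrespondedShape

__all__ = [
    "ShapeModel",
    "ShapeCoefficients",
    "build_model",
    "project",
    "synthesize",
    "compactness",
]

DEFAULT_N_COMPONENTS = 15


@dataclasses.dataclass
class ShapeCoefficients:
    """PC scores of one shape; ``clamped`` marks scores hit by the ±3σ clamp."""

    b: np.ndarray
    clamped: np.ndarray = None

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=np.float64).reshape(-1)
        if not np.all(np.isfinite(self.b)):
            raise ValueError("coefficients must be finite")
        if self.clamped is None:
            self.clamped = np.zeros(len(self.b), dtype=bool)
        self.clamped = np.asarray(self.clamped, dtype=bool).reshape(-1)


@dataclasses.dataclass
class ShapeModel:
    """Mean shape + orthonormal PC basis with per-PC variances (mm^2).

    ``total_variance`` is the full trace of the sample covariance, so
    compactness can be reported even when only K < n-1 components are kept.
    """

    mean_shape: np.ndarray          # (3V,)
    components: np.ndarray          # (3V, K), orthonormal columns
    variances: np.ndarray           # (K,), descending
    n_training: int
    template: TriangleMesh
    total_variance: float = 0.0

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=np.float64).reshape(-1)
        self.components = np.asarray(self.components, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64).reshape(-1)
        if self.components.shape != (len(self.mean_shape), len(self.variances)):
            raise ValueError("components shape inconsistent with mean/variances")
        if np.any(np.diff(self.variances) > 1e-9):
            raise ValueError("variances must be sorted descending")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def n_vertices(self) -> int:
        return len(self.mean_shape) // 3

    def mean_mesh(self) -> TriangleMesh:
        return TriangleMesh(
            self.mean_shape.reshape(-1, 3).copy(),
            self.template.faces.copy(),
            name="mean_shape",
        )

    def instance_mesh(self, coeffs: "ShapeCoefficients") -> TriangleMesh:
        shape = synthesize(self, coeffs)
        return TriangleMesh(shape.coordinates.copy(), self.template.faces.copy(), "instance")

    # -- persistence: single .npz with a JSON metadata block ------------
    def save(self, path) -> None:
        meta = {
            "n_training": int(self.n_training),
            "n_components": int(self.n_components),
            "template_name": self.template.name,
        }
        np.savez_compressed(
            path,
            mean_shape=self.mean_shape,
            components=self.components,
            variances=self.variances,
            total_variance=np.float64(self.total_variance),
            template_vertices=self.template.vertices,
            template_faces=self.template.faces,
            metadata=np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "ShapeModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["metadata"]).decode())
            template = TriangleMesh(
                z["template_vertices"], z["template_faces"], meta.get("template_name", "")
            )
            return cls(
                mean_shape=z["mean_shape"],
                components=z["components"],
                variances=z["variances"],
                n_training=meta["n_training"],
                template=template,
                total_variance=float(z["total_variance"]),
            )


def build_model(
    shapes: Sequence[CorrespondedShape],
    n_components: int = DEFAULT_N_COMPONENTS,
    template: Optional[TriangleMesh] = None,
) -> ShapeModel:
    """Fit the PCA model to fully-observed corresponded training shapes.

    The sample covariance uses divisor ``n - 1``; components are the top-K
    eigenvectors obtained from the thin SVD of the centred data matrix.
    """
    shapes = list(shapes)
    if len(shapes) < 2:
        raise ValueError("need at least 2 training shapes")
    V = shapes[0].n_vertices
    if any(s.n_vertices != V for s in shapes):
        raise ValueError("training shapes must share the template vertex count")
    if any(not s.valid_mask.all() for s in shapes):
        raise ValueError("training shapes must be fully observed (valid_mask all true)")
    n = len(shapes)
    if n_components > n - 1:
        raise ValueError(f"n_components={n_components} exceeds n-1={n - 1}")

    X = np.stack([s.flat() for s in shapes])  # (n, 3V)
    mean = X.mean(axis=0)
    Xc = X - mean
    # thin SVD: Xc = U S Wt, covariance eigvals = S^2/(n-1), eigvecs = rows of Wt
    _, s, Wt = np.linalg.svd(Xc, full_matrices=False)
    variances_all = s**2 / (n - 1)
    components = Wt[:n_components].T
    variances = variances_all[:n_components]

    if template is None:
        raise ValueError("build_model needs the template mesh (topology): pass template=...")
    if template.n_vertices != V:
        raise ValueError("template vertex count does not match the training shapes")
    return ShapeModel(
        mean_shape=mean,
        components=components,
        variances=variances,
        n_training=n,
        template=template,
        total_variance=float(variances_all.sum()),
    )


def project(
    model: ShapeModel,
    shape: CorrespondedShape,
    mask: Optional[np.ndarray] = None,
    clamp: Optional[float] = 3.0,
) -> ShapeCoefficients:
    """Express a shape in PC scores.

    Without a mask this is the orthogonal projection ``b = C^T (x - mean)``.
    With a per-vertex mask only the observed rows enter, and ``b`` solves the
    masked least-squares problem — the mechanism by which a partially
    observed (fractured) shape constrains the full model instance.

    Scores beyond ``clamp`` standard deviations of their mode are clamped to
    the plausibility interval and flagged; pass ``clamp=None`` to disable.
    """
    x = shape.flat()
    if len(x) != len(model.mean_shape):
        raise ValueError("shape is not on the model template")
    r = x - model.mean_shape
    if mask is None:
        b = model.components.T @ r
    else:
        mask = np.asarray(mask, dtype=bool).reshape(-1)
        if len(mask) != model.n_vertices:
            raise ValueError("mask must have one entry per template vertex")
        if mask.sum() < model.n_components:
            raise ValueError(
                "masked projection underdetermined: fewer observed vertices than components"
            )
        rows = np.repeat(mask, 3)
        b, *_ = np.linalg.lstsq(model.components[rows], r[rows], rcond=None)

    clamped = np.zeros(model.n_components, dtype=bool)
    if clamp is not None:
        limit = clamp * np.sqrt(np.maximum(model.variances, 0.0))
        clamped = np.abs(b) > limit
        b = np.clip(b, -limit, limit)
    return ShapeCoefficients(b=b, clamped=clamped)


def synthesize(model: ShapeModel, coeffs: ShapeCoefficients) -> CorrespondedShape:
    """Instantiate the model: ``x = mean + C b`` (fully valid by definition)."""
    b = coeffs.b
    if len(b) != model.n_components:
        raise ValueError("coefficient length does not match the model")
    x = model.mean_shape + model.components @ b
    return CorrespondedShape(
        coordinates=x.reshape(-1, 3),
        template_id=model.template.name,
        valid_mask=np.ones(model.n_vertices, dtype=bool),
    )


def compactness(model: ShapeModel) -> np.ndarray:
    """Cumulative explained-variance fraction per retained component."""
    total = model.total_variance if model.total_variance > 0 else model.variances.sum()
    if total == 0:
        return np.ones(model.n_components)
    return np.cumsum(model.variances) / total
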