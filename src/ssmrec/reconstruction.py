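"""Reconstruct an intact hemipelvis from fractured fragment surfaces.

The fit alternates two steps, starting from the model mean:

1. non-rigid registration of the current model instance onto the merged
   fragment surface, giving template-ordered coordinates plus a validity
   mask (vertices without data support — deleted fragments, holes — are
   carried by regularisation and masked out);
2. masked least-squares projection of the valid coordinates into the PCA
   subspace, with per-mode plausibility clamping, followed by synthesis of
   the next instance.

Fragments are used where they lie; no automatic repositioning of displaced
fragments is attempted.  The correspondence gate (``max_corr_dist``) keeps
grossly displaced fragments from dragging the template instead.

The intact contralateral side, mirrored and registered to the same template,
provides the ground-truth comparator: it is returned as raw corresponded
coordinates, *not* projected into the subspace.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np

from .mesh import EmptyMeshError, TriangleMesh, mirror_sagittal
from .registration import CorrespondedShape, NonRigidParams, nonrigid_icp, rigid_icp
from .shape_model import ShapeCoefficients, ShapeModel, project, synthesize

__all__ = [
    "ReconstructionResult",
    "LowSupportWarning",
    "reconstruct_fracture",
    "reconstruct_from_contralateral",
]

#: below this fraction of supported template vertices, accuracy degrades
#: noticeably and a warning is emitted
LOW_SUPPORT_FRACTION = 0.25


class LowSupportWarning(UserWarning):
    """Raised when too little of the template finds data support."""


@dataclasses.dataclass
class ReconstructionResult:
    reconstructed: CorrespondedShape
    coefficients: ShapeCoefficients
    fraction_valid: float
    n_iterations: int
    converged: bool

    def reconstructed_mesh(self, template: TriangleMesh) -> TriangleMesh:
        return TriangleMesh(
            self.reconstructed.coordinates.copy(), template.faces.copy(), "reconstructed"
        )


def reconstruct_fracture(
    model: ShapeModel,
    fragments: TriangleMesh,
    reg_params: Optional[NonRigidParams] = None,
    max_outer: int = 5,
    tol: float = 0.1,
    clamp: Optional[float] = 3.0,
    prealign: bool = True,
) -> ReconstructionResult:
    """Fit the shape model to a merged fractured segmentation.

    ``fragments`` is the single merged fragment mesh (see
    :func:`ssmrec.mesh.merge_fragments`).  ``tol`` (mm) is the mean
    coordinate change between outer iterations below which the alternation
    is considered converged.  ``prealign`` rigidly aligns the data to the
    model frame first; disable it when the input is already expressed there.
    """
    if reg_params is None:
        reg_params = NonRigidParams()
    if fragments.n_vertices == 0 or fragments.n_faces == 0:
        raise EmptyMeshError("fragments are empty")

    if prealign:
        # bring the data into the model frame once; later passes keep it
        t_align = rigid_icp(fragments, model.mean_mesh())
        fragments = TriangleMesh(
            t_align.apply(fragments.vertices), fragments.faces, fragments.name
        )

    # re-registration passes start from an instance already close to the
    # data, so they skip the high-stiffness annealing levels
    tail = reg_params.stiffness_schedule[-3:]
    refine_params = dataclasses.replace(
        reg_params, stiffness_schedule=tail, outer_iterations=None
    )

    instance = model.mean_mesh()
    coeffs = ShapeCoefficients(np.zeros(model.n_components))
    corr = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_outer + 1):
        params_i = reg_params if n_iter == 1 else refine_params
        corr = nonrigid_icp(instance, fragments, params_i, rigid_prealign=False)
        if not corr.valid_mask.any():
            raise ValueError(
                "no template vertex found data support; fragments may be "
                "misaligned or farther than max_corr_dist"
            )
        coeffs = project(model, corr, mask=corr.valid_mask, clamp=clamp)
        new_shape = synthesize(model, coeffs)
        change = float(
            np.linalg.norm(new_shape.coordinates - instance.vertices, axis=1).mean()
        )
        instance = model.instance_mesh(coeffs)
        if change < tol:
            converged = True
            break

    fraction_valid = float(corr.valid_mask.mean())
    if fraction_valid < LOW_SUPPORT_FRACTION:
        warnings.warn(
            f"only {fraction_valid:.0%} of template vertices found data support "
            f"(< {LOW_SUPPORT_FRACTION:.0%}); reconstruction accuracy degrades "
            "with this much missing data",
            LowSupportWarning,
            stacklevel=2,
        )
    reconstructed = CorrespondedShape(
        instance.vertices.copy(),
        template_id=model.template.name,
        valid_mask=corr.valid_mask.copy(),
    )
    return ReconstructionResult(
        reconstructed=reconstructed,
        coefficients=coeffs,
        fraction_valid=fraction_valid,
        n_iterations=n_iter,
        converged=converged,
    )


def reconstruct_from_contralateral(
    model: ShapeModel,
    contralateral: TriangleMesh,
    reg_params: Optional[NonRigidParams] = None,
    mirror: bool = True,
    plane_normal=(1.0, 0.0, 0.0),
    prealign: bool = True,
) -> CorrespondedShape:
    """Register the (mirrored) intact contralateral side to the template.

    The result is raw dense correspondence — deliberately *not* projected
    into the model subspace — because it serves as the ground-truth
    comparator for the reconstruction.  ``prealign`` rigidly brings the
    mirrored mesh into the model frame first; disable it for inputs already
    expressed there.
    """
    if reg_params is None:
        reg_params = NonRigidParams()
    if contralateral.n_vertices == 0 or contralateral.n_faces == 0:
        raise EmptyMeshError("contralateral mesh is empty")
    target = mirror_sagittal(contralateral, plane_normal) if mirror else contralateral
    return nonrigid_icp(model.mean_mesh(), target, reg_params, rigid_prealign=prealign)
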