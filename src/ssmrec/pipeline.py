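"""End-to-end case and cohort orchestration.

``run_case`` executes the full workflow for one patient-equivalent case:
read fragment meshes, merge, reconstruct with the shape model, and — when an
intact contralateral mesh is available — mirror and register it as ground
truth, then evaluate whole-surface RMSE, plate-fitting region RMSE, the six
clinical parameters, and a per-vertex distance map.

``run_cohort`` maps ``run_case`` over a case table and reproduces the group
summary layout: per-group median (IQR) of every metric plus a Mann-Whitney U
test between two fracture-type groups.

Everything is deterministic for fixed inputs and configuration; reports are
serialised with sorted keys and fixed float formatting so re-runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .evaluation import (
    LandmarkSet,
    clinical_parameters,
    compare_parameters,
    distance_map,
    mann_whitney_u,
    rmse,
    summarize,
)
from .mesh import TriangleMesh, merge_fragments, read_mesh, write_mesh
from .reconstruction import (
    reconstruct_fracture,
    reconstruct_from_contralateral,
)
from .registration import NonRigidParams
from .shape_model import ShapeModel

__all__ = [
    "PipelineConfig",
    "CaseReport",
    "PipelineStageError",
    "run_case",
    "run_cohort",
]

_PARAM_KEYS = (
    "iliopectineal_length",
    "iliopectineal_radius",
    "ischial_length",
    "ischial_radius",
    "acetabular_diameter",
    "quadrilateral_slope",
)


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclasses.dataclass
class PipelineConfig:
    """Everything a case run needs besides the input meshes."""

    model: ShapeModel
    landmarks: Optional[LandmarkSet] = None
    reg_params: NonRigidParams = dataclasses.field(default_factory=NonRigidParams)
    max_outer: int = 5
    tol: float = 0.1
    prealign: bool = True
    mirror_contralateral: bool = True
    mirror_plane_normal: Sequence[float] = (1.0, 0.0, 0.0)
    units_scale: float = 1.0
    output_dir: Optional[Union[str, Path]] = None

    @classmethod
    def from_files(cls, model_path, landmarks_path=None, **kwargs) -> "PipelineConfig":
        model = ShapeModel.load(model_path)
        landmarks = LandmarkSet.from_json(landmarks_path) if landmarks_path else None
        return cls(model=model, landmarks=landmarks, **kwargs)


@dataclasses.dataclass
class CaseReport:
    """Per-case result row; RMSE fields are ``None`` without a contralateral."""

    case_id: str
    fracture_label: str = ""
    rmse_whole: Optional[float] = None
    rmse_platefit: Optional[float] = None
    parameter_differences: Optional[Dict[str, float]] = None
    fraction_valid: float = 0.0
    n_iterations: int = 0
    converged: bool = False
    warnings: List[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        # fixed float formatting for byte-stable serialisation
        for k in ("rmse_whole", "rmse_platefit", "fraction_valid"):
            if d[k] is not None:
                d[k] = round(float(d[k]), 9)
        if d["parameter_differences"] is not None:
            d["parameter_differences"] = {
                k: round(float(v), 9) for k, v in d["parameter_differences"].items()
            }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def to_row(self) -> Dict:
        row = {
            "id": self.case_id,
            "fracture_type": self.fracture_label,
            "rmse_whole_mm": self.rmse_whole,
            "rmse_platefit_mm": self.rmse_platefit,
            "fraction_valid": self.fraction_valid,
            "converged": self.converged,
        }
        diffs = self.parameter_differences or {}
        for k in _PARAM_KEYS:
            row[f"diff_{k}"] = diffs.get(k)
        return row


def _load_mesh_arg(arg, units_scale: float) -> TriangleMesh:
    if isinstance(arg, TriangleMesh):
        return arg
    return read_mesh(arg, units_scale=units_scale)


def run_case(
    fragments: Union[Sequence, TriangleMesh, str, Path],
    contralateral: Optional[Union[TriangleMesh, str, Path]] = None,
    config: Optional[PipelineConfig] = None,
    case_id: str = "case",
    fracture_label: str = "",
) -> CaseReport:
    """Run the full reconstruction workflow for one case.

    ``fragments`` may be a single mesh/path or a sequence of them (separate
    fragment files are merged).  Stage failures raise
    :class:`PipelineStageError` naming the stage.
    """
    if config is None:
        raise ValueError("run_case requires a PipelineConfig")
    model = config.model

    if isinstance(fragments, (TriangleMesh, str, Path)):
        fragments = [fragments]
    try:
        frag_meshes = [_load_mesh_arg(f, config.units_scale) for f in fragments]
    except Exception as exc:
        raise PipelineStageError("mesh_core.read_mesh", exc) from exc
    try:
        merged = merge_fragments(frag_meshes)
    except Exception as exc:
        raise PipelineStageError("mesh_core.merge_fragments", exc) from exc

    caught: List[str] = []
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            result = reconstruct_fracture(
                model,
                merged,
                config.reg_params,
                max_outer=config.max_outer,
                tol=config.tol,
                prealign=config.prealign,
            )
        caught = [str(w.message) for w in wlist]
    except Exception as exc:
        raise PipelineStageError("reconstruction.reconstruct_fracture", exc) from exc

    report = CaseReport(
        case_id=case_id,
        fracture_label=fracture_label,
        fraction_valid=result.fraction_valid,
        n_iterations=result.n_iterations,
        converged=result.converged,
        warnings=caught,
    )

    truth = None
    if contralateral is not None:
        try:
            contra = _load_mesh_arg(contralateral, config.units_scale)
        except Exception as exc:
            raise PipelineStageError("mesh_core.read_mesh", exc) from exc
        try:
            truth = reconstruct_from_contralateral(
                model,
                contra,
                config.reg_params,
                mirror=config.mirror_contralateral,
                plane_normal=config.mirror_plane_normal,
                prealign=config.prealign,
            )
        except Exception as exc:
            raise PipelineStageError(
                "reconstruction.reconstruct_from_contralateral", exc
            ) from exc
        try:
            report.rmse_whole = rmse(result.reconstructed, truth)
            if config.landmarks is not None:
                lm = config.landmarks
                report.rmse_platefit = rmse(result.reconstructed, truth, lm.all_indices)
                p_rec = clinical_parameters(result.reconstructed, lm)
                p_tru = clinical_parameters(truth, lm)
                report.parameter_differences = compare_parameters(p_rec, p_tru)
        except Exception as exc:
            raise PipelineStageError("evaluation", exc) from exc

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_outputs(out, case_id, model, result, truth, report)
    return report


def _write_outputs(out: Path, case_id: str, model, result, truth, report) -> None:
    mesh = result.reconstructed_mesh(model.template)
    write_mesh(mesh, out / f"{case_id}_reconstructed.ply")
    (out / f"{case_id}_coefficients.json").write_text(
        json.dumps(
            {
                "b": [round(float(x), 9) for x in result.coefficients.b],
                "clamped": [bool(x) for x in result.coefficients.clamped],
            },
            sort_keys=True,
            indent=2,
        )
    )
    (out / f"{case_id}_report.json").write_text(report.to_json())
    if truth is not None:
        dm = distance_map(result.reconstructed, truth)
        np.savetxt(
            out / f"{case_id}_distance_map.csv",
            dm.per_vertex_distance,
            fmt="%.9f",
            header="corresponded_distance_mm",
            comments="",
        )


def run_cohort(
    cases: Union[pd.DataFrame, Sequence[Dict]],
    config: PipelineConfig,
) -> Dict:
    """Run every case and build the group summary.

    ``cases``: records with keys ``id``, ``fracture_label``, ``fragments``
    (mesh/path or list thereof) and optional ``contralateral``.  Returns a
    dict with ``reports``, a per-case ``table`` (DataFrame), a per-group
    ``summary`` DataFrame, and ``tests`` (Mann-Whitney U between the first
    two groups, when present).
    """
    if isinstance(cases, pd.DataFrame):
        cases = cases.to_dict("records")
    cases = list(cases)
    if not cases:
        raise ValueError("empty case table")

    reports = [
        run_case(
            c["fragments"],
            c.get("contralateral"),
            config,
            case_id=str(c.get("id", f"case{i:03d}")),
            fracture_label=str(c.get("fracture_label", "")),
        )
        for i, c in enumerate(cases)
    ]
    table = pd.DataFrame([r.to_row() for r in reports])

    metrics = ["rmse_whole_mm", "rmse_platefit_mm"] + [f"diff_{k}" for k in _PARAM_KEYS]
    rows = []
    for label, grp in table.groupby("fracture_type", sort=True):
        for metric in metrics:
            vals = grp[metric].dropna()
            if len(vals):
                s = summarize(vals)
                rows.append({"fracture_type": label, "metric": metric, "n": len(vals), **s})
    summary = pd.DataFrame(rows)

    tests = {}
    labels = sorted(table["fracture_type"].unique())
    if len(labels) >= 2:
        a = table[table["fracture_type"] == labels[0]]
        b = table[table["fracture_type"] == labels[1]]
        for metric in ("rmse_whole_mm", "rmse_platefit_mm"):
            va, vb = a[metric].dropna(), b[metric].dropna()
            if len(va) and len(vb):
                u, p = mann_whitney_u(va, vb)
                tests[metric] = {"U": u, "p": p, "groups": [labels[0], labels[1]]}

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_cases.csv", index=False, float_format="%.9f")
        summary.to_csv(out / "cohort_summary.csv", index=False, float_format="%.9f")
        (out / "cohort_tests.json").write_text(json.dumps(tests, sort_keys=True, indent=2))
    return {"reports": reports, "table": table, "summary": summary, "tests": tests}
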