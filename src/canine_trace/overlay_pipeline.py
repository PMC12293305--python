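"""The two end-to-end displacement-measurement procedures.

Both procedures express the impacted canine's initial and final poses in a
common frame and report the Euclidean distance moved by two annotated
landmarks — the cusp tip and the root apex — plus monthly rates.

* **CBCT method**: needs a segmented canine model from both the initial and
  the final CBCT. The final scan is mapped onto the initial one by a rigid
  fit on stable skull points, and tip/apex distances are measured directly.

* **STL (intraoral-scan) method**: needs only the initial CBCT plus the two
  crown-only intraoral scans. Five steps: (1) segmented teeth from the
  initial CBCT, (2) CBCT teeth superimposed onto the initial scan via
  corresponding tooth points, (3) initial scan carried onto the final scan
  via stable palatal-rugae points, (4) the canine's crown overlaid onto its
  erupted crown in the final scan, (5) tip/apex measurement. The apex of the
  final canine is obtained by rigidly carrying the initial canine's
  annotated apex under the crown-alignment transform: intraoral scans image
  no roots, so this assumes the root is unchanged in shape during traction —
  a stated limitation, logged in every report.

Displacement is a plain point-to-point distance (cusp-to-cusp,
apex-to-apex); no axis decomposition is reported because none is defined by
the measurement itself.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import (
    MethodUnavailableError,
    PipelineError,
    ValidationError,
)
from .geometry_core import (
    LandmarkSet,
    RigidTransform,
    TriangleMesh,
    as_point,
    euclidean_distance,
    read_landmarks,
    read_stl,
)
from .registration import RegistrationResult, crown_align, kabsch_fit

__all__ = [
    "CanineModel",
    "CaseRecord",
    "DisplacementResult",
    "STL_ROOT_ASSUMPTION",
    "displacement_rate",
    "load_case",
    "run_cbct_method",
    "run_stl_method",
    "summarize_cases",
]

log = logging.getLogger("canine_trace.pipeline")

STL_ROOT_ASSUMPTION = (
    "apex position in the intraoral-scan method is the initial root apex "
    "carried rigidly under the crown alignment; assumes no root-shape change "
    "during traction"
)

#: Frame labels for the four acquisitions a case may contain.
FRAMES = ("cbct0", "cbctF", "stl0", "stlF")


@dataclass
class CanineModel:
    """Segmented canine mesh with its two measurement landmarks annotated."""

    mesh: TriangleMesh
    cusp_tip: np.ndarray
    apex: np.ndarray
    side: str = "right"
    impaction: str = "palatal"
    crown_vertex_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.cusp_tip = as_point(self.cusp_tip)
        self.apex = as_point(self.apex)
        if np.allclose(self.cusp_tip, self.apex):
            raise ValidationError("cusp tip and apex must be distinct points")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be left/right, got {self.side!r}")
        if self.impaction not in ("palatal", "buccal"):
            raise ValidationError(
                f"impaction must be palatal/buccal, got {self.impaction!r}"
            )
        lo, hi = self.mesh.bounds()
        for label, p in (("cusp_tip", self.cusp_tip), ("apex", self.apex)):
            if np.any(p < lo - 1.0) or np.any(p > hi + 1.0):
                raise ValidationError(
                    f"{label} {p} lies outside the mesh bounding box (+1 mm)"
                )
        if self.crown_vertex_mask is not None:
            mask = np.asarray(self.crown_vertex_mask, dtype=bool)
            if mask.shape != (self.mesh.n_vertices,):
                raise ValidationError("crown_vertex_mask length != vertex count")
            self.crown_vertex_mask = mask

    def transformed(self, t: RigidTransform) -> "CanineModel":
        return CanineModel(
            self.mesh.transformed(t),
            t.apply(self.cusp_tip),
            t.apply(self.apex),
            self.side,
            self.impaction,
            None if self.crown_vertex_mask is None else self.crown_vertex_mask.copy(),
        )


@dataclass
class CaseRecord:
    """All inputs either measurement method may need for one canine.

    ``landmarks`` is keyed by ``(role, frame)``, e.g. ``("skull", "cbct0")``:
    the same anatomical points are picked independently in each acquisition,
    so each acquisition owns its own coordinates (and picking error).
    """

    case_id: str
    initial_cbct_teeth: list[TriangleMesh]
    initial_canine: CanineModel
    initial_stl_arch: TriangleMesh
    final_stl_arch: TriangleMesh
    landmarks: dict[tuple[str, str], LandmarkSet]
    duration_months: float
    final_canine_cbct: Optional[CanineModel] = None

    def __post_init__(self):
        if self.duration_months <= 0:
            raise ValidationError(
                f"duration_months must be positive, got {self.duration_months}"
            )
        for (role, frame) in self.landmarks:
            if frame not in FRAMES:
                raise ValidationError(f"unknown acquisition frame {frame!r}")

    @property
    def has_final_cbct(self) -> bool:
        return self.final_canine_cbct is not None


@dataclass
class DisplacementResult:
    """Tip/apex displacement (mm) and monthly rates for one case and method."""

    case_id: str
    method: str
    tip_displacement: float
    apex_displacement: float
    tip_rate: float
    apex_rate: float
    duration_months: float
    registration_diagnostics: list[RegistrationResult] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.method not in ("cbct", "stl"):
            raise ValidationError(f"method must be cbct/stl, got {self.method!r}")
        if self.tip_displacement < 0 or self.apex_displacement < 0:
            raise ValidationError("displacements are distances and cannot be negative")
        for rate, disp in (
            (self.tip_rate, self.tip_displacement),
            (self.apex_rate, self.apex_displacement),
        ):
            if abs(rate * self.duration_months - disp) > 1e-9:
                raise ValidationError("rate x duration must equal displacement")


def displacement_rate(distance_mm: float, duration_months: float) -> float:
    """Displacement speed in mm/month."""
    if duration_months <= 0:
        raise ValidationError(
            f"duration must be positive months, got {duration_months}"
        )
    if distance_mm < 0:
        raise ValidationError("distance cannot be negative")
    return distance_mm / duration_months


def _get_landmarks(case: CaseRecord, role: str, frame: str, step: int) -> LandmarkSet:
    try:
        return case.landmarks[(role, frame)]
    except KeyError:
        raise PipelineError(
            f"case {case.case_id!r} is missing {role!r} landmarks in frame {frame!r}",
            step=step,
        ) from None


def run_cbct_method(case: CaseRecord) -> DisplacementResult:
    """Measure displacement by superimposing the final CBCT onto the initial one.

    The rigid fit uses paired skull points (stable cranial structures); the
    transformed final cusp tip / apex are then compared with the initial ones.
    """
    if case.final_canine_cbct is None:
        raise MethodUnavailableError(
            f"case {case.case_id!r} has no final CBCT canine model; the "
            "CBCT-to-CBCT method needs both scans"
        )
    skull0 = _get_landmarks(case, "skull", "cbct0", step=2)
    skullF = _get_landmarks(case, "skull", "cbctF", step=2)
    log.info("[%s/cbct] skull superimposition on %d points", case.case_id, len(skull0))
    fit = kabsch_fit(skullF, skull0)  # maps final frame onto initial frame
    final_in_initial = case.final_canine_cbct.transformed(fit.transform)
    tip = euclidean_distance(case.initial_canine.cusp_tip, final_in_initial.cusp_tip)
    apex = euclidean_distance(case.initial_canine.apex, final_in_initial.apex)
    log.info("[%s/cbct] tip %.3f mm, apex %.3f mm", case.case_id, tip, apex)
    return DisplacementResult(
        case_id=case.case_id,
        method="cbct",
        tip_displacement=tip,
        apex_displacement=apex,
        tip_rate=displacement_rate(tip, case.duration_months),
        apex_rate=displacement_rate(apex, case.duration_months),
        duration_months=case.duration_months,
        registration_diagnostics=[fit],
    )


def run_stl_method(case: CaseRecord, refine_crown: bool = False) -> DisplacementResult:
    """Measure displacement from the initial CBCT and the two intraoral scans.

    Step numbering in errors and logs follows the five-step protocol
    described in the module docstring.
    """
    # Step 1: segmented teeth from the initial CBCT (inputs).
    if case.initial_canine.mesh.n_faces == 0:
        raise PipelineError("initial canine model has an empty mesh", step=1)
    log.info("[%s/stl] step 1: %d segmented CBCT teeth", case.case_id,
             len(case.initial_cbct_teeth))

    # Step 2: CBCT teeth onto the initial scan, via corresponding tooth points.
    teeth_cbct = _get_landmarks(case, "tooth_correspondence", "cbct0", step=2)
    teeth_stl = _get_landmarks(case, "tooth_correspondence", "stl0", step=2)
    fit_cbct_to_stl0 = kabsch_fit(teeth_cbct, teeth_stl)
    log.info("[%s/stl] step 2: CBCT->initial scan rms %.4f mm",
             case.case_id, fit_cbct_to_stl0.rms_residual)

    # Step 3: initial scan (carrying the canine) onto the final scan, via rugae.
    rugae0 = _get_landmarks(case, "palatal_rugae", "stl0", step=3)
    rugaeF = _get_landmarks(case, "palatal_rugae", "stlF", step=3)
    fit_stl0_to_stlF = kabsch_fit(rugae0, rugaeF)
    log.info("[%s/stl] step 3: initial->final scan rms %.4f mm",
             case.case_id, fit_stl0_to_stlF.rms_residual)

    carry = fit_stl0_to_stlF.transform.compose(fit_cbct_to_stl0.transform)
    canine_in_stlF = case.initial_canine.transformed(carry)

    # Step 4: overlap the canine's crown with its erupted crown in the final scan.
    crown0 = _get_landmarks(case, "crown", "cbct0", step=4)
    crownF = _get_landmarks(case, "crown", "stlF", step=4)
    crown0_carried = crown0.transformed(carry)
    fit_crown = crown_align(
        crown0_carried, crownF, canine_in_stlF, case.final_stl_arch, refine=refine_crown
    )
    log.info("[%s/stl] step 4: crown overlay rms %.4f mm (refine=%s)",
             case.case_id, fit_crown.rms_residual, refine_crown)

    # Step 5: measurements between the initial and final canine positions,
    # both expressed in the final-scan frame.
    tip = euclidean_distance(
        canine_in_stlF.cusp_tip, fit_crown.transform.apply(canine_in_stlF.cusp_tip)
    )
    apex = euclidean_distance(
        canine_in_stlF.apex, fit_crown.transform.apply(canine_in_stlF.apex)
    )
    log.info("[%s/stl] step 5: tip %.3f mm, apex %.3f mm", case.case_id, tip, apex)
    return DisplacementResult(
        case_id=case.case_id,
        method="stl",
        tip_displacement=tip,
        apex_displacement=apex,
        tip_rate=displacement_rate(tip, case.duration_months),
        apex_rate=displacement_rate(apex, case.duration_months),
        duration_months=case.duration_months,
        registration_diagnostics=[fit_cbct_to_stl0, fit_stl0_to_stlF, fit_crown],
        notes=[STL_ROOT_ASSUMPTION],
    )


def summarize_cases(results: list[DisplacementResult]) -> pd.DataFrame:
    """Per-method descriptive table: N, mean and sample SD (n-1 denominator).

    Methods may cover different case subsets (a final CBCT is not always
    taken), so N is reported per method. With a single case the SD is
    undefined and reported as NaN.
    """
    if not results:
        raise ValidationError("summarize_cases needs at least one result")
    df = pd.DataFrame(
        {
            "case_id": [r.case_id for r in results],
            "method": [r.method for r in results],
            "tip_displacement": [r.tip_displacement for r in results],
            "apex_displacement": [r.apex_displacement for r in results],
            "tip_rate": [r.tip_rate for r in results],
            "apex_rate": [r.apex_rate for r in results],
        }
    )
    rows = []
    for method, grp in df.groupby("method", sort=False):
        row: dict[str, object] = {"method": method, "n": len(grp)}
        for col in ("tip_displacement", "apex_displacement", "tip_rate", "apex_rate"):
            row[f"{col}_mean"] = float(grp[col].mean())
            row[f"{col}_sd"] = float(grp[col].std(ddof=1)) if len(grp) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Case manifest I/O (used by the CLI): a JSON file referencing STL files and
# landmark CSVs, with paths relative to the manifest location.
# ---------------------------------------------------------------------------

_ROLE_KEYS = {
    "skull": "skull",
    "tooth_correspondence": "tooth_correspondence",
    "palatal_rugae": "palatal_rugae",
    "crown": "crown",
}


def load_case(manifest_path: str | Path) -> CaseRecord:
    """Load a case from a manifest JSON written by ``canine-trace simulate``."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    spec = json.loads(manifest_path.read_text())

    def _mesh(key: str) -> TriangleMesh:
        return read_stl(root / spec["meshes"][key])

    initial_canine = CanineModel(
        mesh=_mesh("initial_canine"),
        cusp_tip=spec["initial_canine"]["cusp_tip"],
        apex=spec["initial_canine"]["apex"],
        side=spec["initial_canine"].get("side", "right"),
        impaction=spec["initial_canine"].get("impaction", "palatal"),
    )
    final_canine = None
    if "final_canine_cbct" in spec.get("meshes", {}):
        final_canine = CanineModel(
            mesh=_mesh("final_canine_cbct"),
            cusp_tip=spec["final_canine_cbct"]["cusp_tip"],
            apex=spec["final_canine_cbct"]["apex"],
            side=spec["initial_canine"].get("side", "right"),
            impaction=spec["initial_canine"].get("impaction", "palatal"),
        )
    landmarks: dict[tuple[str, str], LandmarkSet] = {}
    for frame, csv_rel in spec["landmarks"].items():
        for role, lm_set in read_landmarks(root / csv_rel).items():
            landmarks[(role, frame)] = lm_set
    return CaseRecord(
        case_id=spec["case_id"],
        initial_cbct_teeth=[_mesh("initial_cbct_dentition")],
        initial_canine=initial_canine,
        final_canine_cbct=final_canine,
        initial_stl_arch=_mesh("initial_stl_arch"),
        final_stl_arch=_mesh("final_stl_arch"),
        landmarks=landmarks,
        duration_months=float(spec["duration_months"]),
    )


def result_to_dict(result: DisplacementResult) -> dict:
    """JSON-serialisable report for one method run, including diagnostics."""
    return {
        "case_id": result.case_id,
        "method": result.method,
        "tip_displacement_mm": result.tip_displacement,
        "apex_displacement_mm": result.apex_displacement,
        "tip_rate_mm_per_month": result.tip_rate,
        "apex_rate_mm_per_month": result.apex_rate,
        "duration_months": result.duration_months,
        "notes": result.notes,
        "registrations": [
            {
                "n_landmarks": r.n_landmarks,
                "rms_residual_mm": r.rms_residual,
                "surface_rms_mm": r.surface_rms,
                "transform_matrix_row_major": r.transform.matrix.reshape(-1).tolist(),
                "per_landmark_residuals_mm": {
                    name: res for name, res in r.per_landmark_residuals
                },
            }
            for r in result.registration_diagnostics
        ],
    }
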