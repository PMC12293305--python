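"""Seeded generator of complete synthetic traction cases with known truth.

A case emulates the data a clinic would collect for one impacted maxillary
canine: an initial CBCT segmentation (all teeth with roots, the canine in an
ectopic pose, cusp tip and apex annotated), an initial crown-only intraoral
scan lacking the permanent canine (optionally showing a deciduous canine),
a final crown-only scan with the erupted canine, stable cross-timepoint
landmarks (skull points, palatal rugae, tooth-correspondence points, crown
points), and — for a configurable subset — a final CBCT canine model.

Teeth are parametric solids (tessellated cone-on-cone about a cervical
plane), not anatomical models: the measurement pipeline is purely
rigid-geometric, so anatomical realism adds nothing testable. Crown-only
"scans" are produced by slicing at the cervical (gingival) plane, which
reproduces the roots-are-invisible property the crown-overlay step depends
on. Each acquisition (initial CBCT, final CBCT, initial scan, final scan)
lives in its own random rigid frame, so every overlay the pipeline performs
is non-trivial.

The canine's motion between timepoints is an exactly known rigid transform,
scaled so the cusp tip moves by ``tip_displacement_target`` to machine
precision; the apex displacement follows from the motion and is recorded.
All randomness flows from one seed; the same seed reproduces a case
bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .exceptions import ValidationError
from .geometry_core import (
    LandmarkSet,
    RigidTransform,
    TriangleMesh,
    write_landmarks,
    write_stl,
)
from .overlay_pipeline import CanineModel, CaseRecord

__all__ = [
    "GroundTruth",
    "SceneSpec",
    "SyntheticCase",
    "ToothMesh",
    "make_case",
    "make_cohort",
    "make_tooth",
    "transform_case",
    "write_case",
]

TOOTH_KINDS = ("incisor", "canine", "premolar", "molar")

#: (crown height, crown radius, root length) in mm per tooth kind.
_TOOTH_SIZES = {
    "incisor": (9.0, 3.5, 13.0),
    "canine": (10.0, 4.0, 16.0),
    "premolar": (7.5, 4.0, 13.0),
    "molar": (7.0, 5.5, 12.0),
}
_CROWN_TAPER = {"incisor": 0.85, "canine": 0.6, "premolar": 0.85, "molar": 0.9}


@dataclass
class ToothMesh:
    """A parametric tooth: mesh plus crown/root vertex labels and landmarks.

    Local frame: cervical plane z = 0, crown toward -z (cusp tip at
    ``-crown_height``), root toward +z (apex at ``+root_length``).
    """

    kind: str
    mesh: TriangleMesh
    crown_mask: np.ndarray
    cusp_index: int
    apex_index: int

    @property
    def cusp_tip(self) -> np.ndarray:
        return self.mesh.vertices[self.cusp_index]

    @property
    def apex(self) -> np.ndarray:
        return self.mesh.vertices[self.apex_index]


def make_tooth(
    kind: str,
    crown_height: float | None = None,
    crown_radius: float | None = None,
    root_length: float | None = None,
    n_segments: int = 12,
    n_crown_rings: int = 3,
    n_root_rings: int = 4,
) -> ToothMesh:
    """Build a watertight convex-ish tooth solid with labelled regions.

    The crown vertex set (z <= 0, including the cervical ring) and the root
    vertex set partition all vertices; exactly one cusp-tip vertex and one
    apex vertex exist.
    """
    if kind not in TOOTH_KINDS:
        raise ValidationError(f"unknown tooth kind {kind!r}")
    h, r, root_l = _TOOTH_SIZES[kind]
    h = crown_height if crown_height is not None else h
    r = crown_radius if crown_radius is not None else r
    root_l = root_length if root_length is not None else root_l
    if min(h, r, root_l) <= 0:
        raise ValidationError("tooth dimensions must be positive")
    if n_segments < 3 or n_crown_rings < 1 or n_root_rings < 1:
        raise ValidationError("tessellation too coarse (need >= 3 segments, >= 1 ring)")

    taper = _CROWN_TAPER[kind]
    theta = np.linspace(0.0, 2.0 * math.pi, n_segments, endpoint=False)
    circle = np.column_stack([np.cos(theta), 0.8 * np.sin(theta)])  # elliptical section

    rings: list[np.ndarray] = []
    # cervical ring at z = 0, then crown rings toward the cusp
    rings.append(np.column_stack([r * circle, np.zeros(n_segments)]))
    for j in range(1, n_crown_rings + 1):
        f = j / (n_crown_rings + 1)
        rad = r * (1.0 - f) ** taper
        rings.append(np.column_stack([rad * circle, np.full(n_segments, -h * f)]))
    cusp = np.array([[0.0, 0.0, -h]])
    root_rings: list[np.ndarray] = []
    for j in range(1, n_root_rings + 1):
        f = j / (n_root_rings + 1)
        rad = 0.9 * r * (1.0 - f) ** 0.9
        root_rings.append(
            np.column_stack([rad * circle, np.full(n_segments, root_l * f)])
        )
    apex = np.array([[0.0, 0.0, root_l]])

    vertices = np.vstack(rings + [cusp] + root_rings + [apex])
    cusp_index = n_segments * (n_crown_rings + 1)
    apex_index = len(vertices) - 1

    def ring_start(i: int) -> int:
        return n_segments * i

    faces: list[tuple[int, int, int]] = []

    def connect(a: int, b: int) -> None:
        # quad strip between ring starting at a and ring starting at b
        for k in range(n_segments):
            k1 = (k + 1) % n_segments
            faces.append((a + k, a + k1, b + k))
            faces.append((b + k, a + k1, b + k1))

    def fan(a: int, tip: int) -> None:
        for k in range(n_segments):
            faces.append((a + k, a + (k + 1) % n_segments, tip))

    for i in range(n_crown_rings):
        connect(ring_start(i), ring_start(i + 1))
    fan(ring_start(n_crown_rings), cusp_index)
    root_base = cusp_index + 1
    connect(ring_start(0), root_base)
    for i in range(n_root_rings - 1):
        connect(root_base + n_segments * i, root_base + n_segments * (i + 1))
    fan(root_base + n_segments * (n_root_rings - 1), apex_index)

    mesh = TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))
    crown_mask = mesh.vertices[:, 2] <= 1e-9
    return ToothMesh(kind, mesh, crown_mask, cusp_index, apex_index)


def crown_only(tooth: ToothMesh, transform: RigidTransform | None = None) -> TriangleMesh:
    """Crown part of a tooth (faces whose vertices all lie at/above the cervix)."""
    keep_face = tooth.crown_mask[tooth.mesh.faces].all(axis=1)
    used = np.unique(tooth.mesh.faces[keep_face])
    remap = np.full(tooth.mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    verts = tooth.mesh.vertices[used]
    if transform is not None:
        verts = transform.apply(verts)
    return TriangleMesh(verts, remap[tooth.mesh.faces[keep_face]])


# ---------------------------------------------------------------------------
# Scene specification and case assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic case.

    Defaults reflect a clinically plausible severe impaction: a 15 mm cusp
    path over 30 months (about 0.5 mm/month), ten skull points, six rugae
    points, and noiseless landmark picking (noise is opt-in, 0-0.5 mm).
    """

    seed: int = 0
    n_teeth: int = 14
    arch_width: float = 56.0
    arch_depth: float = 42.0
    side: str = "right"
    impaction: str = "palatal"
    tip_displacement_target: float = 15.0
    duration_months: float = 30.0
    landmark_noise_sigma: float = 0.0
    n_skull_landmarks: int = 10
    n_rugae_landmarks: int = 6
    with_final_cbct: bool = True
    include_deciduous_canine: bool = True
    canine_initial_pose: Optional[RigidTransform] = None
    tilt_range_deg: tuple[float, float] = (25.0, 45.0)

    def __post_init__(self):
        if self.landmark_noise_sigma < 0:
            raise ValidationError("landmark noise sigma must be >= 0")
        if self.tip_displacement_target < 0:
            raise ValidationError("tip displacement target must be >= 0")
        if min(self.n_skull_landmarks, self.n_rugae_landmarks) < 3:
            raise ValidationError("landmark counts must be >= 3")
        if self.n_teeth < 6:
            raise ValidationError("an arch needs at least 6 teeth")
        if min(self.arch_width, self.arch_depth) <= 0:
            raise ValidationError("arch dimensions must be positive")
        if self.duration_months <= 0:
            raise ValidationError("duration must be positive")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be left/right, got {self.side!r}")
        if self.impaction not in ("palatal", "buccal"):
            raise ValidationError("impaction must be palatal or buccal")


@dataclass
class GroundTruth:
    """Known canine motion: transform (anatomy frame) and induced distances."""

    transform: RigidTransform
    tip_displacement: float
    apex_displacement: float
    initial_cusp_tip: np.ndarray
    initial_apex: np.ndarray


@dataclass
class SyntheticCase:
    case: CaseRecord
    truth: GroundTruth
    #: per-vertex source label for the initial scan arch ("incisor_0", ...,
    #: "deciduous_canine"); ``impacted_label`` must never appear among them.
    initial_arch_vertex_labels: np.ndarray
    impacted_label: str = ""
    frames: dict[str, RigidTransform] = field(default_factory=dict)


def _rot_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)


def _random_frame(rng: np.random.Generator, max_angle_deg: float = 25.0,
                  max_shift: float = 15.0) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0.0, max_angle_deg))
    shift = rng.uniform(-max_shift, max_shift, size=3)
    return RigidTransform(_axis_angle(axis, angle), shift)


def _rotation_about(R: np.ndarray, pivot: np.ndarray,
                    extra_shift: np.ndarray) -> RigidTransform:
    return RigidTransform(R, pivot - R @ pivot + extra_shift)


def _arch_layout(spec: SceneSpec) -> list[tuple[str, np.ndarray, float]]:
    """(kind, cervical-centre position, facing angle) for each arch slot."""
    mid = (spec.n_teeth - 1) / 2.0
    a = spec.arch_width / 2.0
    b = spec.arch_depth
    phis = np.linspace(-1.2, 1.2, spec.n_teeth)
    out = []
    for i, phi in enumerate(phis):
        d = abs(i - mid)
        if d < 2.0:
            kind = "incisor"
        elif d < 3.0:
            kind = "canine"
        elif d < 5.0:
            kind = "premolar"
        else:
            kind = "molar"
        pos = np.array([a * math.sin(phi), b * math.cos(phi), 0.0])
        out.append((kind, pos, phi))
    return out


def make_case(spec: SceneSpec) -> SyntheticCase:
    """Generate one complete synthetic case, deterministic in ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    layout = _arch_layout(spec)

    canine_indices = [i for i, (kind, pos, _) in enumerate(layout)
                      if kind == "canine" and (pos[0] > 0) == (spec.side == "right")]
    if not canine_indices:
        raise ValidationError("arch layout has no canine slot on the requested side")
    ic = canine_indices[0]

    placed: list[tuple[ToothMesh, RigidTransform]] = []
    for kind, pos, phi in layout:
        tooth = make_tooth(kind)
        placed.append((tooth, RigidTransform(_rot_z(phi), pos)))

    arch_centre = np.array([0.0, spec.arch_depth * 0.45, 0.0])
    canine_tooth, socket_place = placed[ic]
    socket_pos = layout[ic][1]

    # Ectopic pose of the impacted canine relative to its socket pose.
    if spec.canine_initial_pose is not None:
        ectopic = spec.canine_initial_pose
        rng.uniform(size=3)  # keep the draw stream aligned with the default path
    else:
        tilt = math.radians(rng.uniform(*spec.tilt_range_deg))
        inward = arch_centre - socket_pos
        inward[2] = 0.0
        inward /= np.linalg.norm(inward)
        tangent = np.array([-inward[1], inward[0], 0.0])
        lateral = rng.uniform(3.0, 6.0)
        superior = rng.uniform(6.0, 10.0)
        shift = (inward if spec.impaction == "palatal" else -inward) * lateral
        shift = shift + np.array([0.0, 0.0, superior])
        ectopic = _rotation_about(_axis_angle(tangent, tilt), socket_pos, shift)

    to_initial = ectopic.compose(socket_place)  # tooth-local -> ectopic anatomy pose
    canine_mesh0 = canine_tooth.mesh.transformed(to_initial)
    tip0 = to_initial.apply(canine_tooth.cusp_tip)
    apex0 = to_initial.apply(canine_tooth.apex)
    socket_tip = socket_place.apply(canine_tooth.cusp_tip)

    # Ground-truth motion: undo the ectopic rotation about the canine's
    # centroid, then translate toward the socket; the translation magnitude
    # solves |a + s*u| = target exactly.
    if spec.tip_displacement_target == 0.0:
        motion = RigidTransform.identity()
    else:
        R = ectopic.rotation.T
        centroid = canine_mesh0.vertices.mean(axis=0)
        u = socket_tip - tip0
        un = np.linalg.norm(u)
        if un < 1e-9:
            u = np.array([0.0, 0.0, -1.0])
        else:
            u = u / un
        a_vec = R @ (tip0 - centroid) + centroid - tip0
        au = float(a_vec @ u)
        disc = au * au - float(a_vec @ a_vec) + spec.tip_displacement_target**2
        if disc < 0:
            raise ValidationError(
                "tip displacement target "
                f"{spec.tip_displacement_target} mm is smaller than the swing "
                "of the ectopic rotation; increase the target or reduce tilt"
            )
        s = -au + math.sqrt(disc)
        motion = _rotation_about(R, centroid, s * u)

    tipF = motion.apply(tip0)
    apexF = motion.apply(apex0)
    truth = GroundTruth(
        transform=motion,
        tip_displacement=float(np.linalg.norm(tipF - tip0)),
        apex_displacement=float(np.linalg.norm(apexF - apex0)),
        initial_cusp_tip=tip0,
        initial_apex=apex0,
    )

    # Stable anatomy landmarks shared by both timepoints.
    n_sk, n_ru = spec.n_skull_landmarks, spec.n_rugae_landmarks
    skull_pts = np.column_stack(
        [
            rng.uniform(-35.0, 35.0, n_sk),
            rng.uniform(-5.0, 50.0, n_sk),
            rng.uniform(15.0, 40.0, n_sk),
        ]
    )
    # Rugae lie on the anterior palatal vault: a dome rising ~10 mm from the
    # arch margins, so the point cloud has genuine 3D relief (a flat patch
    # would make the cross-arch rotation of the rugae fit ill-conditioned,
    # which the real anatomy does not).
    ru_x = rng.uniform(-12.0, 12.0, n_ru)
    ru_y = rng.uniform(18.0, 40.0, n_ru)
    ru_z = 10.0 * (1.0 - (ru_x / 12.0) ** 2) * (1.0 - ((ru_y - 29.0) / 11.0) ** 2)
    rugae_pts = np.column_stack([ru_x, ru_y, ru_z])
    erupted = [i for i in range(spec.n_teeth) if i != ic]
    tooth_pts = np.array(
        [placed[i][1].apply(placed[i][0].cusp_tip) for i in erupted]
    )
    tooth_names = [f"tooth_{i}" for i in erupted]

    n_seg = 12  # default tessellation of make_tooth
    ring1 = [n_seg + 3 * k for k in range(4)]  # first crown ring, every 3rd vertex
    crown_local = np.vstack(
        [canine_tooth.cusp_tip[None, :], canine_tooth.mesh.vertices[ring1]]
    )
    crown_pts0 = to_initial.apply(crown_local)  # on the initial canine
    crown_ptsF = motion.apply(crown_pts0)  # same material points after traction
    crown_names = ["cusp"] + [f"crown_{k}" for k in range(1, 5)]

    # Acquisition frames: each scan/volume has its own rigid coordinate frame.
    frames = {name: _random_frame(rng) for name in ("cbct0", "cbctF", "stl0", "stlF")}

    sigma = spec.landmark_noise_sigma

    def noisy(points: np.ndarray, frame: str) -> np.ndarray:
        moved = frames[frame].apply(points)
        if sigma > 0:
            moved = moved + rng.normal(0.0, sigma, moved.shape)
        return moved

    landmarks = {
        ("skull", "cbct0"): LandmarkSet(
            [f"skull_{i}" for i in range(n_sk)], noisy(skull_pts, "cbct0"), "skull"
        ),
        ("skull", "cbctF"): LandmarkSet(
            [f"skull_{i}" for i in range(n_sk)], noisy(skull_pts, "cbctF"), "skull"
        ),
        ("tooth_correspondence", "cbct0"): LandmarkSet(
            tooth_names, noisy(tooth_pts, "cbct0"), "tooth_correspondence"
        ),
        ("tooth_correspondence", "stl0"): LandmarkSet(
            tooth_names, noisy(tooth_pts, "stl0"), "tooth_correspondence"
        ),
        ("palatal_rugae", "stl0"): LandmarkSet(
            [f"ruga_{i}" for i in range(n_ru)], noisy(rugae_pts, "stl0"),
            "palatal_rugae",
        ),
        ("palatal_rugae", "stlF"): LandmarkSet(
            [f"ruga_{i}" for i in range(n_ru)], noisy(rugae_pts, "stlF"),
            "palatal_rugae",
        ),
        ("crown", "cbct0"): LandmarkSet(crown_names, noisy(crown_pts0, "cbct0"),
                                        "crown"),
        ("crown", "stlF"): LandmarkSet(crown_names, noisy(crown_ptsF, "stlF"),
                                       "crown"),
    }

    # Initial CBCT: full (crown+root) meshes of erupted teeth, canine separate.
    f0 = frames["cbct0"]
    initial_cbct_teeth = [
        placed[i][0].mesh.transformed(f0.compose(placed[i][1])) for i in erupted
    ]
    initial_canine = CanineModel(
        mesh=canine_mesh0.transformed(f0),
        cusp_tip=f0.apply(tip0),
        apex=f0.apply(apex0),
        side=spec.side,
        impaction=spec.impaction,
        crown_vertex_mask=canine_tooth.crown_mask.copy(),
    )
    final_canine_cbct = None
    if spec.with_final_cbct:
        fF = frames["cbctF"]
        final_anatomy = canine_mesh0.transformed(motion)
        final_canine_cbct = CanineModel(
            mesh=final_anatomy.transformed(fF),
            cusp_tip=fF.apply(tipF),
            apex=fF.apply(apexF),
            side=spec.side,
            impaction=spec.impaction,
            crown_vertex_mask=canine_tooth.crown_mask.copy(),
        )

    # Initial scan: erupted crowns only; the impacted canine is invisible.
    stl0_parts: list[TriangleMesh] = []
    stl0_labels: list[np.ndarray] = []
    for i in erupted:
        part = crown_only(placed[i][0], frames["stl0"].compose(placed[i][1]))
        stl0_parts.append(part)
        stl0_labels.append(
            np.full(part.n_vertices, f"{layout[i][0]}_{i}", dtype=object)
        )
    if spec.include_deciduous_canine:
        deciduous = make_tooth("canine", crown_height=7.0, crown_radius=3.2,
                               root_length=8.0)
        part = crown_only(deciduous, frames["stl0"].compose(socket_place))
        stl0_parts.append(part)
        stl0_labels.append(np.full(part.n_vertices, "deciduous_canine", dtype=object))
    initial_stl_arch = TriangleMesh.concatenate(stl0_parts)
    initial_labels = np.concatenate(stl0_labels)

    # Final scan: erupted crowns plus the canine crown at its final pose.
    stlF_parts = [
        crown_only(placed[i][0], frames["stlF"].compose(placed[i][1]))
        for i in erupted
    ]
    canine_final_pose = frames["stlF"].compose(motion.compose(to_initial))
    stlF_parts.append(crown_only(canine_tooth, canine_final_pose))
    final_stl_arch = TriangleMesh.concatenate(stlF_parts)

    case = CaseRecord(
        case_id=f"synthetic_{spec.seed}",
        initial_cbct_teeth=initial_cbct_teeth,
        initial_canine=initial_canine,
        final_canine_cbct=final_canine_cbct,
        initial_stl_arch=initial_stl_arch,
        final_stl_arch=final_stl_arch,
        landmarks=landmarks,
        duration_months=spec.duration_months,
    )
    return SyntheticCase(case, truth, initial_labels, f"canine_{ic}", frames)


def make_cohort(
    n_cases: int = 13,
    seed: int = 0,
    template: SceneSpec | None = None,
    final_cbct_fraction: float = 8.0 / 13.0,
    tip_range: tuple[float, float] = (11.0, 19.0),
    duration_range: tuple[float, float] = (24.0, 41.0),
    palatal_fraction: float = 9.0 / 13.0,
) -> list[SyntheticCase]:
    """Generate a cohort of seeded cases.

    Displacement targets and durations are drawn uniformly from stated
    ranges bracketing a severe-impaction clinic population (cusp paths of
    11-19 mm over 24-41 months); a fixed number of cases — round(fraction x
    n), by default 8 of 13 — carries a final CBCT, and impaction sides are
    drawn with a 9:13 palatal proportion. Everything is derived from
    ``seed``.
    """
    if n_cases < 1:
        raise ValidationError("cohort needs at least one case")
    template = template or SceneSpec()
    rng = np.random.default_rng(seed)
    n_final = int(round(final_cbct_fraction * n_cases))
    with_final = np.zeros(n_cases, dtype=bool)
    with_final[rng.choice(n_cases, size=n_final, replace=False)] = True
    cohort = []
    for i in range(n_cases):
        spec = dataclasses.replace(
            template,
            seed=int(rng.integers(0, 2**31 - 1)),
            tip_displacement_target=float(rng.uniform(*tip_range)),
            duration_months=float(rng.uniform(*duration_range)),
            impaction="palatal" if rng.uniform() < palatal_fraction else "buccal",
            side="right" if rng.uniform() < 0.5 else "left",
            with_final_cbct=bool(with_final[i]),
        )
        sc = make_case(spec)
        sc.case.case_id = f"case_{i + 1:02d}"
        cohort.append(sc)
    return cohort


def transform_case(case: CaseRecord, g: RigidTransform) -> CaseRecord:
    """Apply one global rigid motion to every input of a case.

    Useful for frame-invariance checks: all reported quantities are
    distances and must not change.
    """
    return CaseRecord(
        case_id=case.case_id,
        initial_cbct_teeth=[m.transformed(g) for m in case.initial_cbct_teeth],
        initial_canine=case.initial_canine.transformed(g),
        final_canine_cbct=(
            None if case.final_canine_cbct is None
            else case.final_canine_cbct.transformed(g)
        ),
        initial_stl_arch=case.initial_stl_arch.transformed(g),
        final_stl_arch=case.final_stl_arch.transformed(g),
        landmarks={k: v.transformed(g) for k, v in case.landmarks.items()},
        duration_months=case.duration_months,
    )


def write_case(sc: SyntheticCase, outdir: str | Path, dialect: str = "binary") -> Path:
    """Write a case to disk: STL meshes, landmark CSVs per acquisition frame,
    a ``case.json`` manifest the pipeline can load, and a separate
    ``truth.json`` (ground truth for tests only — not a pipeline input).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    case = sc.case

    meshes = {
        "initial_cbct_dentition": TriangleMesh.concatenate(case.initial_cbct_teeth),
        "initial_canine": case.initial_canine.mesh,
        "initial_stl_arch": case.initial_stl_arch,
        "final_stl_arch": case.final_stl_arch,
    }
    if case.final_canine_cbct is not None:
        meshes["final_canine_cbct"] = case.final_canine_cbct.mesh
    mesh_paths = {}
    for name, mesh in meshes.items():
        write_stl(mesh, outdir / f"{name}.stl", dialect=dialect)
        mesh_paths[name] = f"{name}.stl"

    frames = sorted({frame for (_, frame) in case.landmarks})
    lm_paths = {}
    for frame in frames:
        sets = [v for (role, fr), v in case.landmarks.items() if fr == frame]
        write_landmarks(sets, outdir / f"landmarks_{frame}.csv")
        lm_paths[frame] = f"landmarks_{frame}.csv"

    manifest = {
        "case_id": case.case_id,
        "duration_months": case.duration_months,
        "meshes": mesh_paths,
        "landmarks": lm_paths,
        "initial_canine": {
            "cusp_tip": case.initial_canine.cusp_tip.tolist(),
            "apex": case.initial_canine.apex.tolist(),
            "side": case.initial_canine.side,
            "impaction": case.initial_canine.impaction,
        },
    }
    if case.final_canine_cbct is not None:
        manifest["final_canine_cbct"] = {
            "cusp_tip": case.final_canine_cbct.cusp_tip.tolist(),
            "apex": case.final_canine_cbct.apex.tolist(),
        }
    (outdir / "case.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "tip_displacement_mm": sc.truth.tip_displacement,
                "apex_displacement_mm": sc.truth.apex_displacement,
                "motion_matrix_row_major": sc.truth.transform.matrix.reshape(-1).tolist(),
            },
            indent=2,
        )
    )
    return outdir / "case.json"
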