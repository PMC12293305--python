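"""Landmark-based rigid superimposition (Kabsch) and trimmed-ICP refinement.

Every overlay step of both measurement methods reduces to the same
least-squares problem: given paired points ``s_i -> t_i``, find the proper
rotation R and translation t minimising sum ||R s_i + t - t_i||^2. The
closed-form SVD solution is used, with the determinant correction so that
a reflection is never returned (same patient, same chirality). No scale
factor is fitted: scale is identically 1 for same-patient data, and fitting
one would mask calibration errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import (
    ConvergenceWarning,
    CorrespondenceError,
    DegenerateConfigurationError,
    InsufficientLandmarksError,
    RegistrationWarning,
)
from .geometry_core import LandmarkSet, RigidTransform, TriangleMesh

__all__ = [
    "RegistrationResult",
    "crown_align",
    "kabsch_fit",
    "reflection_guard",
    "trimmed_icp",
]

#: Recommended minimum number of skull points for a CBCT-to-CBCT overlay.
RECOMMENDED_SKULL_LANDMARKS = 10

_COLLINEAR_RTOL = 1e-8


@dataclass
class RegistrationResult:
    """Outcome of a rigid fit.

    ``rms_residual`` is the root-mean-square of ``per_landmark_residuals``;
    ``surface_rms`` is populated only when an ICP refinement pass ran, and is
    the RMS of the trimmed closest-point distances at the last iterate.
    """

    transform: RigidTransform
    rms_residual: float
    per_landmark_residuals: list[tuple[str, float]]
    n_landmarks: int
    surface_rms: float | None = None
    n_iterations: int = 0

    def __post_init__(self):
        if self.n_landmarks < 3:
            raise InsufficientLandmarksError(
                f"registration result with {self.n_landmarks} landmarks"
            )
        res = np.array([r for _, r in self.per_landmark_residuals])
        if res.size and abs(self.rms_residual - float(np.sqrt(np.mean(res**2)))) > 1e-12:
            raise ValueError("rms_residual inconsistent with per-landmark residuals")


def reflection_guard(u: np.ndarray, s: np.ndarray, vt: np.ndarray) -> np.ndarray:
    """Proper rotation from the SVD factors of the 3x3 cross-covariance.

    When ``det(V @ U^T) = -1`` the naive product would be a reflection; the
    axis of the smallest singular value is flipped instead (standard Kabsch
    correction), giving the best proper rotation.
    """
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:  # fully degenerate covariance; pick +1 branch
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    return vt.T @ D @ u.T


def _fit_rigid(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid fit on already-paired coordinates."""
    src_c = source.mean(axis=0)
    tgt_c = target.mean(axis=0)
    H = (source - src_c).T @ (target - tgt_c)
    u, s, vt = np.linalg.svd(H)
    R = reflection_guard(u, s, vt)
    return RigidTransform(R, tgt_c - R @ src_c)


def _check_not_collinear(points: np.ndarray, label: str) -> None:
    centred = points - points.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[1] <= _COLLINEAR_RTOL * scale:
        raise DegenerateConfigurationError(
            f"{label} landmarks are collinear; rotation about their axis is "
            "under-determined"
        )


def kabsch_fit(source: LandmarkSet, target: LandmarkSet) -> RegistrationResult:
    """Least-squares rigid superimposition of ``source`` onto ``target``.

    The sets must be paired: identical name sequences, so every
    correspondence is explicit and auditable. At least 3 non-collinear
    landmarks are required. A :class:`RegistrationWarning` is emitted when a
    skull-role overlay uses fewer than ten points, the recommended minimum
    for a cranial-base superimposition.
    """
    if len(source) < 3 or len(target) < 3:
        raise InsufficientLandmarksError(
            f"rigid fit needs >= 3 landmarks, got {len(source)} and {len(target)}"
        )
    if not source.is_paired_with(target):
        raise CorrespondenceError(
            "landmark sets are not paired: name sequences differ "
            f"({source.names[:4]}... vs {target.names[:4]}...)"
        )
    _check_not_collinear(source.points, "source")
    _check_not_collinear(target.points, "target")
    if "skull" in (source.role, target.role) and len(source) < RECOMMENDED_SKULL_LANDMARKS:
        warnings.warn(
            f"skull superimposition with {len(source)} landmarks; at least "
            f"{RECOMMENDED_SKULL_LANDMARKS} are recommended",
            RegistrationWarning,
            stacklevel=2,
        )
    transform = _fit_rigid(source.points, target.points)
    residuals = np.linalg.norm(transform.apply(source.points) - target.points, axis=1)
    return RegistrationResult(
        transform=transform,
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
        per_landmark_residuals=list(zip(source.names, residuals.tolist())),
        n_landmarks=len(source),
    )


def trimmed_icp(
    source_points: np.ndarray,
    target_points: np.ndarray,
    init: RigidTransform,
    trim_fraction: float = 0.8,
    max_iterations: int = 50,
    tolerance: float = 1e-6,
) -> tuple[RigidTransform, float, int]:
    """Point-to-point trimmed ICP starting from ``init``.

    Each iteration matches every source point to its nearest target point,
    keeps the best ``trim_fraction`` of matches (by distance), and re-solves
    the rigid fit on the kept pairs. Stops when the trimmed RMS improves by
    less than ``tolerance`` mm, or at ``max_iterations`` (with a
    :class:`ConvergenceWarning`; the last iterate is returned).

    Returns ``(transform, trimmed_rms, n_iterations)``.
    """
    tree = cKDTree(np.asarray(target_points, dtype=np.float64))
    src = np.asarray(source_points, dtype=np.float64)
    transform = init
    n_keep = max(3, int(np.ceil(trim_fraction * len(src))))
    prev_rms = np.inf
    rms = np.inf
    it = 0
    for it in range(1, max_iterations + 1):
        moved = transform.apply(src)
        dist, idx = tree.query(moved)
        keep = np.argsort(dist)[:n_keep]
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        if prev_rms - rms < tolerance:
            return transform, rms, it
        prev_rms = rms
        transform = _fit_rigid(src[keep], target_points[idx[keep]])
    warnings.warn(
        f"trimmed ICP did not converge in {max_iterations} iterations "
        f"(last trimmed RMS {rms:.3g} mm)",
        ConvergenceWarning,
        stacklevel=2,
    )
    return transform, rms, it


def _crown_vertices(canine) -> np.ndarray:
    """Crown-region vertices of a canine model.

    Uses the explicit crown mask when the model carries one; otherwise takes
    vertices in the cusp-side 45% of the apex-to-cusp axis.
    """
    mesh = canine.mesh
    mask = getattr(canine, "crown_vertex_mask", None)
    if mask is not None:
        return mesh.vertices[np.asarray(mask, dtype=bool)]
    axis = np.asarray(canine.cusp_tip) - np.asarray(canine.apex)
    axis = axis / np.linalg.norm(axis)
    proj = (mesh.vertices - np.asarray(canine.apex)) @ axis
    return mesh.vertices[proj >= 0.55 * proj.max()]


def crown_align(
    initial_crown_landmarks: LandmarkSet,
    final_crown_landmarks: LandmarkSet,
    initial_canine,
    final_crown_mesh: TriangleMesh,
    refine: bool = False,
) -> RegistrationResult:
    """Overlay the initial canine's crown onto its final crown position.

    The landmark fit (cusp tip plus other crown points, paired by name) is
    the reference behaviour. With ``refine=True`` a trimmed ICP pass over
    crown-region vertices polishes the surface agreement, starting from the
    landmark fit — the final arch scan has no roots, so only the crown can
    constrain this transform.
    """
    result = kabsch_fit(initial_crown_landmarks, final_crown_landmarks)
    if not refine:
        return result
    crown_pts = _crown_vertices(initial_canine)
    transform, surface_rms, n_iter = trimmed_icp(
        crown_pts, final_crown_mesh.vertices, init=result.transform
    )
    residuals = np.linalg.norm(
        transform.apply(initial_crown_landmarks.points) - final_crown_landmarks.points,
        axis=1,
    )
    return RegistrationResult(
        transform=transform,
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
        per_landmark_residuals=list(
            zip(initial_crown_landmarks.names, residuals.tolist())
        ),
        n_landmarks=len(initial_crown_landmarks),
        surface_rms=surface_rms,
        n_iterations=n_iter,
    )
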