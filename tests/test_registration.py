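import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from canine_trace.exceptions import (
    CorrespondenceError,
    DegenerateConfigurationError,
    InsufficientLandmarksError,
    RegistrationWarning,
)
from canine_trace.geometry_core import LandmarkSet, RigidTransform
from canine_trace.registration import crown_align, kabsch_fit, reflection_guard
from canine_trace.synthetic_data import SceneSpec, make_case

from conftest import random_rigid


def lm(points, role="tooth_correspondence", names=None):
    points = np.asarray(points, dtype=float)
    names = names or [f"p{i}" for i in range(len(points))]
    return LandmarkSet(names, points, role)


TETRA = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], dtype=float)


def brute_force_objective(source, target):
    """Independent oracle: minimise the rigid-fit objective over rotations by
    quaternion grid search plus local refinement (no SVD involved)."""
    src = source - source.mean(axis=0)
    tgt = target - target.mean(axis=0)

    def objective(R):
        return float(np.sum((src @ R.T - tgt) ** 2))

    grid = Rotation.random(20_000, rng=np.random.default_rng(99))
    values = [objective(r.as_matrix()) for r in grid]
    best = grid[int(np.argmin(values))].as_rotvec()
    res = minimize(
        lambda v: objective(Rotation.from_rotvec(v).as_matrix()),
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
    )
    return float(res.fun)


class TestKabschFit:
    def test_source_equals_target_gives_identity(self):
        res = kabsch_fit(lm(TETRA), lm(TETRA))
        assert res.transform.almost_equals(RigidTransform.identity(), 1e-12)
        assert res.rms_residual < 1e-12

    def test_pure_translation_recovered(self):
        shift = np.array([5.0, -2.0, 7.0])
        res = kabsch_fit(lm(TETRA), lm(TETRA + shift))
        assert np.abs(res.transform.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(res.transform.translation - shift).max() < 1e-12
        assert res.rms_residual < 1e-12

    @pytest.mark.parametrize("seed", range(25))
    def test_random_rigid_motion_recovered_exactly(self, seed):
        rng = np.random.default_rng(seed)
        truth = random_rigid(rng)
        pts = rng.uniform(-30, 30, size=(10, 3))
        res = kabsch_fit(lm(pts), lm(truth.apply(pts)))
        assert res.rms_residual < 1e-9
        assert np.abs(res.transform.rotation - truth.rotation).max() < 1e-9
        assert np.abs(res.transform.translation - truth.translation).max() < 1e-9

    def test_noisy_fit_bounded_by_noise_model(self):
        rng = np.random.default_rng(42)
        truth = random_rigid(rng)
        pts = rng.uniform(-30, 30, size=(10, 3))
        noisy_target = truth.apply(pts) + rng.normal(0, 0.2, (10, 3))
        res = kabsch_fit(lm(pts), lm(noisy_target))
        assert 0.0 < res.rms_residual < 0.5
        assert np.abs(res.transform.translation - truth.translation).max() < 0.3

    def test_rms_matches_per_landmark_residuals(self, rng):
        truth = random_rigid(rng)
        pts = rng.uniform(-30, 30, size=(8, 3))
        res = kabsch_fit(lm(pts), lm(truth.apply(pts) + rng.normal(0, 0.1, (8, 3))))
        manual = np.sqrt(np.mean([r**2 for _, r in res.per_landmark_residuals]))
        assert res.rms_residual == pytest.approx(manual, abs=1e-12)

    def test_left_invariance_of_residual(self, rng):
        g = random_rigid(rng)
        truth = random_rigid(rng)
        pts = rng.uniform(-30, 30, size=(9, 3))
        tgt = truth.apply(pts) + rng.normal(0, 0.15, (9, 3))
        base = kabsch_fit(lm(pts), lm(tgt)).rms_residual
        moved = kabsch_fit(lm(g.apply(pts)), lm(g.apply(tgt))).rms_residual
        assert abs(base - moved) < 1e-9

    @pytest.mark.parametrize("n_points", [4, 5])
    def test_objective_matches_brute_force_oracle(self, n_points):
        rng = np.random.default_rng(n_points)
        pts = rng.uniform(-20, 20, size=(n_points, 3))
        tgt = random_rigid(rng).apply(pts) + rng.normal(0, 0.5, (n_points, 3))
        res = kabsch_fit(lm(pts), lm(tgt))
        kabsch_obj = np.sum(
            (res.transform.apply(pts) - tgt) ** 2
        )
        oracle = brute_force_objective(pts, tgt)
        assert kabsch_obj <= oracle + 1e-9
        assert kabsch_obj == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self, rng):
        pts = rng.uniform(-20, 20, size=(7, 3))
        tgt = random_rigid(rng).apply(pts) + rng.normal(0, 0.3, (7, 3))
        res = kabsch_fit(lm(pts), lm(tgt))
        rot, _ = Rotation.align_vectors(
            tgt - tgt.mean(axis=0), pts - pts.mean(axis=0)
        )
        assert np.abs(res.transform.rotation - rot.as_matrix()).max() < 1e-8

    def test_too_few_landmarks(self):
        with pytest.raises(InsufficientLandmarksError):
            kabsch_fit(lm(TETRA[:2]), lm(TETRA[:2]))

    def test_collinear_landmarks(self):
        line = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [3, 3, 3]], dtype=float)
        with pytest.raises(DegenerateConfigurationError):
            kabsch_fit(lm(line), lm(line))

    def test_name_mismatch(self):
        with pytest.raises(CorrespondenceError):
            kabsch_fit(
                lm(TETRA, names=["a", "b", "c", "d"]),
                lm(TETRA, names=["a", "b", "d", "c"]),
            )

    def test_skull_fit_below_ten_points_warns(self):
        src = lm(TETRA, role="skull", names=list("abcd"))
        tgt = lm(TETRA + 1.0, role="skull", names=list("abcd"))
        with pytest.warns(RegistrationWarning):
            kabsch_fit(src, tgt)

    def test_ten_skull_points_do_not_warn(self, rng, recwarn):
        pts = rng.uniform(-30, 30, size=(10, 3))
        kabsch_fit(lm(pts, role="skull"), lm(pts + 2.0, role="skull"))
        assert not [w for w in recwarn if issubclass(w.category, RegistrationWarning)]


class TestReflectionGuard:
    def test_mirror_target_yields_proper_rotation(self):
        mirrored = TETRA * np.array([-1.0, 1.0, 1.0])
        res = kabsch_fit(lm(TETRA), lm(mirrored))
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rms_residual > 0.1  # a reflection is inexpressible rigidly

    def test_well_posed_case_matches_naive_product(self, rng):
        truth = random_rigid(rng)
        pts = rng.uniform(-20, 20, size=(6, 3))
        tgt = truth.apply(pts)
        H = (pts - pts.mean(0)).T @ (tgt - tgt.mean(0))
        u, s, vt = np.linalg.svd(H)
        naive = vt.T @ u.T
        assert np.linalg.det(naive) > 0  # well-posed: guard must not alter it
        assert np.abs(reflection_guard(u, s, vt) - naive).max() < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_near_planar_sets_stay_proper(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-20, 20, size=(8, 3))
        pts[:, 2] = rng.normal(0, 1e-4, 8)  # planar plus jitter
        tgt = random_rigid(rng).apply(pts) + rng.normal(0, 0.05, (8, 3))
        res = kabsch_fit(lm(pts), lm(tgt))
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)


class TestCrownAlign:
    def test_refine_off_equals_landmark_fit(self, noiseless_case):
        case = noiseless_case.case
        crown0 = case.landmarks[("crown", "cbct0")]
        crownF = case.landmarks[("crown", "stlF")]
        a = crown_align(
            crown0, crownF, case.initial_canine, case.final_stl_arch, refine=False
        )
        b = kabsch_fit(crown0, crownF)
        assert a.transform.almost_equals(b.transform, 1e-12)
        assert a.rms_residual == b.rms_residual

    def test_exact_landmarks_recover_generating_motion(self, rng):
        sc = make_case(SceneSpec(seed=21))
        case = sc.case
        # carry the canine into the final-scan frame exactly as the pipeline does
        from canine_trace.registration import kabsch_fit as kf

        t1 = kf(
            case.landmarks[("tooth_correspondence", "cbct0")],
            case.landmarks[("tooth_correspondence", "stl0")],
        ).transform
        t3 = kf(
            case.landmarks[("palatal_rugae", "stl0")],
            case.landmarks[("palatal_rugae", "stlF")],
        ).transform
        carry = t3.compose(t1)
        res = crown_align(
            case.landmarks[("crown", "cbct0")].transformed(carry),
            case.landmarks[("crown", "stlF")],
            case.initial_canine.transformed(carry),
            case.final_stl_arch,
            refine=False,
        )
        assert res.rms_residual < 1e-9

    def test_refinement_does_not_worsen_surface_fit(self):
        sc = make_case(SceneSpec(seed=5, landmark_noise_sigma=0.1))
        case = sc.case
        crown0 = case.landmarks[("crown", "cbct0")]
        crownF = case.landmarks[("crown", "stlF")]
        refined = crown_align(
            crown0, crownF, case.initial_canine, case.final_stl_arch, refine=True
        )
        assert refined.surface_rms is not None
        # surface RMS of the pure landmark fit, measured the same way
        from scipy.spatial import cKDTree

        lm_fit = kabsch_fit(crown0, crownF)
        crown_pts = case.initial_canine.mesh.vertices[
            case.initial_canine.crown_vertex_mask
        ]
        d, _ = cKDTree(case.final_stl_arch.vertices).query(
            lm_fit.transform.apply(crown_pts)
        )
        keep = np.sort(d)[: max(3, int(np.ceil(0.8 * len(d))))]
        landmark_surface_rms = float(np.sqrt(np.mean(keep**2)))
        assert refined.surface_rms <= landmark_surface_rms + 1e-9
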