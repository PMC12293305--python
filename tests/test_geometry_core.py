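import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canine_trace.exceptions import MeshFormatError, ValidationError
from canine_trace.geometry_core import (
    LandmarkSet,
    RigidTransform,
    TriangleMesh,
    compose,
    euclidean_distance,
    invert,
    read_landmarks,
    read_stl,
    write_landmarks,
    write_stl,
)
from canine_trace.synthetic_data import make_tooth

from conftest import random_rigid

ONE_FACET_ASCII = """solid test
  facet normal 0 0 1
    outer loop
      vertex 0 0 0
      vertex 1 0 0
      vertex 0 1 0
    endloop
  endfacet
endsolid test
"""


def one_facet_mesh():
    return TriangleMesh(
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        np.array([[0, 1, 2]]),
    )


class TestStlIO:
    def test_ascii_single_facet(self, tmp_path):
        p = tmp_path / "one.stl"
        p.write_text(ONE_FACET_ASCII)
        mesh = read_stl(p)
        assert mesh.n_vertices == 3
        assert mesh.n_faces == 1

    def test_binary_layout_is_84_plus_50_per_triangle(self, tmp_path):
        p = write_stl(one_facet_mesh(), tmp_path / "one.stl", dialect="binary")
        assert p.stat().st_size == 84 + 50

    def test_empty_mesh_rejected_on_write(self, tmp_path):
        empty = TriangleMesh(np.zeros((3, 3)) + np.eye(3), np.zeros((0, 3), int))
        with pytest.raises(ValidationError):
            write_stl(empty, tmp_path / "x.stl")

    @pytest.mark.parametrize("dialect", ["binary", "ascii"])
    def test_round_trip_identity(self, tmp_path, dialect):
        tooth = make_tooth("canine")
        mesh = tooth.mesh
        back = read_stl(write_stl(mesh, tmp_path / f"c.{dialect}.stl", dialect))
        assert back.n_faces == mesh.n_faces
        # same vertex multiset; binary stores float32, ascii full precision
        a = np.array(sorted(map(tuple, mesh.vertices)))
        b = np.array(sorted(map(tuple, back.vertices)))
        tol = 1e-12 if dialect == "ascii" else 1e-5
        assert np.abs(a - b).max() < tol

    def test_binary_round_trip_bit_identical(self, tmp_path):
        """Values written as float32 reload without any further loss."""
        mesh = make_tooth("molar").mesh
        p1 = tmp_path / "a.stl"
        p2 = tmp_path / "b.stl"
        first = read_stl(write_stl(mesh, p1, "binary"))
        second = read_stl(write_stl(first, p2, "binary"))
        assert np.array_equal(first.vertices, second.vertices)
        assert np.array_equal(first.faces, second.faces)

    def test_exact_weld_merges_shared_vertices(self, tmp_path):
        # two facets sharing an edge: 6 stored corners, 4 distinct vertices
        mesh = TriangleMesh(
            np.array(
                [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=float
            ),
            np.array([[0, 1, 2], [1, 3, 2]]),
        )
        back = read_stl(write_stl(mesh, tmp_path / "quad.stl", "binary"))
        assert back.n_vertices == 4
        assert back.n_faces == 2

    def test_binary_size_mismatch_names_byte_offset(self, tmp_path):
        p = write_stl(one_facet_mesh(), tmp_path / "trunc.stl", "binary")
        p.write_bytes(p.read_bytes()[:-10])
        with pytest.raises(MeshFormatError) as exc:
            read_stl(p)
        assert exc.value.byte_offset is not None
        assert "byte offset" in str(exc.value)

    def test_ascii_malformed_vertex_line(self, tmp_path):
        p = tmp_path / "bad.stl"
        p.write_text(ONE_FACET_ASCII.replace("vertex 1 0 0", "vertex 1 zero 0"))
        with pytest.raises(MeshFormatError) as exc:
            read_stl(p)
        assert exc.value.byte_offset is not None

    def test_trimesh_reads_our_files_identically(self, tmp_path):
        trimesh = pytest.importorskip("trimesh")
        mesh = make_tooth("canine").mesh
        for dialect in ("binary", "ascii"):
            p = write_stl(mesh, tmp_path / f"t.{dialect}.stl", dialect)
            other = trimesh.load(p, process=False)
            assert len(other.faces) == mesh.n_faces
            ours = np.array(sorted(map(tuple, mesh.triangles().reshape(-1, 3))))
            theirs = np.array(sorted(map(tuple, np.asarray(other.triangles).reshape(-1, 3))))
            assert np.abs(ours - theirs).max() < 1e-5


class TestMeshValidation:
    def test_out_of_range_face_index(self):
        with pytest.raises(ValidationError):
            TriangleMesh(np.eye(3), np.array([[0, 1, 3]]))

    def test_degenerate_face(self):
        with pytest.raises(ValidationError):
            TriangleMesh(np.eye(3), np.array([[0, 1, 1]]))


class TestRigidTransform:
    def test_identity_leaves_points(self, rng):
        pts = rng.normal(size=(5, 3))
        assert np.array_equal(RigidTransform.identity().apply(pts), pts)

    def test_pure_translation(self):
        t = RigidTransform(np.eye(3), [1.0, 2.0, 3.0])
        assert np.allclose(t.apply([0, 0, 0]), [1, 2, 3])

    def test_quarter_turn_about_z(self):
        c, s = 0.0, 1.0
        t = RigidTransform([[c, -s, 0], [s, c, 0], [0, 0, 1]], [0, 0, 0])
        assert np.abs(t.apply([1.0, 0, 0]) - [0, 1, 0]).max() < 1e-12

    def test_invert_identity(self):
        assert RigidTransform.identity().inverse().almost_equals(
            RigidTransform.identity()
        )

    def test_compose_two_translations(self):
        t1 = RigidTransform(np.eye(3), [1, 0, 0])
        t2 = RigidTransform(np.eye(3), [0, 1, 0])
        assert np.allclose(compose(t2, t1).apply([0, 0, 0]), [1, 1, 0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_inverse_is_two_sided(self, seed):
        t = random_rigid(np.random.default_rng(seed))
        assert compose(invert(t), t).almost_equals(RigidTransform.identity(), 1e-9)
        assert compose(t, invert(t)).almost_equals(RigidTransform.identity(), 1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_isometry(self, seed):
        rng = np.random.default_rng(seed)
        t = random_rigid(rng)
        pts = rng.uniform(-50, 50, size=(8, 3))
        moved = t.apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_compose_associative(self, rng):
        a, b, c = (random_rigid(rng) for _ in range(3))
        left = compose(compose(a, b), c)
        right = compose(a, compose(b, c))
        assert left.almost_equals(right, 1e-9)

    def test_reflection_rejected(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValidationError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))


class TestDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 0, 0), (3, 4, 0), 5.0),
            ((1, 1, 1), (1, 1, 1), 0.0),
            ((1, 1, 1), (2, 2, 2), math.sqrt(3)),
        ],
    )
    def test_examples(self, a, b, expected):
        assert euclidean_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(2, 3))
        assert euclidean_distance(a, b) == euclidean_distance(b, a)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            euclidean_distance((np.nan, 0, 0), (0, 0, 0))


class TestLandmarks:
    def test_csv_round_trip(self, tmp_path, rng):
        sets = [
            LandmarkSet(["a", "b", "c"], rng.normal(size=(3, 3)), "skull"),
            LandmarkSet(["r1", "r2", "r3"], rng.normal(size=(3, 3)), "palatal_rugae"),
        ]
        path = write_landmarks(sets, tmp_path / "lm.csv")
        back = read_landmarks(path)
        assert set(back) == {"skull", "palatal_rugae"}
        assert back["skull"].names == ["a", "b", "c"]
        assert np.abs(back["skull"].points - sets[0].points).max() < 1e-12

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValidationError):
            LandmarkSet(["a", "a", "b"], np.zeros((3, 3)), "skull")

    def test_pairing_requires_identical_name_sequences(self):
        a = LandmarkSet(["p", "q", "r"], np.zeros((3, 3)), "skull")
        b = LandmarkSet(["p", "r", "q"], np.zeros((3, 3)), "skull")
        assert not a.is_paired_with(b)

    def test_unknown_role_rejected(self):
        with pytest.raises(ValidationError):
            LandmarkSet(["a", "b", "c"], np.zeros((3, 3)), "mystery")
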