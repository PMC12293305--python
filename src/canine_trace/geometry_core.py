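"""Fundamental 3D types, STL I/O and rigid-transform algebra.

Coordinates are millimetres in a right-handed frame; no axis semantics are
imposed because every quantity the package reports is a frame-invariant
distance. All internal arithmetic is float64 even though binary STL stores
float32: registration residuals at the 1e-9 mm level require it.
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import MeshFormatError, ValidationError

__all__ = [
    "LANDMARK_ROLES",
    "LandmarkSet",
    "RigidTransform",
    "TriangleMesh",
    "apply_transform",
    "compose",
    "euclidean_distance",
    "invert",
    "read_landmarks",
    "read_stl",
    "write_landmarks",
    "write_stl",
]

#: Roles a landmark set may declare; pairing across timepoints is by name.
LANDMARK_ROLES = (
    "skull",
    "tooth_correspondence",
    "palatal_rugae",
    "crown",
    "cusp_tip",
    "apex",
)

_ORTHO_TOL = 1e-9


def as_point(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Coerce to a finite float64 3-vector (mm)."""
    a = np.asarray(p, dtype=np.float64).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"point has non-finite coordinates: {a}")
    return a


def euclidean_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Straight-line distance between two points, in mm."""
    return float(np.linalg.norm(as_point(a) - as_point(b)))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation``.

    The rotation must be orthonormal with determinant +1: same-patient
    superimposition is an isometry, so reflections and scaling are
    rejected at construction.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = as_point(self.translation)
        if not np.all(np.isfinite(R)):
            raise ValidationError("rotation has non-finite entries")
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-8:
            raise ValidationError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one point (shape (3,)) or a stack of points (n, 3)."""
        pts = np.asarray(points, dtype=np.float64)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Return the motion 'apply ``first``, then apply ``self``'."""
        return RigidTransform(
            self.rotation @ first.rotation,
            self.rotation @ first.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def almost_equals(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() <= tol
            and np.abs(self.translation - other.translation).max() <= tol
        )


def compose(t2: RigidTransform, t1: RigidTransform) -> RigidTransform:
    """Composition: ``t1`` first, then ``t2``."""
    return t2.compose(t1)


def invert(t: RigidTransform) -> RigidTransform:
    return t.inverse()


@dataclass
class TriangleMesh:
    """Indexed triangle surface: ``vertices`` (n, 3) float64 mm, ``faces`` (m, 3) int."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(v)):
            raise ValidationError("mesh has non-finite vertex coordinates")
        if f.size:
            if f.min() < 0 or f.max() >= len(v):
                raise ValidationError(
                    f"face index out of range (0..{len(v) - 1}): "
                    f"min {f.min()}, max {f.max()}"
                )
            degenerate = (
                (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            )
            if degenerate.any():
                raise ValidationError(
                    f"{int(degenerate.sum())} degenerate face(s) with repeated "
                    "vertex indices"
                )
        self.vertices = v
        self.faces = f

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min_corner, max_corner) of the axis-aligned bounding box."""
        if not len(self.vertices):
            raise ValidationError("empty mesh has no bounds")
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def transformed(self, t: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(t.apply(self.vertices), self.faces.copy())

    def triangles(self) -> np.ndarray:
        """Per-face vertex coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    @staticmethod
    def concatenate(meshes: Iterable["TriangleMesh"]) -> "TriangleMesh":
        verts, faces, offset = [], [], 0
        for m in meshes:
            verts.append(m.vertices)
            faces.append(m.faces + offset)
            offset += m.n_vertices
        if not verts:
            raise ValidationError("cannot concatenate zero meshes")
        return TriangleMesh(np.vstack(verts), np.vstack(faces))


@dataclass
class LandmarkSet:
    """Named, ordered 3D points (mm).

    Two sets are *paired* only if their name sequences match exactly; the
    rigid fit refuses anything else so that correspondence stays auditable.
    """

    names: list[str]
    points: np.ndarray
    role: str = "tooth_correspondence"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(pts)):
            raise ValidationError("landmark coordinates must be finite")
        names = [str(n) for n in self.names]
        if len(names) != len(pts):
            raise ValidationError(
                f"{len(names)} names for {len(pts)} points"
            )
        if len(set(names)) != len(names):
            raise ValidationError("landmark names must be unique within a set")
        if self.role not in LANDMARK_ROLES:
            raise ValidationError(
                f"unknown landmark role {self.role!r}; expected one of {LANDMARK_ROLES}"
            )
        self.names = names
        self.points = pts

    def __len__(self) -> int:
        return len(self.names)

    def is_paired_with(self, other: "LandmarkSet") -> bool:
        return self.names == other.names

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(list(self.names), t.apply(self.points), self.role)


def apply_transform(obj, transform: RigidTransform):
    """Apply a rigid transform to a mesh, landmark set, or point array."""
    if isinstance(obj, TriangleMesh):
        return obj.transformed(transform)
    if isinstance(obj, LandmarkSet):
        return obj.transformed(transform)
    return transform.apply(np.asarray(obj, dtype=np.float64))


# ---------------------------------------------------------------------------
# STL I/O
#
# Binary layout: 80-byte header, uint32 triangle count, then per triangle a
# 50-byte record (normal 3xf4, three vertices 9xf4, uint16 attribute).
# Duplicated vertices across facets are merged with an exact-match weld
# (tolerance 0) on read, preserving first-occurrence order: geometry is
# never moved, only re-indexed.
# ---------------------------------------------------------------------------

_BINARY_RECORD = np.dtype(
    [("normal", "<f4", 3), ("vertices", "<f4", (3, 3)), ("attr", "<u2")]
)


def _weld(tri_vertices: np.ndarray) -> TriangleMesh:
    flat = np.ascontiguousarray(tri_vertices.reshape(-1, 3), dtype=np.float64)
    uniq, first, inverse = np.unique(
        flat, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first)
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    return TriangleMesh(uniq[order], rank[inverse].reshape(-1, 3))


def _face_normals(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.triangles()
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    length = np.linalg.norm(n, axis=1, keepdims=True)
    length[length == 0] = 1.0
    return n / length

def read_stl(path: str | Path) -> TriangleMesh:
    """Read a binary or ASCII STL file into a welded :class:`TriangleMesh`.

    STL is unitless; coordinates are taken as millimetres. Raises
    :class:`MeshFormatError` (naming the byte offset) on malformed input and
    :class:`ValidationError` on an empty or degenerate mesh.
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 15:
        raise MeshFormatError(f"{path}: too short to be an STL file", byte_offset=0)
    head = raw[:512].lstrip()
    if head.startswith(b"solid") and b"facet" in raw[:4096]:
        return _read_stl_ascii(raw, path)
    return _read_stl_binary(raw, path)


def _read_stl_binary(raw: bytes, path: Path) -> TriangleMesh:
    if len(raw) < 84:
        raise MeshFormatError(
            f"{path}: binary STL truncated before triangle count", byte_offset=80
        )
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * count
    if len(raw) != expected:
        raise MeshFormatError(
            f"{path}: header declares {count} triangles ({expected} bytes) "
            f"but file has {len(raw)} bytes",
            byte_offset=min(len(raw), expected),
        )
    if count == 0:
        raise ValidationError(f"{path}: empty mesh (0 triangles)")
    records = np.frombuffer(raw, dtype=_BINARY_RECORD, count=count, offset=84)
    return _weld(records["vertices"].astype(np.float64))


def _read_stl_ascii(raw: bytes, path: Path) -> TriangleMesh:
    text = raw.decode("ascii", errors="replace")
    vertices: list[list[float]] = []
    offset = 0
    for line in text.splitlines(keepends=True):
        stripped = line.strip()
        if stripped.startswith("vertex"):
            parts = stripped.split()
            if len(parts) != 4:
                raise MeshFormatError(
                    f"{path}: malformed vertex line {stripped!r}", byte_offset=offset
                )
            try:
                vertices.append([float(x) for x in parts[1:]])
            except ValueError:
                raise MeshFormatError(
                    f"{path}: non-numeric vertex in line {stripped!r}",
                    byte_offset=offset,
                ) from None
        offset += len(line.encode("ascii", errors="replace"))
    if not vertices:
        raise ValidationError(f"{path}: empty mesh (no vertex records)")
    if len(vertices) % 3:
        raise MeshFormatError(
            f"{path}: vertex count {len(vertices)} is not a multiple of 3",
            byte_offset=offset,
        )
    tri = np.asarray(vertices, dtype=np.float64).reshape(-1, 3, 3)
    return _weld(tri)


def write_stl(mesh: TriangleMesh, path: str | Path, dialect: str = "binary") -> Path:
    """Write a mesh as STL. ``dialect`` is ``"binary"`` or ``"ascii"``.

    A binary file is exactly ``84 + 50 * n_faces`` bytes. ASCII prints full
    float64 precision so a round trip reproduces coordinates exactly.
    """
    if dialect not in ("binary", "ascii"):
        raise ValidationError(f"unknown STL dialect {dialect!r}")
    if mesh.n_faces == 0:
        raise ValidationError("refusing to write a mesh with no faces")
    path = Path(path)
    if dialect == "binary":
        records = np.zeros(mesh.n_faces, dtype=_BINARY_RECORD)
        records["normal"] = _face_normals(mesh).astype(np.float32)
        records["vertices"] = mesh.triangles().astype(np.float32)
        with open(path, "wb") as fh:
            fh.write(b"canine_trace binary STL".ljust(80, b" "))
            fh.write(struct.pack("<I", mesh.n_faces))
            fh.write(records.tobytes())
    else:
        buf = io.StringIO()
        buf.write("solid canine_trace\n")
        normals = _face_normals(mesh)
        for tri, n in zip(mesh.triangles(), normals):
            buf.write(f"  facet normal {n[0]:.17g} {n[1]:.17g} {n[2]:.17g}\n")
            buf.write("    outer loop\n")
            for v in tri:
                buf.write(f"      vertex {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            buf.write("    endloop\n  endfacet\n")
        buf.write("endsolid canine_trace\n")
        path.write_text(buf.getvalue(), encoding="ascii")
    return path


# ---------------------------------------------------------------------------
# Landmark CSV: header `name,x,y,z,role`, mm, decimal point, UTF-8. One file
# may mix roles; readers get a dict keyed by role.
# ---------------------------------------------------------------------------

def write_landmarks(sets: Iterable[LandmarkSet], path: str | Path) -> Path:
    rows = []
    for s in sets:
        for name, p in zip(s.names, s.points):
            rows.append({"name": name, "x": p[0], "y": p[1], "z": p[2], "role": s.role})
    if not rows:
        raise ValidationError("no landmarks to write")
    pd.DataFrame(rows, columns=["name", "x", "y", "z", "role"]).to_csv(
        path, index=False
    )
    return Path(path)


def read_landmarks(path: str | Path) -> dict[str, LandmarkSet]:
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z", "role"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: landmark CSV must have columns {sorted(required)}"
        )
    out: dict[str, LandmarkSet] = {}
    for role, grp in df.groupby("role", sort=False):
        out[str(role)] = LandmarkSet(
            [str(n) for n in grp["name"]],
            grp[["x", "y", "z"]].to_numpy(dtype=np.float64),
            str(role),
        )
    return out
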