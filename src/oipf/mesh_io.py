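"""Triangle-mesh container, STL read/write and seeded surface sampling.

STL carries no units; this package mandates millimetres throughout.
Reading welds duplicated vertices (STL stores each triangle standalone)
and drops degenerate faces so downstream area/adjacency computations are
well defined.  Surface sampling is area-weighted uniform and fully
deterministic given a seed -- it is the only stochastic step feeding the
ICP registration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import trimesh

from .errors import InvalidArgumentError, STLFormatError

#: vertices closer than this (mm) are merged on read
WELD_TOL = 1e-6
#: faces with area below this (mm^2) are dropped as degenerate
DEGENERATE_AREA = 1e-12
#: default point count per mesh for registration
DEFAULT_SAMPLE_COUNT = 20_000

_STL_BINARY_HEADER = 80
_STL_BINARY_RECORD = 50


@dataclass
class TriangleMesh:
    """Vertices (N x 3, mm) + faces (M x 3 indices) + optional face labels.

    ``face_labels`` names a region per face (``body``, ``lateral_extension``,
    ``appendage`` for the synthetic surrogate); regions can be excluded
    from sampling, e.g. intraoperatively bent areas.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_labels: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise InvalidArgumentError("mesh vertices contain non-finite coordinates")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise InvalidArgumentError("face indices out of range")
        if self.face_labels is not None:
            self.face_labels = np.asarray(self.face_labels)
            if len(self.face_labels) != len(self.faces):
                raise InvalidArgumentError("face_labels length must match faces")

    # -- geometry helpers --------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (M, 3, 3)."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        return np.stack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def transformed(self, transform) -> "TriangleMesh":
        """Return a copy with vertices mapped through a RigidTransform."""
        return TriangleMesh(
            transform.apply(self.vertices),
            self.faces.copy(),
            None if self.face_labels is None else self.face_labels.copy(),
        )

    def submesh(self, face_mask: np.ndarray) -> "TriangleMesh":
        """Keep only faces where ``face_mask`` is True; reindex vertices."""
        faces = self.faces[np.asarray(face_mask, dtype=bool)]
        used = np.unique(faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[used] = np.arange(len(used))
        labels = (
            None
            if self.face_labels is None
            else self.face_labels[np.asarray(face_mask, dtype=bool)]
        )
        return TriangleMesh(self.vertices[used], remap[faces], labels)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )


@dataclass(frozen=True)
class SurfaceSample:
    """Points sampled on a mesh surface, with provenance.

    Every point lies on the face recorded in ``face_index`` (exactly, by
    barycentric construction).
    """

    points: np.ndarray
    face_index: np.ndarray
    seed: int


def _weld(vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL):
    """Merge vertices closer than ``tol`` (grid snap) and drop degenerate faces."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts = vertices[np.sort(first)]
    # map unique-row ids onto the sorted-first ordering
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    faces = rank[inverse][faces]
    mesh = TriangleMesh(verts, faces)
    ok = mesh.face_areas() > DEGENERATE_AREA
    # also drop faces with repeated vertex indices
    f = mesh.faces
    ok &= (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    return mesh.submesh(ok)


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file; weld vertices and drop degenerate faces."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    size = os.path.getsize(path)
    with open(path, "rb") as fh:
        head = fh.read(6)
    is_ascii = head.startswith(b"solid")
    if not is_ascii:
        if size < _STL_BINARY_HEADER + 4:
            raise STLFormatError(
                f"{path}: truncated binary STL header at byte {size} "
                f"(need {_STL_BINARY_HEADER + 4})"
            )
        with open(path, "rb") as fh:
            fh.seek(_STL_BINARY_HEADER)
            n_tri = int.from_bytes(fh.read(4), "little")
        expected = _STL_BINARY_HEADER + 4 + _STL_BINARY_RECORD * n_tri
        if size < expected:
            raise STLFormatError(
                f"{path}: binary STL truncated at byte {size}, "
                f"expected {expected} for {n_tri} triangles"
            )
    try:
        tm = trimesh.load_mesh(path, file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise STLFormatError(f"{path}: malformed STL ({exc})") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise STLFormatError(f"{path}: STL contains no triangles")
    return _weld(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write a mesh as STL (``binary`` default, ``ascii`` optional)."""
    if dialect not in ("binary", "ascii"):
        raise InvalidArgumentError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    if mesh.n_faces == 0:
        raise InvalidArgumentError("refusing to write an empty mesh")
    tm = mesh.to_trimesh()
    data = trimesh.exchange.stl.export_stl(tm) if dialect == "binary" else (
        trimesh.exchange.stl.export_stl_ascii(tm).encode()
    )
    with open(path, "wb") as fh:
        fh.write(data)


def sample_surface(
    mesh: TriangleMesh,
    n_points: int = DEFAULT_SAMPLE_COUNT,
    seed: int = 0,
    exclude_labels: Sequence[str] | None = None,
    exclude_faces: Iterable[int] | None = None,
) -> SurfaceSample:
    """Draw ``n_points`` area-weighted uniform points on the surface.

    Faces whose label is in ``exclude_labels`` (or whose index is in
    ``exclude_faces``) are skipped -- used to keep bent/adjusted implant
    regions out of the registration.
    """
    if mesh.n_faces == 0:
        raise InvalidArgumentError("cannot sample an empty mesh")
    if n_points < 1:
        raise InvalidArgumentError(f"n_points must be >= 1, got {n_points}")
    keep = np.ones(mesh.n_faces, dtype=bool)
    if exclude_labels is not None:
        if mesh.face_labels is None:
            raise InvalidArgumentError("mesh has no face labels to exclude by")
        keep &= ~np.isin(mesh.face_labels, list(exclude_labels))
    if exclude_faces is not None:
        keep[np.asarray(list(exclude_faces), dtype=np.int64)] = False
    areas = mesh.face_areas() * keep
    total = areas.sum()
    if total <= 0:
        raise InvalidArgumentError("all faces excluded from sampling")
    rng = np.random.default_rng(seed)
    face_idx = rng.choice(mesh.n_faces, size=n_points, p=areas / total)
    tri = mesh.triangles()[face_idx]
    # uniform barycentric via square-root trick
    r1 = np.sqrt(rng.random(n_points))[:, None]
    r2 = rng.random(n_points)[:, None]
    pts = (1 - r1) * tri[:, 0] + r1 * (1 - r2) * tri[:, 1] + r1 * r2 * tri[:, 2]
    return SurfaceSample(points=pts, face_index=face_idx, seed=seed)
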