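"""Mesh and orientation I/O.

Facet patches are exchanged as PLY / STL / OBJ triangle meshes with
coordinates in millimetres (laser-scanner native units).  STL and OBJ carry
no unit metadata, so an explicit ``units`` override exists for meshes saved
in metres.  Anatomical orientation (dorsal–volar, radial–ulnar axes) can be
supplied as a small JSON landmark file; without one, downstream code falls
back to a principal-component frame.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import DegenerateInputError, FormatError, ValidationError

log = logging.getLogger(__name__)

#: formats supported for both reading and writing, keyed by extension
SUPPORTED_FORMATS = {".ply", ".stl", ".obj"}

#: vertices closer than this (mm) are welded into one
WELD_TOLERANCE = 1e-9

#: triangles with less area (mm^2) are dropped during cleaning
DEGENERATE_AREA = 1e-12


@dataclass
class TriangleMesh:
    """A triangulated articular facet patch, coordinates in mm."""

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray     # (m, 3) int64
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be an (m, 3) array")

    # -- basic quantities -------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangle_corners(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_cross(self) -> np.ndarray:
        """Unnormalized face normals (cross products); norm = 2 x area."""
        tri = self.triangle_corners()
        return np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_cross(), axis=1)

    def face_normals(self) -> np.ndarray:
        cross = self.face_cross()
        norm = np.linalg.norm(cross, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return cross / norm

    def face_centroids(self) -> np.ndarray:
        return self.triangle_corners().mean(axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident face normals, unit length."""
        cross = self.face_cross()  # area-weighted by construction
        out = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(out, self.faces[:, k], cross)
        norm = np.linalg.norm(out, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return out / norm

    def mean_surface_normal(self) -> np.ndarray:
        """Unit mean of face normals, area weighted."""
        total = self.face_cross().sum(axis=0)
        n = np.linalg.norm(total)
        if n == 0:
            raise DegenerateInputError("mesh has no net surface orientation")
        return total / n

    def area_weighted_centroid(self) -> np.ndarray:
        areas = self.face_areas()
        return (self.face_centroids() * areas[:, None]).sum(axis=0) / areas.sum()

    # -- validation and cleaning ------------------------------------------
    def validate(self) -> None:
        """Raise if the mesh violates its structural invariants."""
        if not np.isfinite(self.vertices).all():
            raise ValidationError(f"{self.name or 'mesh'}: non-finite vertex coordinates")
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValidationError(f"{self.name or 'mesh'}: face references an invalid vertex index")
        if self.n_vertices < 4 or self.n_faces < 1:
            raise DegenerateInputError(
                f"{self.name or 'mesh'}: needs >=4 vertices and >=1 face "
                f"(got {self.n_vertices}/{self.n_faces})"
            )
        if (self.face_areas() < DEGENERATE_AREA).any():
            raise ValidationError(f"{self.name or 'mesh'}: contains zero-area faces; call cleaned()")

    def cleaned(self, weld_tol: float = WELD_TOLERANCE) -> "TriangleMesh":
        """Weld duplicate vertices, drop degenerate faces and unused vertices.

        Idempotent: cleaning a cleaned mesh returns identical arrays.
        """
        if not np.isfinite(self.vertices).all():
            raise ValidationError(f"{self.name or 'mesh'}: non-finite vertex coordinates")
        # weld: quantize to the tolerance grid, keep first representative
        decimals = max(0, int(round(-np.log10(max(weld_tol, 1e-12)))))
        key = np.round(self.vertices, decimals=decimals)
        _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
        # preserve original ordering of first occurrences
        order = np.argsort(first)
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        vertices = self.vertices[np.sort(first)]
        faces = rank[inverse][self.faces]

        # drop faces with repeated vertices or negligible area
        distinct = (
            (faces[:, 0] != faces[:, 1])
            & (faces[:, 1] != faces[:, 2])
            & (faces[:, 0] != faces[:, 2])
        )
        faces = faces[distinct]
        if len(faces):
            tri = vertices[faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
            )
            faces = faces[areas >= DEGENERATE_AREA]

        # drop unreferenced vertices
        used = np.unique(faces)
        remap = -np.ones(len(vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(vertices[used], remap[faces], name=self.name)

    def submesh(self, face_indices: np.ndarray, name: str | None = None) -> "TriangleMesh":
        """Mesh restricted to the given faces (unused vertices dropped)."""
        faces = self.faces[np.asarray(face_indices)]
        used = np.unique(faces)
        remap = np.zeros(self.n_vertices, dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[used], remap[faces], name=name or self.name)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class OrientationSpec:
    """Anatomical axes for a facet, from landmarks or PCA fallback."""

    dorsal_volar_axis: np.ndarray | None = None
    radial_ulnar_axis: np.ndarray | None = None
    proximal_distal_axis: np.ndarray | None = None
    source: str = "pca-default"  # {"landmarks", "pca-default"}


PCA_DEFAULT = OrientationSpec(source="pca-default")


def read_mesh(path: str | Path, units: str = "mm") -> TriangleMesh:
    """Load a facet mesh in mm, cleaning degenerate geometry.

    Parameters
    ----------
    path:
        A PLY, STL or OBJ file; format detected from the extension.
    units:
        ``"mm"`` (default) or ``"m"``; metre coordinates are scaled x1000.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() not in SUPPORTED_FORMATS:
        raise FormatError(f"unsupported mesh format '{path.suffix}' (need PLY/STL/OBJ)")
    if units not in {"mm", "m"}:
        raise ValidationError(f"units must be 'mm' or 'm', got {units!r}")
    try:
        raw = trimesh.load(str(path), file_type=path.suffix.lstrip("."), process=False)
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, trimesh.Trimesh) or len(raw.faces) == 0:
        raise FormatError(f"{path} does not contain a triangle mesh")
    vertices = np.asarray(raw.vertices, dtype=np.float64)
    if units == "m":
        vertices = vertices * 1000.0
    mesh = TriangleMesh(vertices, np.asarray(raw.faces), name=path.stem).cleaned()
    if mesh.n_vertices < 4:
        raise DegenerateInputError(
            f"{path}: only {mesh.n_vertices} vertices / {mesh.n_faces} faces after "
            "cleaning; cannot support a surface fit"
        )
    mesh.validate()
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh; binary PLY by default, format chosen by extension.

    Round-trip contract: ``read_mesh(write_mesh(m))`` reproduces vertices
    within 1e-6 mm for PLY (which stores float64 here) and STL/OBJ at their
    native precision.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in SUPPORTED_FORMATS:
        raise FormatError(f"unsupported mesh format '{suffix}' (need PLY/STL/OBJ)")
    mesh.validate()
    tm = mesh.to_trimesh()
    try:
        if suffix == ".ply":
            data = trimesh.exchange.ply.export_ply(tm, encoding="binary_little_endian")
            path.write_bytes(data)
        else:
            tm.export(str(path))
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValidationError("orientation axis has zero length")
    return v / n


def read_orientation(path: str | Path) -> OrientationSpec:
    """Read a landmark orientation JSON; fall back to PCA if absent.

    The file holds named unit vectors, e.g.
    ``{"dorsal_volar": [1,0,0], "radial_ulnar": [0,1,0]}``.  Axes more than
    10 degrees from orthogonal are rejected; smaller deviations are fixed by
    Gram-Schmidt (dorsal_volar kept, radial_ulnar corrected, third derived
    right-handed).
    """
    path = Path(path)
    if not path.exists():
        warnings.warn(f"orientation file {path} not found; using PCA frame", stacklevel=2)
        log.warning("orientation file %s not found; using PCA frame", path)
        return OrientationSpec(source="pca-default")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: invalid JSON: {exc}") from exc
    if "dorsal_volar" not in payload or "radial_ulnar" not in payload:
        raise ValidationError(f"{path}: needs 'dorsal_volar' and 'radial_ulnar' axes")
    dv = _unit(payload["dorsal_volar"])
    ru = _unit(payload["radial_ulnar"])
    angle = np.degrees(np.arccos(np.clip(np.abs(dv @ ru), 0.0, 1.0)))
    if 90.0 - angle > 10.0:
        raise ValidationError(
            f"{path}: axes are {angle:.1f} degrees apart; more than 10 degrees "
            "from orthogonal"
        )
    ru = _unit(ru - (ru @ dv) * dv)
    third = np.cross(dv, ru)
    return OrientationSpec(
        dorsal_volar_axis=dv,
        radial_ulnar_axis=ru,
        proximal_distal_axis=third,
        source="landmarks",
    )
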