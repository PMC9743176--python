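"""Closed-triangle-mesh integrals: volume, centroid, and axial moment of inertia.

The displaced volume and center of buoyancy of a model are integrals over its
external envelope, and the moment of inertia of a uniform component is an
integral over its solid interior.  All three reduce, by the divergence
theorem, to sums over signed tetrahedra formed by each oriented face and the
origin — no voxelisation or surface sampling is involved, so watertight
meshes are evaluated exactly (up to float rounding).

Meshes must be watertight and consistently wound: every edge shared by
exactly two faces traversed in opposite directions.  Inward-oriented meshes
(negative enclosed volume) are flipped automatically with a warning rather
than rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "MeshValidationError",
    "load_mesh",
    "mesh_volume",
    "mesh_centroid",
    "mesh_second_moments",
    "mesh_inertia",
]


class MeshValidationError(ValueError):
    """Mesh is open or inconsistently oriented; offending edges are listed."""

    def __init__(self, message: str, bad_edges=()):
        super().__init__(message)
        self.bad_edges = tuple(bad_edges)


@dataclass(frozen=True)
class TriangleMesh:
    """A triangle surface mesh: vertex coordinates (cm) and 0-based face indices.

    Construction validates index bounds, watertightness and winding
    consistency, and flips an inward-oriented mesh so the enclosed volume is
    positive.  Use ``TriangleMesh(vertices, faces, validate=False)`` only for
    meshes already known good.
    """

    vertices: np.ndarray
    faces: np.ndarray
    validate: bool = True

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError(f"faces must be (m, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if self.validate:
            _check_watertight(v, f)
            if _signed_volume(v, f) < 0:
                logger.warning("mesh is inward-oriented; flipping face winding")
                object.__setattr__(self, "faces", f[:, ::-1].copy())

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float), self.faces, validate=False)

    def rotated(self, rotation_matrix) -> "TriangleMesh":
        R = np.asarray(rotation_matrix, float)
        return TriangleMesh(self.vertices @ R.T, self.faces, validate=False)


def _check_watertight(vertices: np.ndarray, faces: np.ndarray) -> None:
    """Every directed edge must be matched by exactly one reverse edge."""
    if len(faces) == 0:
        raise MeshValidationError("mesh has no faces")
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    directed = {}
    for a, b in edges:
        key = (int(a), int(b))
        directed[key] = directed.get(key, 0) + 1
    bad = []
    for (a, b), count in directed.items():
        if count != 1 or directed.get((b, a), 0) != 1:
            bad.append((a, b))
    if bad:
        bad.sort()
        shown = ", ".join(f"{a}-{b}" for a, b in bad[:8])
        more = f" (+{len(bad) - 8} more)" if len(bad) > 8 else ""
        raise MeshValidationError(
            f"mesh is not watertight/consistently oriented; offending edges: {shown}{more}",
            bad_edges=bad,
        )


def _face_triples(mesh_or_v, faces=None):
    if faces is None:
        v, f = mesh_or_v.vertices, mesh_or_v.faces
    else:
        v, f = mesh_or_v, faces
    return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]


def _signed_volume(vertices, faces) -> float:
    a, b, c = _face_triples(vertices, faces)
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (cm^3) via signed origin tetrahedra."""
    return _signed_volume(mesh.vertices, mesh.faces)


def mesh_centroid(mesh: TriangleMesh) -> np.ndarray:
    """Volume centroid: first moments of the signed tetrahedra over the volume.

    Each tetrahedron (origin, a, b, c) has centroid (a + b + c)/4 and signed
    volume det(a, b, c)/6.
    """
    a, b, c = _face_triples(mesh)
    det = np.einsum("ij,ij->i", a, np.cross(b, c))
    vol = det.sum() / 6.0
    if vol == 0:
        raise MeshValidationError("mesh encloses zero volume")
    moment = (det[:, None] * (a + b + c)).sum(axis=0) / 24.0
    return moment / vol


def mesh_second_moments(mesh: TriangleMesh) -> np.ndarray:
    """Second-moment matrix S = integral of r r^T dV over the enclosed solid.

    For a tetrahedron with one vertex at the origin and the others at
    v1, v2, v3 (signed volume V = det/6):

        S_tet = (det / 120) * ( sum_k v_k v_k^T + (sum_k v_k)(sum_k v_k)^T )

    Summing over all faces gives the exact polyhedral second moments, from
    which any axial moment of inertia follows.
    """
    a, b, c = _face_triples(mesh)
    det = np.einsum("ij,ij->i", a, np.cross(b, c))
    s = np.einsum("i,ij,ik->jk", det, a, a)
    s += np.einsum("i,ij,ik->jk", det, b, b)
    s += np.einsum("i,ij,ik->jk", det, c, c)
    total = a + b + c
    s += np.einsum("i,ij,ik->jk", det, total, total)
    return s / 120.0


def mesh_inertia(mesh: TriangleMesh, density: float, axis_point, axis_direction) -> float:
    """Moment of inertia (g cm^2) of the uniform solid about an arbitrary axis.

    Assembled from the volume, first and second moments so the parallel-axis
    theorem holds identically:

        I = rho * integral of |(r - p) - ((r - p).n) n|^2 dV
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    p = np.asarray(axis_point, dtype=float)
    n = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("axis direction must be nonzero")
    n = n / norm
    vol = mesh_volume(mesh)
    centroid = mesh_centroid(mesh)
    m1 = centroid * vol  # integral of r dV
    s = mesh_second_moments(mesh)
    # expand |r - p|^2 - ((r - p).n)^2 and integrate term by term
    int_r2 = float(np.trace(s))
    int_rn2 = float(n @ s @ n)
    i = (int_r2 - 2.0 * float(m1 @ p) + vol * float(p @ p)
         - int_rn2 + 2.0 * float(m1 @ n) * float(p @ n) - vol * float(p @ n) ** 2)
    return density * i


def load_mesh(path) -> TriangleMesh:
    """Load an STL (ASCII or binary) or OBJ file as a validated TriangleMesh.

    Material/texture statements in OBJ files are ignored; orientation is taken
    from face winding, never from stored normals.
    """
    import trimesh as _trimesh

    tm = _trimesh.load(str(path), force="mesh", process=True)
    return TriangleMesh(np.asarray(tm.vertices, float), np.asarray(tm.faces, np.int64))
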