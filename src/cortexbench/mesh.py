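"""Triangular surface meshes with persistent vertex correspondence.

All coordinates are millimetres. Meshes deformed along a distortion
trajectory keep their vertex order and face list, so per-vertex distances
between a surface and its deformed counterpart are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Mesh:
    """Triangulated surface.

    Parameters
    ----------
    vertices : (Nv, 3) float array, mm.
    faces : (Nf, 3) int array of vertex indices.
    normals : optional (Nv, 3) float array of unit vertex normals.
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (Nv, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (Nf, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("non-finite vertex coordinates")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices out of range")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.vertices.shape:
                raise ValueError("normals must match vertices in shape")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (Ne, 2) index array."""
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def volume(self) -> float:
        """Signed enclosed volume (divergence theorem over the triangles)."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)

    def with_vertices(self, vertices: np.ndarray) -> "Mesh":
        """Same topology, new vertex coordinates (normals dropped)."""
        return Mesh(vertices=np.asarray(vertices, dtype=np.float64), faces=self.faces)


@dataclass(frozen=True)
class DistortionStats:
    """Summary of per-vertex Euclidean distances between corresponding meshes."""

    mean_mm: float
    sd_mm: float
    p95_mm: float


def mesh_distance(mesh_a: Mesh, mesh_b: Mesh) -> DistortionStats:
    """Per-vertex distance statistics between two corresponding meshes.

    Both meshes must share a vertex count (index correspondence); returns
    the mean, standard deviation and 95th percentile of the per-vertex
    Euclidean distances, in mm.
    """
    if mesh_a.n_vertices != mesh_b.n_vertices:
        raise ValueError(
            f"vertex-count mismatch: {mesh_a.n_vertices} vs {mesh_b.n_vertices}"
        )
    d = np.linalg.norm(mesh_a.vertices - mesh_b.vertices, axis=1)
    return DistortionStats(
        mean_mm=float(d.mean()),
        sd_mm=float(d.std()),
        p95_mm=float(np.percentile(d, 95.0)),
    )
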