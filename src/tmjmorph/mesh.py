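"""Triangulated surfaces in mm coordinates.

Carries the reconstructed condyle/disc models, the point sets for the
Hausdorff/RMSD metrics, and the per-vertex signed-distance channel used for
the disc-condyle color maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SurfaceMesh:
    """Vertices (N, 3) in mm, faces (M, 3) vertex indices, optional scalar channel."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_scalars: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh vertices must be finite")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError(
                f"face indices out of range [0, {len(self.vertices)}): "
                f"min {self.faces.min()}, max {self.faces.max()}"
            )
        if self.vertex_scalars is not None:
            self.vertex_scalars = np.asarray(self.vertex_scalars, dtype=np.float64).ravel()
            if self.vertex_scalars.shape != (len(self.vertices),):
                raise ValueError("vertex_scalars must have one value per vertex")

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(M, 3, 3) triangle corner coordinates."""
        return self.vertices[self.faces]

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        if normalized:
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            n = n / norm
        return n

    def area(self) -> float:
        """Total surface area, mm^2."""
        return float(np.linalg.norm(self.face_normals(normalized=False), axis=1).sum() / 2.0)

    def volume(self) -> float:
        """Enclosed volume by the divergence theorem, mm^3 (requires a closed mesh)."""
        tri = self.triangles()
        signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
        return float(abs(signed.sum()))

    def drop_degenerate_faces(self, min_area: float = 1e-12) -> "SurfaceMesh":
        areas = np.linalg.norm(self.face_normals(normalized=False), axis=1) / 2.0
        return SurfaceMesh(self.vertices, self.faces[areas > min_area], self.vertex_scalars)

    def with_scalars(self, scalars: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices, self.faces, scalars)

    def transformed(self, transform) -> "SurfaceMesh":
        return SurfaceMesh(transform.apply(self.vertices), self.faces, self.vertex_scalars)
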