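"""Rigid transforms in physical (mm) coordinates.

A rigid transform is parameterized by three Euler angles in degrees
(extrinsic x-y-z convention), a translation vector in mm, and a rotation
center in mm.  A point ``p`` maps to ``R (p - c) + c + t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees) about ``center`` followed by a translation (mm)."""

    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "translation", "center"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be 3 finite components, got {v!r}")
            object.__setattr__(self, name, v)

    # -- matrix forms -----------------------------------------------------
    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix acting on mm coordinates."""
        R = self.rotation_matrix
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.center + self.translation - R @ self.center
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, center: np.ndarray | None = None) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        R = matrix[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("matrix is not a proper rotation")
        c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
        angles = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        t = matrix[:3, 3] - c + R @ c
        return cls(rotation_deg=angles, translation=t, center=c)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    # -- algebra ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (N, 3) array of mm points."""
        points = np.asarray(points, dtype=float)
        return (points - self.center) @ self.rotation_matrix.T + self.center + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix))

    # -- summaries --------------------------------------------------------
    @property
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation as a single angle (degrees)."""
        return float(np.degrees(Rotation.from_matrix(self.rotation_matrix).magnitude()))

    @property
    def translation_magnitude(self) -> float:
        """Net displacement of the rotation center (mm)."""
        return float(np.linalg.norm(self.translation))

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg.tolist(),
            "translation_mm": self.translation.tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation_deg=np.asarray(d["rotation_deg"], dtype=float),
            translation=np.asarray(d["translation_mm"], dtype=float),
            center=np.asarray(d.get("center_mm", np.zeros(3)), dtype=float),
        )
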