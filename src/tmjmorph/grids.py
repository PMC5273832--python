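"""Voxel grids: scalar volumes and binary masks with physical geometry.

Axis ``k`` of ``data`` runs along world axis ``k``; voxel ``(i, j, k)`` has
its center at ``origin + (i, j, k) * spacing`` (mm).  This is the frame every
registration, segmentation, and morphometry step operates in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelVolume:
    """A 3D scalar image with per-axis spacing and origin in mm."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must have 3 axes, got {self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 positive mm values, got {self.spacing}")
        if self.origin.shape != (3,) or not np.all(np.isfinite(self.origin)):
            raise ValueError(f"origin must be 3 finite mm values, got {self.origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(indices, dtype=float) * self.spacing + self.origin

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def world_center(self) -> np.ndarray:
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.spacing

    def voxel_centers(self, stride: int = 1) -> np.ndarray:
        """World coordinates of voxel centers, optionally strided, as (N, 3)."""
        axes = [np.arange(0, n, stride) for n in self.shape]
        idx = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        return self.index_to_world(idx)

    def same_grid(self, other: "VoxelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


class MaskVolume(VoxelVolume):
    """Binary occupancy on a voxel grid; values are exactly {0, 1}."""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        values = np.unique(data)
        if not np.all(np.isin(values, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.data = data.astype(np.uint8)
        super().__post_init__()

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3

    @classmethod
    def from_volume(cls, volume: VoxelVolume, data: np.ndarray) -> "MaskVolume":
        """A mask sharing ``volume``'s grid."""
        return cls(data=data, spacing=volume.spacing.copy(), origin=volume.origin.copy())
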