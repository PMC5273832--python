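"""Change metrics on registered Time-1/Time-2 structures.

Three complementary measures:

* **DSI** — Dice similarity index ``2 |M1 ∩ M2| / (|M1| + |M2|)`` on voxel
  masks: 1 = perfect overlap (no displacement), 0 = no overlap (full
  displacement).
* **Hausdorff / RMSD** — nearest-point (point-to-triangle) surface
  distances pooled over both directions; the RMSD summarizes the distance
  field, ``hausdorff_max`` is its maximum.  Small RMSD with low DSI (or the
  converse) signals shape change rather than rigid displacement, so the two
  are reported together.
* **MxD color map** — per-vertex signed nearest distance from one surface
  (the disc) to another (the condyle); the maximum magnitude MxD summarizes
  the disc-condyle relationship and the signed channel drives the color map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import MaskVolume
from .mesh import SurfaceMesh
from .meshdist import closest_on_mesh
from .records import JointRecord
from .segmentation import mask_to_mesh

DISC_POSITION_LABELS = ("normal", "mild", "moderate", "severe")
OSSEOUS_LABELS = ("normal", "remodeling", "DJD")


@dataclass
class GradingLabels:
    """Expert-supplied ordinal grades; stored, never computed."""

    disc_position: str
    osseous: str

    def __post_init__(self) -> None:
        if self.disc_position not in DISC_POSITION_LABELS:
            raise ValueError(f"disc position must be one of {DISC_POSITION_LABELS}")
        if self.osseous not in OSSEOUS_LABELS:
            raise ValueError(f"osseous condition must be one of {OSSEOUS_LABELS}")


@dataclass
class OverlapResult:
    dsi: float
    volume_t1: float            # mm^3, |M1|
    volume_t2: float            # mm^3, |M2|
    volume_intersection: float  # mm^3, |M1 ∩ M2|


@dataclass
class DistanceResult:
    rmsd: float                 # mm, RMS of pooled bidirectional distances
    hausdorff_max: float        # mm, max of the directed maxima
    distances_12: np.ndarray = field(repr=False)
    distances_21: np.ndarray = field(repr=False)


@dataclass
class RelationResult:
    mxd: float                  # mm, max |signed distance|
    signed_distances: np.ndarray = field(repr=False)
    color_range: tuple[float, float] = (0.0, 0.0)  # (max, min) signed, mm
    colored_mesh: SurfaceMesh | None = None


def dice_similarity(mask_t1: MaskVolume, mask_t2: MaskVolume) -> OverlapResult:
    """Voxel-count Dice overlap of two masks on a common grid."""
    if not mask_t1.same_grid(mask_t2):
        raise ValueError("masks are on different grids; resample to a common grid first")
    n1, n2 = mask_t1.voxel_count, mask_t2.voxel_count
    if n1 == 0 and n2 == 0:
        raise ValueError("both masks are empty")
    inter = int(np.logical_and(mask_t1.data, mask_t2.data).sum())
    vox = mask_t1.voxel_volume_mm3
    return OverlapResult(
        dsi=2.0 * inter / (n1 + n2),
        volume_t1=n1 * vox,
        volume_t2=n2 * vox,
        volume_intersection=inter * vox,
    )


def hausdorff_rmsd(mesh_t1: SurfaceMesh, mesh_t2: SurfaceMesh) -> DistanceResult:
    """Symmetric nearest-point surface distances between two meshes (mm)."""
    if len(mesh_t1) == 0 or len(mesh_t2) == 0:
        raise ValueError("cannot measure distances on an empty mesh")
    d12, _, _ = closest_on_mesh(mesh_t1.vertices, mesh_t2)
    d21, _, _ = closest_on_mesh(mesh_t2.vertices, mesh_t1)
    pooled = np.concatenate([d12, d21])
    return DistanceResult(
        rmsd=float(np.sqrt(np.mean(pooled**2))),
        hausdorff_max=float(max(d12.max(), d21.max())),
        distances_12=d12,
        distances_21=d21,
    )


def distance_map(source: SurfaceMesh, target: SurfaceMesh) -> RelationResult:
    """Per-vertex signed nearest distance from ``source`` to ``target``.

    Positive where the source vertex lies on the outward-normal side of its
    nearest target triangle.  ``mxd`` is the maximum magnitude; the signed
    channel is attached to a copy of the source mesh for PLY export.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("cannot build a distance map on an empty mesh")
    dist, closest, tri_idx = closest_on_mesh(source.vertices, target)
    normals = target.face_normals()[tri_idx]
    side = np.einsum("ij,ij->i", source.vertices - closest, normals)
    signed = dist * np.where(side >= 0, 1.0, -1.0)
    colored = source.with_scalars(signed)
    return RelationResult(
        mxd=float(np.abs(signed).max()),
        signed_distances=signed,
        color_range=(float(signed.max()), float(signed.min())),
        colored_mesh=colored,
    )


@dataclass
class JointModels:
    """One timepoint's segmented structures (masks; meshes derived on demand)."""

    condyle_mask: MaskVolume | None = None
    disc_mask: MaskVolume | None = None
    condyle_mesh: SurfaceMesh | None = None
    disc_mesh: SurfaceMesh | None = None

    def mesh_of(self, structure: str) -> SurfaceMesh | None:
        mesh = getattr(self, f"{structure}_mesh")
        if mesh is None:
            mask = getattr(self, f"{structure}_mask")
            if mask is not None and mask.voxel_count:
                mesh = mask_to_mesh(mask)
                setattr(self, f"{structure}_mesh", mesh)
        return mesh


def joint_change_report(
    t1: JointModels, t2: JointModels, joint_id: int = 0, group: str = "mandibulotomy"
) -> JointRecord:
    """Assemble condyle DSI/RMSD, disc DSI/RMSD and MxD(T1, T2) into one row.

    Missing structures yield missing fields, never an exception.
    """
    values: dict[str, float | None] = {}
    for structure in ("condyle", "disc"):
        m1, m2 = getattr(t1, f"{structure}_mask"), getattr(t2, f"{structure}_mask")
        if m1 is not None and m2 is not None and (m1.voxel_count or m2.voxel_count):
            values[f"{structure}_dsi"] = dice_similarity(m1, m2).dsi
        s1, s2 = t1.mesh_of(structure), t2.mesh_of(structure)
        if s1 is not None and s2 is not None:
            values[f"{structure}_rmsd"] = hausdorff_rmsd(s1, s2).rmsd
    for label, tp in (("mxd_t1", t1), ("mxd_t2", t2)):
        disc, condyle = tp.mesh_of("disc"), tp.mesh_of("condyle")
        if disc is not None and condyle is not None:
            values[label] = distance_map(disc, condyle).mxd
    return JointRecord(joint_id=joint_id, group=group, **values)
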