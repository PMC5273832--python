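"""Synthetic joint phantoms and cohort simulation.

The image phantom stands in for the paired bone-contrast (CBCT-like) and
soft-tissue (MRI-like) acquisitions of one temporomandibular joint: the
condylar head is an upper half-ellipsoid, bright only in the bone volume and
faintly dark (like cortical bone on MRI) in the soft volume; the articular
disc is a biconcave lens seated above the condyle with a stated gap, darkest
structure in the soft volume and invisible in the bone volume.  Analytic
shapes keep every volume and overlap checkable against closed forms:

* half-ellipsoid volume  (2/3) pi a b c
* lens volume            pi R^2 (t_center + t_edge) / 2   for the parabolic
  thickness profile t(rho) = t_c + (t_e - t_c) (rho/R)^2
* sphere-overlap Dice    (4 r + d)(2 r - d)^2 / (16 r^3)  at separation d.

The cohort simulator draws per-joint imaging outcomes and per-patient
clinical outcomes from group-specific truncated normals whose default
moments are the empirical moments of the built-in cohort fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .fixture_tables import load_fixture_cohort
from .grids import MaskVolume, VoxelVolume
from .records import CohortTable, JointRecord, PatientRecord
from .registration import resample_to_common_grid
from .transforms import RigidTransform


@dataclass
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic joint."""

    condyle_semiaxes: tuple[float, float, float] = (9.0, 6.0, 7.0)  # mm
    disc_radius: float = 6.0                 # mm, outer radius of the lens
    disc_center_thickness: float = 1.2       # mm, thin intermediate zone
    disc_edge_thickness: float = 3.0         # mm, thick bands (biconcave)
    gap: float = 0.8                         # mm joint space condyle-disc
    bone_intensity: float = 1.0
    disc_intensity: float = 0.05
    background_intensity: float = 0.35
    soft_bone_intensity: float = 0.18        # condyle as seen in the soft volume
    noise_sd: float = 0.05
    spacing: float = 0.5                     # mm isotropic
    margin: float = 3.0                      # mm padding around the shapes
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = (*self.condyle_semiaxes, self.disc_radius,
                   self.disc_center_thickness, self.disc_edge_thickness,
                   self.spacing, self.margin)
        if any(v <= 0 for v in lengths):
            raise ValueError("all phantom lengths must be > 0")
        if self.disc_edge_thickness < self.disc_center_thickness:
            raise ValueError("biconcave disc requires edge thickness >= center thickness")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    # -- analytic oracles -------------------------------------------------
    def condyle_volume_mm3(self) -> float:
        a, b, c = self.condyle_semiaxes
        return 2.0 / 3.0 * np.pi * a * b * c

    def disc_volume_mm3(self) -> float:
        return np.pi * self.disc_radius**2 * (
            self.disc_center_thickness + self.disc_edge_thickness
        ) / 2.0


def sphere_overlap_dice(radius: float, separation: float) -> float:
    """Dice of two equal balls whose centers are ``separation`` apart."""
    r, d = radius, separation
    if d >= 2 * r:
        return 0.0
    lens = np.pi * (4 * r + d) * (2 * r - d) ** 2 / 12.0
    return float(lens / (4.0 / 3.0 * np.pi * r**3))


def _grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    a, b, c = spec.condyle_semiaxes
    r, m = spec.disc_radius, spec.margin
    top = c + spec.gap + spec.disc_edge_thickness + m
    lo = np.array([-max(a, r) - m, -max(b, r) - m, -m])
    hi = np.array([max(a, r) + m, max(b, r) + m, top])
    shape = np.ceil((hi - lo) / spec.spacing).astype(int) + 1
    origin = lo
    ax = [origin[k] + np.arange(shape[k]) * spec.spacing for k in range(3)]
    x, y, z = np.meshgrid(*ax, indexing="ij", sparse=True)
    return x, y, z, origin, shape


def make_joint_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[VoxelVolume, VoxelVolume, MaskVolume, MaskVolume]:
    """Build (bone_volume, soft_volume, condyle_mask, disc_mask).

    Deterministic under ``spec.seed``; raises if the disc would touch the
    condyle (gap <= 0).
    """
    spec = spec or PhantomSpec()
    if spec.gap <= 0:
        raise ValueError("gap must be > 0: condyle and disc may not overlap")
    a, b, c = spec.condyle_semiaxes
    x, y, z, origin, _shape = _grid(spec)

    condyle = ((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0) & (z >= 0)
    rho2 = x**2 + y**2
    t = spec.disc_center_thickness + (
        spec.disc_edge_thickness - spec.disc_center_thickness
    ) * rho2 / spec.disc_radius**2
    z0 = c + spec.gap + spec.disc_edge_thickness / 2.0
    disc = (rho2 <= spec.disc_radius**2) & (np.abs(z - z0) <= t / 2.0)

    bg = spec.background_intensity
    bone_data = np.where(condyle, spec.bone_intensity, bg).astype(np.float64)
    soft_data = np.where(
        disc, spec.disc_intensity, np.where(condyle, spec.soft_bone_intensity, bg)
    ).astype(np.float64)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        bone_data = bone_data + rng.normal(0.0, spec.noise_sd, bone_data.shape)
        soft_data = soft_data + rng.normal(0.0, spec.noise_sd, soft_data.shape)

    spacing = np.full(3, spec.spacing)
    bone = VoxelVolume(bone_data, spacing, origin)
    soft = VoxelVolume(soft_data, spacing, origin)
    condyle_mask = MaskVolume(condyle.astype(np.uint8), spacing.copy(), origin.copy())
    disc_mask = MaskVolume(disc.astype(np.uint8), spacing.copy(), origin.copy())
    return bone, soft, condyle_mask, disc_mask


def ball_mask(radius: float, spacing: float = 0.5, margin: float = 6.0) -> MaskVolume:
    """A voxelized ball, for overlap/displacement oracles."""
    half = radius + margin
    n = int(np.ceil(2 * half / spacing)) + 1
    origin = np.full(3, -half)
    ax = origin[0] + np.arange(n) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    inside = x**2 + y**2 + z**2 <= radius**2
    return MaskVolume(inside.astype(np.uint8), np.full(3, spacing), origin)


def displace_phantom(masks, transform: RigidTransform):
    """Resample Time-1 masks under a rigid transform to obtain Time-2 masks.

    ``masks`` may be a single :class:`MaskVolume` or a dict of them; the
    structure is preserved.  Nearest-neighbor resampling keeps voxel counts
    within interpolation tolerance (~2%).
    """
    if isinstance(masks, dict):
        return {k: displace_phantom(v, transform) for k, v in masks.items()}
    return resample_to_common_grid(masks, transform, masks, order=0)


def misalign_modality(soft_volume: VoxelVolume, transform: RigidTransform) -> VoxelVolume:
    """Apply a known rigid misalignment to the soft-tissue volume.

    The returned volume is ``soft(T^-1 x)``; registration against the bone
    volume should recover ``transform.inverse()`` (equivalently, composing
    the recovered transform with ``transform`` gives identity).  Regions
    swept in from outside the original extent are filled by edge replication
    (a real acquisition has tissue there, not void).
    """
    return resample_to_common_grid(soft_volume, transform, soft_volume, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

JOINT_OUTCOMES = ("condyle_dsi", "condyle_rmsd", "disc_dsi", "disc_rmsd", "mxd_t1", "mxd_t2")
PATIENT_OUTCOMES = ("mouth_opening_t1", "mouth_opening_t2", "jfls_t1", "jfls_t2")
_BOUNDS = {
    "condyle_dsi": (0.0, 1.0),
    "disc_dsi": (0.0, 1.0),
    "condyle_rmsd": (0.0, np.inf),
    "disc_rmsd": (0.0, np.inf),
    "mxd_t1": (0.0, np.inf),
    "mxd_t2": (0.0, np.inf),
    "mouth_opening_t1": (1e-6, np.inf),
    "mouth_opening_t2": (1e-6, np.inf),
    "jfls_t1": (0.0, 50.0),
    "jfls_t2": (0.0, 50.0),
}


def fixture_moments() -> dict:
    """Per-group empirical means and sds of every outcome in the fixture."""
    table = load_fixture_cohort()
    out: dict = {}
    for group in ("mandibulotomy", "transoral"):
        sub = table.subset(group)
        jf, pf = sub.joints_frame(), sub.patients_frame()
        means, sds = {}, {}
        for col in JOINT_OUTCOMES:
            means[col] = float(jf[col].mean())
            sds[col] = float(jf[col].std(ddof=1))
        for col in PATIENT_OUTCOMES:
            means[col] = float(pf[col].mean())
            sds[col] = float(pf[col].std(ddof=1))
        out[group] = {"means": means, "sds": sds}
    return out


@dataclass
class CohortSimSpec:
    """Statistical structure of a simulated two-arm cohort."""

    group_sizes: dict = field(default_factory=lambda: {"mandibulotomy": 9, "transoral": 7})
    moments: dict = field(default_factory=fixture_moments)  # per-group means/sds
    jfls_rounding: str = "round"  # "round" or "floor"
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 patients, got {n}")
        for g, m in self.moments.items():
            if any(sd < 0 for sd in m["sds"].values()):
                raise ValueError(f"group {g!r} has a negative sd")


def _draw(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, min(hi, np.finfo(float).max))))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(spec: CohortSimSpec | None = None) -> CohortTable:
    """Draw a cohort with the configured group-specific outcome distributions.

    DSI values are truncated to [0, 1], distances to [0, inf), JFLS totals
    are integers in [0, 50]; deterministic under ``spec.seed``.
    """
    spec = spec or CohortSimSpec()
    rng = np.random.default_rng(spec.seed)
    patients, joints = [], []
    pid = jid = 0
    for group in sorted(spec.group_sizes):
        n_pat = spec.group_sizes[group]
        n_joint = 2 * n_pat
        m = spec.moments[group]
        jdraw = {
            c: _draw(rng, m["means"][c], m["sds"][c], *_BOUNDS[c], n_joint)
            for c in JOINT_OUTCOMES
        }
        pdraw = {
            c: _draw(rng, m["means"][c], m["sds"][c], *_BOUNDS[c], n_pat)
            for c in PATIENT_OUTCOMES
        }
        round_fn = np.floor if spec.jfls_rounding == "floor" else np.round
        for c in ("jfls_t1", "jfls_t2"):
            pdraw[c] = round_fn(pdraw[c]).astype(int)
        for i in range(n_pat):
            pid += 1
            jids = (jid + 1, jid + 2)
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    group=group,
                    joint_ids=jids,
                    **{c: pdraw[c][i] for c in PATIENT_OUTCOMES},
                )
            )
            for local, k in zip((2 * i, 2 * i + 1), jids):
                joints.append(
                    JointRecord(
                        joint_id=k,
                        group=group,
                        **{c: float(jdraw[c][local]) for c in JOINT_OUTCOMES},
                    )
                )
            jid += 2
    return CohortTable(patients=patients, joints=joints, metadata={"simulated": True, "seed": spec.seed})
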