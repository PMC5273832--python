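"""End-to-end orchestration: register → segment → mesh → measure → report.

``run_joint`` processes one joint's paired timepoints (bone volume +
soft-tissue volume each) into a per-joint outcome row plus mesh artifacts;
``run_cohort`` turns a cohort table into the group-average, between-group
difference, and correlation outputs.  Every stage's parameters are logged so
runs are auditable and reproducible: re-running an identical config writes
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .grids import MaskVolume, VoxelVolume
from .io import export_cohort_csv, write_mesh, write_scalar_mesh
from .morphometry import JointModels, distance_map, joint_change_report
from .records import CohortTable
from .registration import RegistrationConfig, register_rigid, resample_to_common_grid
from .segmentation import SegmentationConfig, threshold_segment
from .stats import (
    between_group_comparison,
    correlation_matrix,
    correlation_r_frame,
    group_averages,
)

log = logging.getLogger("tmjmorph")


@dataclass
class RunConfig:
    """Serializable configuration of a full run."""

    out_dir: str = "tmjmorph_out"
    seed: int = 0
    register: bool = True
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    condyle_segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(threshold="auto", polarity="bright")
    )
    disc_segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(
            threshold=0.12, polarity="dark", presmooth_sigma=0.5
        )
    )
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "registration" in d and isinstance(d["registration"], dict):
            reg = dict(d["registration"])
            if "grid_offsets_mm" in reg:
                reg["grid_offsets_mm"] = tuple(reg["grid_offsets_mm"])
            d["registration"] = RegistrationConfig(**reg)
        for key in ("condyle_segmentation", "disc_segmentation"):
            if key in d and isinstance(d[key], dict):
                d[key] = SegmentationConfig(**d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class TimepointInputs:
    """One acquisition: bone-contrast volume plus (optionally misaligned)
    soft-tissue volume; an optional precomputed disc mask bypasses the
    dark-threshold path (the clinical disc is manually segmented)."""

    bone: VoxelVolume
    soft: VoxelVolume | None = None
    disc_mask: MaskVolume | None = None


def _segment_timepoint(inputs: TimepointInputs, config: RunConfig, label: str) -> JointModels:
    if config.register and inputs.soft is not None:
        result = register_rigid(inputs.bone, inputs.soft, config.registration)
        log.info(
            "%s: registration MI=%.4f nats, iterations=%d, converged=%s, transform=%s",
            label, result.mutual_information, result.iterations, result.converged,
            result.transform.to_dict(),
        )
        # edge replication: constant-fill voids would masquerade as "dark
        # tissue" to the disc threshold
        soft = resample_to_common_grid(inputs.soft, result.transform, inputs.bone, mode="nearest")
    else:
        soft = inputs.soft

    condyle = threshold_segment(inputs.bone, config.condyle_segmentation)
    log.info("%s: condyle segmentation %d voxels (config=%s)", label,
             condyle.voxel_count, config.condyle_segmentation)
    disc = inputs.disc_mask
    if disc is None and soft is not None:
        disc = threshold_segment(soft, config.disc_segmentation)
        log.info("%s: disc segmentation %d voxels (config=%s)", label,
                 disc.voxel_count, config.disc_segmentation)
    if disc is None:
        log.warning("%s: no soft-tissue volume or disc mask; disc outcomes will be missing", label)
    return JointModels(condyle_mask=condyle, disc_mask=disc)


def run_joint(
    t1: TimepointInputs,
    t2: TimepointInputs,
    config: RunConfig | None = None,
    joint_id: int = 1,
    group: str = "mandibulotomy",
):
    """Process one joint at two timepoints into a JointRecord + artifacts.

    Returns ``(record, models_t1, models_t2)``; STL models and the
    disc-condyle color-map PLY are written under ``config.out_dir``.
    """
    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    models_t1 = _segment_timepoint(t1, config, f"joint{joint_id}/T1")
    models_t2 = _segment_timepoint(t2, config, f"joint{joint_id}/T2")
    record = joint_change_report(models_t1, models_t2, joint_id=joint_id, group=group)

    for label, models in (("t1", models_t1), ("t2", models_t2)):
        for structure in ("condyle", "disc"):
            mesh = models.mesh_of(structure)
            if mesh is not None:
                write_mesh(mesh, out / f"joint{joint_id}_{structure}_{label}.stl")
    disc_t2, condyle_t2 = models_t2.mesh_of("disc"), models_t2.mesh_of("condyle")
    if disc_t2 is not None and condyle_t2 is not None:
        rel = distance_map(disc_t2, condyle_t2)
        write_scalar_mesh(rel.colored_mesh, out / f"joint{joint_id}_disc_condyle_map_t2.ply")
        log.info("joint%d: MxD(T2)=%.2f mm, color range %.2f to %.2f mm",
                 joint_id, rel.mxd, *rel.color_range)
    d1, d2 = models_t1.mesh_of("disc"), models_t2.mesh_of("disc")
    if d1 is not None and d2 is not None:
        rel12 = distance_map(d2, d1)
        write_scalar_mesh(rel12.colored_mesh, out / f"joint{joint_id}_disc_change_map.ply")

    row = {k: getattr(record, k) for k in (
        "joint_id", "group", "condyle_dsi", "condyle_rmsd",
        "disc_dsi", "disc_rmsd", "mxd_t1", "mxd_t2")}
    csv_path = out / f"joint{joint_id}_record.csv"
    header = ",".join(row)
    values = ",".join("NA" if v is None else str(v) for v in row.values())
    csv_path.write_text(header + "\n" + values + "\n")
    return record, models_t1, models_t2


def run_cohort(table: CohortTable, out_dir: str | Path) -> dict:
    """Cohort statistics and report from an assembled outcome table.

    Writes group averages, the between-group difference table (per-outcome
    mean differences with 95% CIs and the Hotelling T² summary), the
    Spearman correlation matrix, the cohort CSV, and a markdown report.
    """
    if not table.patients:
        raise ValueError("cohort is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    averages = group_averages(table)
    averages.to_csv(out / "group_averages.csv")
    comparison = between_group_comparison(table)
    diff_rows = [dataclasses.asdict(o) for o in comparison.outcome_differences]
    import pandas as pd

    diff_frame = pd.DataFrame(diff_rows)
    diff_frame.to_csv(out / "between_group_differences.csv", index=False)
    corr = correlation_matrix(table)
    corr_r = correlation_r_frame(corr)
    corr_r.to_csv(out / "correlation_matrix.csv")
    export_cohort_csv(table, out / "cohort.csv")

    summary = {
        "hotelling": {
            "t2": comparison.t2,
            "f": comparison.f_statistic,
            "df": [comparison.df1, comparison.df2],
            "p_value": comparison.p_value,
        },
        "group_sizes": {g: list(v) for g, v in table.group_sizes().items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    lines = ["# Cohort report", "", "## Group averages", "",
             averages.round(2).to_markdown(), "",
             "## Between-group differences (group A − group B, 95% CI)", "",
             diff_frame.round(3).to_markdown(index=False), "",
             f"Hotelling T² = {comparison.t2:.2f}, "
             f"F({comparison.df1}, {comparison.df2}) = {comparison.f_statistic:.2f}, "
             f"p = {comparison.p_value:.3g}", "",
             "## Spearman correlations (pooled groups, * p < 0.05)", "",
             corr_r.to_markdown(), ""]
    (out / "report.md").write_text("\n".join(lines))
    return {"averages": averages, "comparison": comparison, "correlations": corr,
            "summary": summary}
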