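"""Cohort data model: per-joint and per-patient outcome rows.

One :class:`JointRecord` mirrors a row of the study-style outcome table
(condyle/disc overlap and surface-distance metrics plus the disc-condyle
MxD at both timepoints); one :class:`PatientRecord` owns exactly two joints
and the clinical outcomes (maximum interincisal mouth opening in mm and the
10-item Jaw Function Limitation Scale total, 0-50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("mandibulotomy", "transoral")

JOINT_COLUMNS = [
    "joint_id",
    "patient_id",
    "group",
    "condyle_dsi",
    "condyle_rmsd",
    "disc_dsi",
    "disc_rmsd",
    "mxd_t1",
    "mxd_t2",
]
PATIENT_COLUMNS = [
    "patient_id",
    "group",
    "mouth_opening_t1",
    "mouth_opening_t2",
    "jfls_t1",
    "jfls_t2",
    "age",
    "sex",
    "tumor",
]


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _check_range(name: str, value, lo: float | None, hi: float | None) -> float | None:
    if _is_missing(value):
        return None
    value = float(value)
    if lo is not None and value < lo or hi is not None and value > hi:
        raise ValueError(f"{name}={value} outside valid range [{lo}, {hi}]")
    return value


@dataclass
class JointRecord:
    joint_id: int
    group: str
    condyle_dsi: float | None = None
    condyle_rmsd: float | None = None
    disc_dsi: float | None = None
    disc_rmsd: float | None = None
    mxd_t1: float | None = None
    mxd_t2: float | None = None
    patient_id: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        self.condyle_dsi = _check_range("condyle_dsi", self.condyle_dsi, 0.0, 1.0)
        self.disc_dsi = _check_range("disc_dsi", self.disc_dsi, 0.0, 1.0)
        self.condyle_rmsd = _check_range("condyle_rmsd", self.condyle_rmsd, 0.0, None)
        self.disc_rmsd = _check_range("disc_rmsd", self.disc_rmsd, 0.0, None)
        self.mxd_t1 = _check_range("mxd_t1", self.mxd_t1, 0.0, None)
        self.mxd_t2 = _check_range("mxd_t2", self.mxd_t2, 0.0, None)

    @property
    def mxd_change(self) -> float | None:
        if self.mxd_t1 is None or self.mxd_t2 is None:
            return None
        return self.mxd_t2 - self.mxd_t1


@dataclass
class PatientRecord:
    patient_id: int
    group: str
    joint_ids: tuple[int, int]
    mouth_opening_t1: float | None = None
    mouth_opening_t2: float | None = None
    jfls_t1: int | None = None
    jfls_t2: int | None = None
    age: float | None = None
    sex: str | None = None
    tumor: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if len(self.joint_ids) != 2:
            raise ValueError("each patient owns exactly two joints")
        self.joint_ids = tuple(int(j) for j in self.joint_ids)
        for name in ("mouth_opening_t1", "mouth_opening_t2"):
            v = _check_range(name, getattr(self, name), 0.0, None)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 mm")
            setattr(self, name, v)
        for name in ("jfls_t1", "jfls_t2"):
            v = _check_range(name, getattr(self, name), 0, 50)
            setattr(self, name, None if v is None else int(v))

    @property
    def mouth_opening_decrease(self) -> float | None:
        if self.mouth_opening_t1 is None or self.mouth_opening_t2 is None:
            return None
        return self.mouth_opening_t1 - self.mouth_opening_t2

    @property
    def jfls_increase(self) -> float | None:
        if self.jfls_t1 is None or self.jfls_t2 is None:
            return None
        return self.jfls_t2 - self.jfls_t1


@dataclass
class CohortTable:
    """All patients and joints of a two-arm cohort."""

    patients: list[PatientRecord]
    joints: list[JointRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        owner: dict[int, int] = {}
        for p in self.patients:
            for j in p.joint_ids:
                if j in owner:
                    raise ValueError(f"joint {j} claimed by patients {owner[j]} and {p.patient_id}")
                owner[j] = p.patient_id
        for rec in self.joints:
            if rec.joint_id not in owner:
                raise ValueError(f"joint {rec.joint_id} belongs to no patient")
            if rec.patient_id is None:
                rec.patient_id = owner[rec.joint_id]
            elif rec.patient_id != owner[rec.joint_id]:
                raise ValueError(f"joint {rec.joint_id} owner mismatch")

    def group_sizes(self) -> dict[str, tuple[int, int]]:
        """{group: (n_patients, n_joints)}."""
        out = {}
        for g in GROUPS:
            out[g] = (
                sum(p.group == g for p in self.patients),
                sum(j.group == g for j in self.joints),
            )
        return out

    def joints_frame(self) -> pd.DataFrame:
        rows = [{c: getattr(j, c) for c in JOINT_COLUMNS} for j in self.joints]
        return pd.DataFrame(rows, columns=JOINT_COLUMNS).astype({"joint_id": int})

    def patients_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            row = {c: getattr(p, c) for c in PATIENT_COLUMNS}
            row["joint_ids"] = "{}|{}".format(*p.joint_ids)
            rows.append(row)
        return pd.DataFrame(rows, columns=PATIENT_COLUMNS + ["joint_ids"])

    def joints_with_clinical(self) -> pd.DataFrame:
        """Per-joint frame with the owning patient's clinical values replicated.

        The unit of analysis for imaging and imaging-clinical correlations is
        the joint; clinical outcomes are measured per patient and attached to
        both of the patient's joints.
        """
        jf = self.joints_frame()
        pf = self.patients_frame().drop(columns=["group", "joint_ids"])
        merged = jf.merge(pf, on="patient_id", how="left", validate="many_to_one")
        merged["mxd_change"] = merged["mxd_t2"] - merged["mxd_t1"]
        merged["mouth_opening_decrease"] = merged["mouth_opening_t1"] - merged["mouth_opening_t2"]
        merged["jfls_increase"] = merged["jfls_t2"] - merged["jfls_t1"]
        return merged

    def subset(self, group: str) -> "CohortTable":
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}")
        return CohortTable(
            patients=[p for p in self.patients if p.group == group],
            joints=[j for j in self.joints if j.group == group],
            metadata=dict(self.metadata),
        )

    def equals(self, other: "CohortTable") -> bool:
        a, b = self.joints_frame(), other.joints_frame()
        c, d = self.patients_frame(), other.patients_frame()
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
            pd.testing.assert_frame_equal(c, d, check_dtype=False)
        except AssertionError:
            return False
        return True

    @staticmethod
    def nan_to_none(value):
        return None if (value is None or (isinstance(value, float) and np.isnan(value))) else value
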