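"""Cohort statistics: JFLS scoring, Hotelling T², Spearman, power.

The unit of analysis is the joint (n = 2 per patient) for imaging outcomes
and imaging-clinical correlations, with each patient's clinical values
replicated to both joints; clinical-only summaries use patients.  Missing
cells are handled by pairwise deletion throughout — never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import CohortTable

# ---------------------------------------------------------------------------
# JFLS
# ---------------------------------------------------------------------------

JFLS_ITEMS = (
    "talking for a long period",
    "grinding thin foods",
    "prolonged chewing",
    "activity at home/school/work",
    "clenching teeth during sports",
    "opening mouth widely",
    "yawning",
    "brushing back teeth",
    "falling asleep",
    "sleeping through the night",
)


@dataclass
class JFLSResponse:
    """Ten limitation items, each scored 0 (none) to 5 (extreme)."""

    items: tuple

    def __post_init__(self) -> None:
        items = tuple(self.items)
        if len(items) != 10:
            raise ValueError(f"JFLS has 10 items, got {len(items)}")
        for i, v in enumerate(items):
            if int(v) != v or not 0 <= v <= 5:
                raise ValueError(f"JFLS item {i + 1} must be an integer 0-5, got {v}")
        self.items = tuple(int(v) for v in items)


def jfls_total(response: JFLSResponse | tuple) -> int:
    """Total limitation score: the sum of the ten items (0-50)."""
    if not isinstance(response, JFLSResponse):
        response = JFLSResponse(response)
    return sum(response.items)


# ---------------------------------------------------------------------------
# change scores
# ---------------------------------------------------------------------------

JOINT_CHANGE_OUTCOMES = [
    "condyle_dsi",
    "condyle_rmsd",
    "disc_dsi",
    "disc_rmsd",
    "mxd_change",
    "mouth_opening_decrease",
    "jfls_increase",
]


def outcome_differences(table: CohortTable) -> dict[str, pd.DataFrame]:
    """Per-unit change scores.

    ``joints``: per-joint frame including MxD change (T2 − T1) and the
    owning patient's clinical changes replicated; ``patients``: per-patient
    mouth-opening decrease (T1 − T2) and JFLS increase (T2 − T1).  Missing
    cells propagate as missing.
    """
    joints = table.joints_with_clinical()
    pf = table.patients_frame()
    pf["mouth_opening_decrease"] = pf["mouth_opening_t1"] - pf["mouth_opening_t2"]
    pf["jfls_increase"] = pf["jfls_t2"] - pf["jfls_t1"]
    return {"joints": joints, "patients": pf}


def group_averages(table: CohortTable) -> pd.DataFrame:
    """Per-group means of every outcome, in the layout of the study tables."""
    diffs = outcome_differences(table)
    jf, pf = diffs["joints"], diffs["patients"]
    rows = []
    for group in sorted({p.group for p in table.patients}):
        jg = jf[jf["group"] == group]
        pg = pf[pf["group"] == group]
        rows.append(
            {
                "group": group,
                "n_patients": len(pg),
                "n_joints": len(jg),
                "condyle_dsi": jg["condyle_dsi"].mean(),
                "condyle_rmsd": jg["condyle_rmsd"].mean(),
                "disc_dsi": jg["disc_dsi"].mean(),
                "disc_rmsd": jg["disc_rmsd"].mean(),
                "mxd_t1": jg["mxd_t1"].mean(),
                "mxd_t2": jg["mxd_t2"].mean(),
                "mxd_change": jg["mxd_change"].mean(),
                "mouth_opening_t1": pg["mouth_opening_t1"].mean(),
                "mouth_opening_t2": pg["mouth_opening_t2"].mean(),
                "mouth_opening_decrease": pg["mouth_opening_decrease"].mean(),
                "jfls_t1": pg["jfls_t1"].mean(),
                "jfls_t2": pg["jfls_t2"].mean(),
                "jfls_increase": pg["jfls_increase"].mean(),
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Hotelling T²
# ---------------------------------------------------------------------------


@dataclass
class OutcomeDifference:
    name: str
    mean_difference: float
    std_error: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class HotellingResult:
    t2: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    outcome_differences: list[OutcomeDifference] = field(default_factory=list)


def hotelling_two_sample(
    group_a: np.ndarray, group_b: np.ndarray, outcome_names: list[str] | None = None
) -> HotellingResult:
    """Classical two-sample Hotelling T² with pooled covariance.

    ``group_a`` and ``group_b`` are (n, p) complete-case outcome matrices.
    The p-value comes from the exact F conversion
    ``F = T² (n1 + n2 - p - 1) / ((n1 + n2 - 2) p)`` with (p, n1+n2-p-1)
    degrees of freedom.  Per-outcome mean differences (a − b) carry pooled-t
    standard errors and 95% CIs.
    """
    A = np.atleast_2d(np.asarray(group_a, dtype=float))
    B = np.atleast_2d(np.asarray(group_b, dtype=float))
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("groups must be (n, p) matrices with matching p")
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("Hotelling T² requires complete cases; drop missing rows first")
    n1, n2, p = len(A), len(B), A.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 units")
    if n1 + n2 - p - 1 < 1:
        raise ValueError(f"too few units ({n1}+{n2}) for {p} outcomes")
    d = A.mean(axis=0) - B.mean(axis=0)
    S = ((n1 - 1) * np.cov(A, rowvar=False, ddof=1).reshape(p, p)
         + (n2 - 1) * np.cov(B, rowvar=False, ddof=1).reshape(p, p)) / (n1 + n2 - 2)
    try:
        solve = np.linalg.solve(S, d)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; reduce or decorrelate the outcome set"
        ) from exc
    t2 = float(n1 * n2 / (n1 + n2) * d @ solve)
    df1, df2 = p, n1 + n2 - p - 1
    f_stat = t2 * df2 / ((n1 + n2 - 2) * p)
    p_value = float(sps.f.sf(f_stat, df1, df2))

    names = outcome_names or [f"outcome_{i + 1}" for i in range(p)]
    tcrit = sps.t.ppf(0.975, n1 + n2 - 2)
    diffs = []
    for j, name in enumerate(names):
        se = math.sqrt(S[j, j] * (1 / n1 + 1 / n2))
        tj = d[j] / se if se > 0 else np.inf * np.sign(d[j])
        diffs.append(
            OutcomeDifference(
                name=name,
                mean_difference=float(d[j]),
                std_error=float(se),
                ci_low=float(d[j] - tcrit * se),
                ci_high=float(d[j] + tcrit * se),
                p_value=float(2 * sps.t.sf(abs(tj), n1 + n2 - 2)),
            )
        )
    return HotellingResult(
        t2=t2, f_statistic=float(f_stat), df1=df1, df2=df2, p_value=p_value,
        outcome_differences=diffs,
    )


# ---------------------------------------------------------------------------
# Spearman correlation with strength bands
# ---------------------------------------------------------------------------

STRENGTH_BANDS = (  # upper edge (inclusive) of |r|, label
    (0.3, "negligible"),
    (0.5, "low"),
    (0.7, "moderate"),
    (0.9, "high"),
    (1.0, "very high"),
)


def strength_label(r: float) -> str:
    """Band the correlation magnitude: ≤0.3 negligible, ≤0.5 low, ≤0.7
    moderate, ≤0.9 high, else very high (closing the published guide's gaps
    at the band edges)."""
    a = abs(r)
    for edge, label in STRENGTH_BANDS:
        if a <= edge + 1e-12:
            return label
    return "very high"


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    strength: str
    n: int


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties and pairwise deletion."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need at least 3 complete pairs, got {len(x)}")
    res = sps.spearmanr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, p_value=float(res.pvalue), strength=strength_label(r), n=len(x))


def correlation_matrix(table: CohortTable, alpha: float = 0.05) -> pd.DataFrame:
    """Pooled-both-groups Spearman correlations among the change outcomes.

    Outcomes are per joint, with each patient's clinical change replicated to
    the patient's two joints.  Entries are :class:`CorrelationResult`; the
    diagonal is None.  Symmetric.
    """
    jf = outcome_differences(table)["joints"]
    cols = JOINT_CHANGE_OUTCOMES
    out = pd.DataFrame(index=cols, columns=cols, dtype=object)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            res = spearman(jf[a].to_numpy(float), jf[b].to_numpy(float))
            out.loc[a, b] = res
            out.loc[b, a] = res
    return out


def correlation_r_frame(matrix: pd.DataFrame) -> pd.DataFrame:
    """Numeric r values (with significance stars) from a correlation matrix."""
    def fmt(cell):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return ""
        star = "*" if cell.p_value < 0.05 else ""
        return f"{cell.r:.2f}{star}"

    return matrix.map(fmt)


# ---------------------------------------------------------------------------
# power / sample size
# ---------------------------------------------------------------------------


@dataclass
class PowerSpec:
    """Two-arm sample-size computation for a Cohen-style effect size f."""

    effect_size_f: float = 0.8
    alpha: float = 0.05
    power: float = 0.8
    mcid_points: float = 5.4     # minimum clinically important JFLS difference
    dropout: float = 0.0         # expected dropout fraction

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.effect_size_f <= 0:
            raise ValueError("effect size must be > 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class SampleSizeResult:
    n_per_arm: int
    n_recruited_per_arm: int
    total_n: int
    achieved_power_exact: float


def exact_power_two_groups(n_per_arm: int, effect_size_f: float, alpha: float = 0.05) -> float:
    """Exact noncentral-F power of the two-group comparison at Cohen's f."""
    N = 2 * n_per_arm
    lam = effect_size_f**2 * N
    fcrit = sps.f.ppf(1 - alpha, 1, N - 2)
    return float(sps.ncf.sf(fcrit, 1, N - 2, lam))


def sample_size(spec: PowerSpec | None = None) -> SampleSizeResult:
    """Per-arm n for a two-group comparison, normal-approximation convention.

    Uses the classical table formula ``N = ((z_{1-α/2} + z_{power}) / f)²``
    rounded up and split across the two arms (at α = 0.05, power = 0.8,
    f = 0.8 this gives 7 per arm, as the standard power tables list; the
    exact noncentral-F power at that n is also reported).  Dropout inflates
    recruitment by 1 / (1 − dropout).
    """
    spec = spec or PowerSpec()
    z = sps.norm.ppf(1 - spec.alpha / 2) + sps.norm.ppf(spec.power)
    if z <= 0:
        n_per_arm = 2
    else:
        total = (z / spec.effect_size_f) ** 2
        n_per_arm = max(2, math.ceil(total / 2))
    recruited = math.ceil(n_per_arm / (1 - spec.dropout))
    return SampleSizeResult(
        n_per_arm=n_per_arm,
        n_recruited_per_arm=recruited,
        total_n=2 * n_per_arm,
        achieved_power_exact=exact_power_two_groups(n_per_arm, spec.effect_size_f, spec.alpha),
    )


# ---------------------------------------------------------------------------
# convenience: the full between-group comparison of a cohort table
# ---------------------------------------------------------------------------

COMPARISON_OUTCOMES = JOINT_CHANGE_OUTCOMES


def between_group_comparison(table: CohortTable, outcomes: list[str] | None = None) -> HotellingResult:
    """Hotelling T² comparison (first group listed minus second) on per-joint
    change outcomes, complete-case."""
    outcomes = outcomes or COMPARISON_OUTCOMES
    jf = outcome_differences(table)["joints"]
    groups = sorted(jf["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    sub = jf[["group"] + outcomes].dropna()
    A = sub[sub["group"] == groups[0]][outcomes].to_numpy(float)
    B = sub[sub["group"] == groups[1]][outcomes].to_numpy(float)
    return hotelling_two_sample(A, B, outcome_names=outcomes)
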