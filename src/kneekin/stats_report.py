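"""Descriptive summaries and paired/unpaired t comparisons of kinematics records.

Mirrors the study's statistical treatment of the measured parameters:
per-cell mean +- SD tables (sample SD, n-1 denominator, one decimal) and
two-sided Student t-tests — paired within a group across conditions,
unpaired between groups within a condition.  The unpaired default is the
pooled-variance test (matching the era's statistics-package default); the
Welch variant is available via ``welch=True``.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05

#: Measured quantities that appear in summary tables.
SUMMARY_PARAMS = (
    "medial_ap", "lateral_ap", "central_ap", "rotation",
    "height", "pf_angle", "tilt", "shift",
)

PF_TABLE_PARAMS = ("height", "pf_angle", "tilt", "shift")

PARAM_LABELS = {
    "height": "Patellar height [mm]",
    "pf_angle": "Femoro-patellar angle [deg]",
    "tilt": "Tilt angle [deg]",
    "shift": "Patellar shift (to lateral) [mm]",
    "medial_ap": "Medial condyle AP [mm]",
    "lateral_ap": "Lateral condyle AP [mm]",
    "central_ap": "Central point AP [mm]",
    "rotation": "Epicondylar rotation [deg]",
}


class StatsError(ValueError):
    """Raised for malformed comparison inputs."""


@dataclass
class TTestResult:
    """Two-sided t-test result; ``degenerate`` flags a zero-variance input."""

    t: float
    df: float
    p: float
    significant: bool
    degenerate: bool = False


def summarize(records: pd.DataFrame,
              params: tuple[str, ...] = SUMMARY_PARAMS) -> pd.DataFrame:
    """Per group x condition x parameter: sample mean, SD (n-1), n.

    Every cell must hold at least two records.
    """
    params = [p for p in params if p in records.columns]
    rows = []
    for (group, flexion, muscle), cell in records.groupby(["group", "flexion", "muscle"]):
        for p in params:
            vals = cell[p].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                raise StatsError(
                    f"cell {group}/{flexion}/{muscle}/{p} has {len(vals)} records (< 2)"
                )
            rows.append(dict(
                group=group, flexion=int(flexion), muscle=muscle, parameter=p,
                mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n=len(vals),
            ))
    return pd.DataFrame(rows)


def _paired_t(diffs: np.ndarray) -> TTestResult:
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 2:
        raise StatsError("paired test needs >= 2 pairs")
    sd = diffs.std(ddof=1)
    if sd == 0:
        if np.all(diffs == 0):  # identical conditions: no difference at all
            return TTestResult(0.0, n - 1, 1.0, False)
        return TTestResult(np.nan, n - 1, np.nan, False, degenerate=True)
    t = diffs.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(float(t), n - 1, float(p), p < ALPHA)


def paired_compare(
    records: pd.DataFrame,
    condition_a: tuple[int, str],
    condition_b: tuple[int, str],
    parameter: str,
    group: str | None = None,
) -> TTestResult:
    """Paired Student t on within-subject differences between two conditions.

    Conditions are (flexion, muscle) keys; every subject must appear in
    both.  df = n - 1, two-sided p.
    """
    df = records if group is None else records[records["group"] == group]

    def cell(key):
        sub = df[(df["flexion"] == key[0]) & (df["muscle"] == key[1])]
        return sub.set_index("subject")[parameter]

    a, b = cell(condition_a), cell(condition_b)
    if set(a.index) != set(b.index):
        raise StatsError("paired comparison requires matched subjects in both conditions")
    diffs = (b - a.reindex(b.index)).to_numpy(dtype=float)
    return _paired_t(diffs)


def _unpaired_t(x: np.ndarray, y: np.ndarray, welch: bool) -> TTestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("unpaired test needs n >= 2 per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        return TTestResult(np.nan, len(x) + len(y) - 2, np.nan, False, degenerate=True)
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    if welch:
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        dof = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    else:
        dof = len(x) + len(y) - 2
    return TTestResult(float(t), float(dof), float(p), p < ALPHA)


def unpaired_compare(
    records: pd.DataFrame,
    group_a: str,
    group_b: str,
    condition: tuple[int, str],
    parameter: str,
    welch: bool = False,
) -> TTestResult:
    """Two-sample Student t between groups within one condition.

    Pooled variance by default; ``welch=True`` drops the equal-variance
    assumption (Welch-Satterthwaite df).
    """
    def cell(group):
        sub = records[(records["group"] == group)
                      & (records["flexion"] == condition[0])
                      & (records["muscle"] == condition[1])]
        return sub[parameter].dropna().to_numpy(dtype=float)

    return _unpaired_t(cell(group_a), cell(group_b), welch)


def compare_groups_all(
    records: pd.DataFrame,
    group_a: str = "healthy",
    group_b: str = "pcl_deficient",
    params: tuple[str, ...] = SUMMARY_PARAMS,
    welch: bool = False,
) -> pd.DataFrame:
    """Unpaired group comparison for every condition x parameter."""
    conditions = sorted(
        {(int(f), m) for f, m in records[["flexion", "muscle"]].itertuples(index=False)}
    )
    rows = []
    for cond in conditions:
        for p in params:
            if p not in records.columns:
                continue
            r = unpaired_compare(records, group_a, group_b, cond, p, welch=welch)
            rows.append(dict(group_a=group_a, group_b=group_b,
                             flexion=cond[0], muscle=cond[1], parameter=p,
                             t=r.t, df=r.df, p=r.p, significant=r.significant))
    return pd.DataFrame(rows)


def significance_pattern(comparisons: pd.DataFrame) -> bool:
    """True when the group differences match the published pattern:

    tilt and shift significant at 90 degrees (both muscle states) and at no
    other flexion angle; patellar height and patellofemoral angle not
    significant in any condition.
    """
    pf = comparisons[comparisons["parameter"].isin(PF_TABLE_PARAMS)]
    for row in pf.itertuples():
        expected = row.parameter in ("tilt", "shift") and row.flexion == 90
        if bool(row.significant) != expected:
            return False
    return True


def format_pf_table(summary: pd.DataFrame) -> str:
    """Aligned plain-text mirror of the patellofemoral summary table.

    One block per group, rows = the four parameters, columns = the six
    conditions, cells formatted ``mean +- SD`` to one decimal.
    """
    conditions = [(f, m) for f in (0, 30, 90) for m in ("relaxed", "active")]
    col_heads = [f"{f}deg {'flex.' if m == 'active' else ''}".strip()
                 for f, m in conditions]
    lines = []
    for group, sub in summary.groupby("group"):
        lines.append(f"== {group} ==")
        head = f"{'parameter':<34}" + "".join(f"{h:>16}" for h in col_heads)
        lines.append(head)
        for p in PF_TABLE_PARAMS:
            cells = []
            for f, m in conditions:
                row = sub[(sub["parameter"] == p) & (sub["flexion"] == f)
                          & (sub["muscle"] == m)]
                if len(row) == 1:
                    cells.append(f"{row['mean'].iloc[0]:.1f} ± {row['sd'].iloc[0]:.1f}")
                else:
                    cells.append("-")
            lines.append(f"{PARAM_LABELS[p]:<34}" + "".join(f"{c:>16}" for c in cells))
        lines.append("")
    return "\n".join(lines)
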