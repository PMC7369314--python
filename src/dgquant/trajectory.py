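"""Group trajectory tables, attrition metrics, and effect sizes.

Per-animal endpoints (densities, co-expression percentages, morphology
fractions) are aggregated into mean ± SEM per sex x region x time point —
the shape of the study's figure panels — plus two effect-size primitives,
Cohen's d and partial eta squared.  Omnibus repeated-measures ANOVA and post
hoc machinery are deliberately not re-implemented: the tidy long-format
output is designed to be handed to any stats package.

SEM uses the sample standard deviation (n - 1 denominator); groups of one
animal report a mean with SEM absent rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ENDPOINTS",
    "TrajectorySummary",
    "summarize",
    "attrition",
    "cohens_d",
    "partial_eta_sq",
]

ENDPOINTS = (
    "brdu_density",
    "ki67_density",
    "sox2_density",
    "brdu_dcx_density",
    "brdu_sox2_density",
    "pct_neun",
    "pct_dcx",
    "pct_sox2",
    "pct_dcx_type_a",
    "pct_dcx_type_b",
    "pct_dcx_type_c",
)

GROUP_COLS = ["sex", "region", "time_point"]


@dataclass
class TrajectorySummary:
    """Mean ± SEM per (sex, region, time) group for one endpoint."""

    endpoint: str
    table: pd.DataFrame  # columns: sex, region, time_point, n, mean, sem

    def group(self, sex: str, region: str, time_point: str) -> pd.Series:
        t = self.table
        row = t[
            (t["sex"] == sex) & (t["region"] == region) & (t["time_point"] == time_point)
        ]
        if row.empty:
            raise KeyError(f"no group ({sex}, {region}, {time_point}) in summary")
        return row.iloc[0]

    def to_csv(self, path: str | Path) -> None:
        out = self.table.assign(endpoint=self.endpoint)
        out.to_csv(path, index=False)


def summarize(records: pd.DataFrame, endpoint: str) -> TrajectorySummary:
    """Group means and SEMs of one endpoint over sex x region x time.

    ``records`` is the tidy per-animal-x-region frame (as produced by
    :func:`dgquant.synth.cohort_to_frame` or assembled from the stereology
    and phenotyping CSVs).
    """
    if records.empty:
        raise ValueError("records frame is empty")
    if endpoint not in records.columns:
        known = [c for c in records.columns if c in ENDPOINTS]
        raise ValueError(f"unknown endpoint {endpoint!r}; available: {known}")

    def _agg(g: pd.Series) -> pd.Series:
        vals = g.dropna().to_numpy(dtype=float)
        n = vals.size
        mean = vals.mean() if n else np.nan
        sem = vals.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan
        return pd.Series({"n": n, "mean": mean, "sem": sem})

    table = (
        records.groupby(GROUP_COLS, sort=True)[endpoint]
        .apply(_agg)
        .unstack()
        .reset_index()
    )
    table["n"] = table["n"].astype(int)
    return TrajectorySummary(endpoint=endpoint, table=table)


def attrition(
    summary: TrajectorySummary,
    sex: str,
    region: str,
    t_from: str,
    t_to: str,
) -> float:
    """Signed percent change in the group mean between two time points.

    ``100 * (mean(t_to) - mean(t_from)) / mean(t_from)``; negative values are
    attrition (loss of the birth-dated cohort).
    """
    m_from = float(summary.group(sex, region, t_from)["mean"])
    m_to = float(summary.group(sex, region, t_to)["mean"])
    if m_from == 0:
        raise ValueError(
            f"mean at {t_from} is zero for ({sex}, {region}); percent change undefined"
        )
    return 100.0 * (m_to - m_from) / m_from


def cohens_d(group_a, group_b) -> float:
    """Cohen's d with the pooled (n-1)-weighted standard deviation.

    Positive when group A's mean exceeds group B's; antisymmetric in its
    arguments.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("pooled standard deviation is zero: d undefined")
    return float((a.mean() - b.mean()) / pooled)


def partial_eta_sq(ss_effect: float, ss_error: float) -> float:
    """Partial eta squared: SS_effect / (SS_effect + SS_error), in [0, 1]."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("both sums of squares are zero: effect size undefined")
    return ss_effect / (ss_effect + ss_error)


def contrasts_table(records: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Cohen's d for the male-vs-female contrast at every region x time.

    Skips cells where either sex has fewer than two animals or the pooled SD
    is zero.
    """
    rows = []
    for (region, t), sub in records.groupby(["region", "time_point"]):
        a = sub.loc[sub["sex"] == "male", endpoint].dropna().to_numpy()
        b = sub.loc[sub["sex"] == "female", endpoint].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        try:
            d = cohens_d(a, b)
        except ValueError:
            continue
        rows.append(
            {
                "endpoint": endpoint,
                "contrast": "male_vs_female",
                "region": region,
                "time_point": t,
                "cohens_d": d,
            }
        )
    return pd.DataFrame(rows)
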