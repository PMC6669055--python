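"""Cross-sectional prevalence of wasting, stunting and concurrence by age.

Visits are grouped by completed month of age (0-23).  If a child has
several measurements within one month bin, the mean z-score within the bin
decides the classification for that month ("mean-then-classify"), so each
child contributes at most once per bin.  Prevalence is the percentage of
classified children per sex and month.  A local-regression smoother in the
style of published prevalence figures is provided for presentation only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "monthly_classification",
    "prevalence_table",
    "outcome_stunted_20_24",
    "grouped_prevalence",
    "loess_smooth",
]


def monthly_classification(visits: pd.DataFrame, max_month: int = 23) -> pd.DataFrame:
    """One row per (subject, completed month) with mean z-scores and flags.

    Flags are computed from the within-month mean LAZ/WLZ with strict < -2
    thresholds; a month with no valid z-score for an index leaves that flag
    missing.
    """
    df = visits.loc[visits["month"].between(0, max_month)]
    g = df.groupby(["subject_id", "sex", "month"], as_index=False).agg(
        mean_laz=("laz", "mean"), mean_wlz=("wlz", "mean")
    )
    g["stunted"] = np.where(
        g["mean_laz"].isna(), np.nan, (g["mean_laz"] < -2).astype(float)
    )
    g["wasted"] = np.where(
        g["mean_wlz"].isna(), np.nan, (g["mean_wlz"] < -2).astype(float)
    )
    g["concurrent"] = np.where(
        g["stunted"].isna() | g["wasted"].isna(),
        np.nan,
        ((g["stunted"] == 1) & (g["wasted"] == 1)).astype(float),
    )
    return g


def _pct(series: pd.Series) -> float:
    s = series.dropna()
    return 100.0 * s.mean() if len(s) else np.nan


def prevalence_table(monthly: pd.DataFrame, max_month: int = 23) -> pd.DataFrame:
    """Percent stunted/wasted/concurrent per sex and completed month of age.

    ``n`` counts unique classified subjects in the bin (visits collapse to
    one classification per subject-month upstream).  Empty bins yield n = 0
    with missing percentages.
    """
    rows = []
    for sex in sorted(monthly["sex"].unique()):
        sub = monthly.loc[monthly["sex"] == sex]
        for month in range(0, max_month + 1):
            bin_ = sub.loc[sub["month"] == month]
            rows.append(
                {
                    "sex": sex,
                    "month": month,
                    "n": int(bin_["subject_id"].nunique()),
                    "pct_stunted": _pct(bin_["stunted"]),
                    "pct_wasted": _pct(bin_["wasted"]),
                    "pct_concurrent": _pct(bin_["concurrent"]),
                }
            )
    return pd.DataFrame(rows)


def outcome_stunted_20_24(visits: pd.DataFrame, rule: str = "mean") -> pd.Series:
    """Binary stunting outcome in the 20-24-month window, per subject.

    ``rule="mean"``: stunted iff the mean LAZ over all visits at completed
    ages 20-23 months is < -2 (mirrors the within-month mean convention).
    ``rule="any"``: stunted iff any such visit has LAZ < -2.  Subjects with
    no visit in the window get NaN (excluded from models downstream).
    """
    if rule not in ("mean", "any"):
        raise ValueError("rule must be 'mean' or 'any'")
    win = visits.loc[visits["month"].between(20, 23)].dropna(subset=["laz"])
    if rule == "mean":
        out = win.groupby("subject_id")["laz"].mean() < -2
    else:
        out = win.groupby("subject_id")["laz"].agg(lambda s: bool((s < -2).any()))
    out = out.astype(float)
    out.name = "stunted_20_24"
    all_subjects = pd.Index(visits["subject_id"].unique(), name="subject_id")
    return out.reindex(all_subjects)


def grouped_prevalence(
    monthly: pd.DataFrame, grouping: pd.Series, max_month: int = 23
) -> pd.DataFrame:
    """Prevalence table within each level of a per-row or per-subject grouping.

    ``grouping`` is either indexed by subject_id (e.g. the 20-24-month
    stunting outcome) or aligned row-wise with ``monthly`` (e.g. current
    wasting).  Rows with missing group are dropped.
    """
    df = monthly.copy()
    if grouping.index.name == "subject_id":
        df["group"] = df["subject_id"].map(grouping)
    else:
        if len(grouping) != len(df):
            raise ValueError(
                "grouping must be subject_id-indexed or row-aligned with monthly"
            )
        df["group"] = np.asarray(grouping)
    df = df.dropna(subset=["group"])
    out = []
    for level, sub in df.groupby("group", sort=True):
        tab = prevalence_table(sub, max_month=max_month)
        tab.insert(0, "group", level)
        out.append(tab)
    return pd.concat(out, ignore_index=True)


def loess_smooth(x, y, span: float = 0.6, grid=None):
    """Local linear regression with tricube weights (presentation only).

    ``span`` is the fraction of points in each local window.  Returns
    ``(grid, fitted)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 101)
    grid = np.asarray(grid, float)
    k = max(2, int(np.ceil(span * len(x))))
    fitted = np.empty_like(grid)
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.sort(d)[k - 1]
        w = np.clip(1 - (d / max(h, 1e-12)) ** 3, 0, None) ** 3
        X = np.column_stack([np.ones_like(x), x - x0])
        WX = X * w[:, None]
        beta = np.linalg.lstsq(WX.T @ X, WX.T @ y, rcond=None)[0]
        fitted[i] = beta[0]
    return grid, fitted
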