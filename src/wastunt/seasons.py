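"""Wet/dry season calendar and per-infant seasonal wasting episodes.

In the West Kiang setting the annual wet ("hungry") season runs July
through October; the dry/harvest season covers November through June of
the following calendar year.  For each infant we construct three windows:
the first wet season of life (the season of birth, if born in July-October),
the intervening dry season, and the second wet season.  Within a window a
child is classed as wasted if the median of their WLZ observations in that
window is below -2; a child is eligible for the repeated-episode analysis
only with at least one observation in each of the three windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "SeasonWindow",
    "season_of",
    "life_season_windows",
    "summarize_episodes",
    "WET_MONTHS",
]

WET_MONTHS = frozenset({7, 8, 9, 10})


@dataclass(frozen=True)
class SeasonWindow:
    label: str  # "wet" | "dry"
    start: date
    end: date  # inclusive
    ordinal: str  # "wet1" | "dry" | "wet2"

    def contains(self, d) -> bool:
        d = pd.Timestamp(d).date()
        return self.start <= d <= self.end


def season_of(d) -> str:
    """"wet" for dates in July-October, else "dry"."""
    return "wet" if pd.Timestamp(d).month in WET_MONTHS else "dry"


def life_season_windows(dob) -> tuple[SeasonWindow, SeasonWindow, SeasonWindow]:
    """First-wet / intervening-dry / second-wet windows for one infant.

    The first wet season is the July-October window containing the birth
    date if the child was born in the wet season, otherwise the next one to
    start; the second wet season is the following year's window.
    """
    dob = pd.Timestamp(dob).date()
    year1 = dob.year if dob < date(dob.year, 11, 1) else dob.year + 1
    wet1 = SeasonWindow("wet", date(year1, 7, 1), date(year1, 10, 31), "wet1")
    dry = SeasonWindow("dry", date(year1, 11, 1), date(year1 + 1, 6, 30), "dry")
    wet2 = SeasonWindow(
        "wet", date(year1 + 1, 7, 1), date(year1 + 1, 10, 31), "wet2"
    )
    return wet1, dry, wet2


def summarize_episodes(
    visits: pd.DataFrame, include_birth_visit: bool = True
) -> pd.DataFrame:
    """Per-subject seasonal episode summary over the three life windows.

    Returns one row per subject: observation counts, median WLZ and wasted
    flag per window, and the eligibility flag (>= 1 observation in every
    window).  ``include_birth_visit=False`` drops each child's day-of-birth
    measurement before counting window observations.
    """
    df = visits.copy()
    df["visit_date"] = pd.to_datetime(df["visit_date"])
    df["dob"] = pd.to_datetime(df["dob"])
    if not include_birth_visit:
        df = df.loc[df["visit_date"] > df["dob"]]
    rows = []
    for sid, sub in df.groupby("subject_id", sort=True):
        windows = life_season_windows(sub["dob"].iloc[0])
        row = {"subject_id": sid}
        eligible = True
        for win in windows:
            dates = sub["visit_date"].dt.date
            in_win = (dates >= win.start) & (dates <= win.end)
            wlz = sub.loc[in_win, "wlz"].dropna()
            key = win.ordinal
            row[f"n_{key}"] = int(len(wlz))
            med = float(np.median(wlz)) if len(wlz) else np.nan
            row[f"med_wlz_{key}"] = med
            row[f"wasted_{key}"] = bool(med < -2) if len(wlz) else np.nan
            eligible &= len(wlz) >= 1
        row["eligible"] = eligible
        rows.append(row)
    return pd.DataFrame(rows)
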