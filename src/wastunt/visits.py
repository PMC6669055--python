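"""Visit-table schema helpers.

The canonical longitudinal table has one row per clinic measurement
occasion with columns: ``subject_id``, ``sex`` ("F"/"M"), ``dob``,
``visit_date`` (ISO-8601 dates), ``weight_kg``, ``length_cm``, ``muac_cm``.
Derived columns added here: ``age_days``, ``age_months`` (at 365.25/12 days
per month) and ``month`` (completed months of age).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DAYS_PER_MONTH = 365.25 / 12.0

REQUIRED_COLUMNS = [
    "subject_id",
    "sex",
    "dob",
    "visit_date",
    "weight_kg",
    "length_cm",
]


def add_age_columns(visits: pd.DataFrame) -> pd.DataFrame:
    """Attach age_days, age_months and completed-month columns from the dates.

    Raises if any visit predates its subject's date of birth.
    """
    df = visits.copy()
    df["dob"] = pd.to_datetime(df["dob"])
    df["visit_date"] = pd.to_datetime(df["visit_date"])
    age_days = (df["visit_date"] - df["dob"]).dt.days.astype(float)
    if np.any(age_days < 0):
        bad = df.loc[age_days < 0, "subject_id"].iloc[0]
        raise ValueError(f"visit before date of birth (subject {bad!r})")
    df["age_days"] = age_days
    df["age_months"] = age_days / DAYS_PER_MONTH
    df["month"] = np.floor(age_days / DAYS_PER_MONTH).astype(int)
    return df


def read_visits_csv(path) -> pd.DataFrame:
    """Read a visit table, parse dates and derive age columns."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"visit table missing columns: {missing}")
    return add_age_columns(df)


def sort_visits(visits: pd.DataFrame) -> pd.DataFrame:
    """Sort by subject and visit date (the order every sequential rule assumes)."""
    return visits.sort_values(["subject_id", "visit_date"], kind="mergesort").reset_index(
        drop=True
    )
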