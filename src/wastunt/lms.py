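"""LMS (Box-Cox) anthropometric z-scores and nutritional-state classification.

A growth reference is summarised by three curves: the Box-Cox power ``L``,
the median ``M`` and the coefficient of variation ``S``, indexed either by
age in days (length-for-age) or by length in cm (weight-for-length).  The
z-score of a measurement ``x`` against a reference point (L, M, S) is

    z = ((x / M)**L - 1) / (L * S)        (L != 0)
    z = log(x / M) / S                    (L -> 0)

Classification thresholds follow the conventional cut-offs: wasting is
WLZ < -2, stunting is LAZ < -2, and a small mid-upper arm circumference is
MUAC < 12.5 cm.  All thresholds are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .visits import DAYS_PER_MONTH

__all__ = [
    "LMSReference",
    "AnthroAssessment",
    "compute_zscore",
    "invert_zscore",
    "lookup_lms",
    "classify",
    "toy_reference",
    "read_lms_csv",
    "write_lms_csv",
    "add_zscores",
    "WASTING_CUTOFF",
    "STUNTING_CUTOFF",
    "MUAC_CUTOFF_CM",
]

WASTING_CUTOFF = -2.0
STUNTING_CUTOFF = -2.0
MUAC_CUTOFF_CM = 12.5

#: |L| below this uses the logarithmic limit form of the Box-Cox transform.
_L_LOG_TOL = 1e-7


class LMSRangeError(ValueError):
    """Lookup index outside the reference grid."""


@dataclass(frozen=True)
class LMSReference:
    """Sex- and index-variable-specific (L, M, S) grid with linear interpolation.

    Parameters
    ----------
    axis
        Label of the index variable: ``"age_days"`` for length-for-age,
        ``"length_cm"`` for weight-for-length.
    tables
        Mapping ``sex -> (grid, L, M, S)`` where each element is a 1-D float
        array; the grid must be strictly increasing, M and S positive.
    """

    axis: str
    tables: dict = field(repr=False)

    def __post_init__(self):
        for sex, (grid, L, M, S) in self.tables.items():
            grid, L, M, S = (np.asarray(a, dtype=float) for a in (grid, L, M, S))
            if not (len(grid) == len(L) == len(M) == len(S)):
                raise ValueError(f"ragged LMS table for sex {sex!r}")
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"LMS grid not strictly increasing for sex {sex!r}")
            if np.any(M <= 0) or np.any(S <= 0):
                raise ValueError(f"nonpositive M or S in LMS table for sex {sex!r}")
            self.tables[sex] = (grid, L, M, S)

    @property
    def sexes(self):
        return sorted(self.tables)

    def range(self, sex) -> tuple[float, float]:
        grid = self.tables[sex][0]
        return float(grid[0]), float(grid[-1])


def compute_zscore(x, L, M, S):
    """Box-Cox z-score of measurement ``x`` against an (L, M, S) triple.

    Vectorised over all arguments; uses the log-limit form where |L| is
    numerically zero so the result is continuous in L.
    """
    x, L, M, S = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (x, L, M, S))
    )
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("measurement, M and S must all be positive")
    log_ratio = np.log(x / M)
    near_zero = np.abs(L) < _L_LOG_TOL
    Lsafe = np.where(near_zero, 1.0, L)
    # expm1 keeps the power form accurate as L -> 0
    z = np.where(
        near_zero,
        log_ratio / S,
        np.expm1(Lsafe * log_ratio) / (Lsafe * S),
    )
    return z if z.ndim else float(z)


def invert_zscore(z, L, M, S):
    """Measurement whose z-score against (L, M, S) equals ``z``.

    Raises
    ------
    ValueError
        If the Box-Cox inverse is nonpositive (z beyond the support of the
        transform for the given L, S).
    """
    z, L, M, S = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (z, L, M, S))
    )
    if np.any(M <= 0) or np.any(S <= 0):
        raise ValueError("M and S must be positive")
    near_zero = np.abs(L) < _L_LOG_TOL
    Lsafe = np.where(near_zero, 1.0, L)
    base = 1.0 + Lsafe * S * z
    if np.any(~near_zero & (base <= 0)):
        raise ValueError("z-score outside the domain of the Box-Cox inverse")
    # log1p keeps the inverse power form accurate as L -> 0
    x = np.where(
        near_zero,
        M * np.exp(S * z),
        M * np.exp(np.log1p(np.where(base > 0, Lsafe * S * z, 0.0)) / Lsafe),
    )
    return x if x.ndim else float(x)


def lookup_lms(ref: LMSReference, sex, index_value):
    """Interpolate (L, M, S) at ``index_value`` for one sex.

    Linear interpolation between bracketing grid points; exact at grid
    points.  Values outside the grid raise :class:`LMSRangeError` naming the
    axis and its bounds.
    """
    if sex not in ref.tables:
        raise KeyError(f"sex {sex!r} not in reference (has {ref.sexes})")
    grid, L, M, S = ref.tables[sex]
    iv = np.asarray(index_value, dtype=float)
    lo, hi = ref.range(sex)
    if np.any(iv < lo) or np.any(iv > hi):
        raise LMSRangeError(
            f"{ref.axis}={index_value} outside reference range [{lo}, {hi}]"
        )
    out = tuple(np.interp(iv, grid, curve) for curve in (L, M, S))
    if iv.ndim == 0:
        return tuple(float(v) for v in out)
    return out


@dataclass(frozen=True)
class AnthroAssessment:
    """Z-scores plus derived nutritional-state flags for one measurement occasion.

    Flags are ``None`` (not ``False``) when the underlying input is missing.
    """

    laz: Optional[float]
    wlz: Optional[float]
    muac_cm: Optional[float] = None
    wasted: Optional[bool] = None
    stunted: Optional[bool] = None
    concurrent: Optional[bool] = None
    small_muac: Optional[bool] = None


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def classify(laz=None, wlz=None, muac_cm=None) -> AnthroAssessment:
    """Classify wasted / stunted / concurrent / small-MUAC from z-scores.

    Strict thresholds: wasted iff WLZ < -2, stunted iff LAZ < -2, concurrent
    iff both, small MUAC iff MUAC < 12.5 cm.  A missing input leaves the
    corresponding flag undefined (``None``) rather than false.
    """
    wasted = None if _is_missing(wlz) else bool(wlz < WASTING_CUTOFF)
    stunted = None if _is_missing(laz) else bool(laz < STUNTING_CUTOFF)
    concurrent = None if (wasted is None or stunted is None) else (wasted and stunted)
    small_muac = None if _is_missing(muac_cm) else bool(muac_cm < MUAC_CUTOFF_CM)
    return AnthroAssessment(
        laz=None if _is_missing(laz) else float(laz),
        wlz=None if _is_missing(wlz) else float(wlz),
        muac_cm=None if _is_missing(muac_cm) else float(muac_cm),
        wasted=wasted,
        stunted=stunted,
        concurrent=concurrent,
        small_muac=small_muac,
    )


def toy_reference() -> tuple[LMSReference, LMSReference]:
    """Small synthetic (L, M, S) reference pair for tests and simulation.

    Returns ``(length_for_age, weight_for_length)``.  The curves are smooth
    analytic stand-ins with plausible magnitudes (birth length ~50 cm rising
    to ~86 cm by 26 mo; weight ~3.3 kg at 50 cm), *not* the WHO standard.
    Real WHO tables in the same CSV schema are a drop-in replacement.
    """
    # length-for-age: monthly grid 0..26 mo, in days
    months = np.arange(0, 27, dtype=float)
    age_days = months * DAYS_PER_MONTH
    tables_lfa = {}
    for sex, offset in (("F", -0.7), ("M", 0.0)):
        M = 50.0 + offset + 37.0 * (1.0 - np.exp(-months / 9.5))
        L = np.ones_like(M)
        S = 0.035 + 0.0002 * months
        tables_lfa[sex] = (age_days, L, M, S)
    lfa = LMSReference(axis="age_days", tables=tables_lfa)

    # weight-for-length: 1-cm grid 42..100 cm
    length = np.arange(42.0, 101.0)
    tables_wfl = {}
    for sex, scale in (("F", 0.985), ("M", 1.0)):
        M = scale * 3.3 * (length / 50.0) ** 2.35
        L = np.full_like(M, -0.35)
        S = 0.085 + 0.0002 * (length - 42.0)
        tables_wfl[sex] = (length, L, M, S)
    wfl = LMSReference(axis="length_cm", tables=tables_wfl)
    return lfa, wfl


def write_lms_csv(refs, path):
    """Write one or more references to a single CSV (sex, index_value, L, M, S, axis)."""
    rows = []
    for ref in np.atleast_1d(refs):
        for sex, (grid, L, M, S) in ref.tables.items():
            rows.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "index_value": grid,
                        "L": L,
                        "M": M,
                        "S": S,
                        "axis": ref.axis,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_lms_csv(path) -> dict[str, LMSReference]:
    """Read references from CSV, keyed by axis label."""
    df = pd.read_csv(path)
    out = {}
    for axis, sub in df.groupby("axis"):
        tables = {}
        for sex, rows in sub.groupby("sex"):
            rows = rows.sort_values("index_value")
            tables[sex] = (
                rows["index_value"].to_numpy(float),
                rows["L"].to_numpy(float),
                rows["M"].to_numpy(float),
                rows["S"].to_numpy(float),
            )
        out[axis] = LMSReference(axis=axis, tables=tables)
    return out


def add_zscores(
    visits: pd.DataFrame,
    lfa: LMSReference,
    wfl: LMSReference,
    out_of_range: str = "nan",
) -> pd.DataFrame:
    """Attach ``laz`` and ``wlz`` columns computed from raw anthropometry.

    LAZ scores length against the age-indexed reference; WLZ scores weight
    against the length-indexed reference.  ``out_of_range`` controls index
    values beyond a reference grid: ``"nan"`` yields a missing z-score,
    ``"error"`` raises :class:`LMSRangeError`.
    """
    if out_of_range not in ("nan", "error"):
        raise ValueError("out_of_range must be 'nan' or 'error'")
    df = visits.copy()
    laz = np.full(len(df), np.nan)
    wlz = np.full(len(df), np.nan)
    for sex, idx in df.groupby("sex").groups.items():
        sub = df.loc[idx]
        age = sub["age_days"].to_numpy(float)
        length = sub["length_cm"].to_numpy(float)
        weight = sub["weight_kg"].to_numpy(float)

        for ref, index_vals, meas, target in (
            (lfa, age, length, laz),
            (wfl, length, weight, wlz),
        ):
            lo, hi = ref.range(sex)
            ok = (index_vals >= lo) & (index_vals <= hi) & np.isfinite(meas)
            if out_of_range == "error" and not np.all(
                ok | ~np.isfinite(index_vals)
            ):
                bad = index_vals[~ok]
                raise LMSRangeError(
                    f"{ref.axis} value(s) outside [{lo}, {hi}]: e.g. {bad[0]}"
                )
            if ok.any():
                L, M, S = lookup_lms(ref, sex, index_vals[ok])
                vals = compute_zscore(meas[ok], L, M, S)
                pos = np.asarray(idx)[ok]
                target[df.index.get_indexer(pos)] = vals
    df["laz"] = laz
    df["wlz"] = wlz
    return df
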