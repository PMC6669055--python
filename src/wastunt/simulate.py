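"""Seeded synthetic longitudinal cohorts with known ground truth.

Two generator pathways, deliberately separate:

* :func:`generate_cohort` emits a continuous-z visit table following the
  clinic schedule (birth, 6 weeks, 3 months, then 3-monthly to 24 months,
  with dropout and date jitter).  LAZ declines with age around
  subject-level intercept/slope random effects; WLZ follows a mean age
  curve plus an annual seasonal forcing (trough in the July-October wet
  season, amplitude growing over infancy) plus subject random effects
  including a personal seasonal sin/cos pair, plus lagged wasting ->
  stunting coupling (a wasting episode leaves a decaying deficit in
  subsequent LAZ).  Raw lengths and weights are back-computed through the
  bundled LMS reference so the z-scoring pipeline is exercised end to end.

* :func:`generate_binary_panel` simulates 3-monthly binary (stunted,
  wasted) chains from the exact time-lagged random-intercept logistic
  transition model, for coefficient-recovery tests.

Every draw flows from one seed; :class:`TruthManifest` records the
generative parameters, per-subject random effects, noise-free z-scores and
(after :func:`plant_outliers`) the identity of every corrupted record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.special import expit

from . import lms as lms_mod
from .visits import DAYS_PER_MONTH, add_age_columns

__all__ = ["SyntheticConfig", "TruthManifest", "generate_cohort",
           "generate_binary_panel", "plant_outliers", "panel_to_pairs"]


@dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic cohort.

    Defaults describe the study-like condition: a seasonal rural setting
    with a wet-season WLZ trough, wasting prevalence peaking in the
    10-20% band around one year, stunting rising towards ~35-40% by two
    years, and a lagged wasting -> stunting coupling.
    """

    n_subjects: int = 500
    birth_start: date = date(1990, 1, 1)
    birth_end: date = date(1993, 12, 31)
    # visit schedule
    followup_days: int = 730
    attendance_prob: float = 0.85
    jitter_sd_days: float = 7.0
    jitter_max_days: float = 21.0
    # LAZ mean curve (z at birth, z at 24 months; linear in between)
    laz_birth_mean: float = -0.4
    laz_24m_mean: float = -1.6
    laz_intercept_sd: float = 0.9
    laz_slope_sd: float = 0.02  # per month
    laz_residual_sd: float = 0.45
    # WLZ mean curve anchors at 0/3/12/24 months (early catch-up, midyear dip)
    wlz_anchor_ages: tuple = (0.0, 3.0, 12.0, 24.0)
    wlz_anchor_values: tuple = (-1.0, -0.35, -0.95, -0.7)
    # seasonal forcing of WLZ: amp * agescale(age) * cos(2 pi (doy - peak)/365.25)
    wlz_seasonal_amplitude: float = 0.4
    wlz_seasonal_peak_doy: float = 46.0  # mid-dry-season peak -> wet-season trough
    seasonal_age_scaling: bool = True  # amplitude ramps in over infancy
    # mild LAZ seasonality trailing the WLZ cycle (length responds later)
    laz_seasonal_amplitude: float = 0.15
    laz_seasonal_lag_days: float = 90.0
    # subject-level random effects for WLZ
    re_intercept_sd: float = 0.6
    re_slope_sd: float = 0.02  # per month
    re_seasonal_sd: float = 0.4  # per sin/cos component
    residual_sd: float = 0.5
    # sex effects (boys fare worse)
    boy_laz_shift: float = -0.15
    boy_wlz_shift: float = -0.10
    # wasting -> stunting coupling: decaying LAZ deficit after wasted visits
    laz_wasting_deficit: float = 0.4
    deficit_persistence: float = 0.85  # retained fraction per 3 months
    frailty_corr: float = 0.4  # corr(WLZ intercept, LAZ intercept)
    # planted corruption
    outlier_rate: float = 0.0
    # binary-panel transition model (log-odds)
    panel_waves: int = 8  # ages 0, 3, ..., 21 months
    panel_stunt_intercept: float = float(np.log(0.012))
    panel_stunt_sex: float = float(np.log(1.6))
    panel_stunt_age: float = float(np.log(1.1))  # per lagged month
    panel_stunt_lag_stunt: float = float(np.log(8.2))
    panel_stunt_lag_waste: float = float(np.log(3.2))
    panel_waste_intercept: float = float(np.log(0.013))
    panel_waste_sex: float = float(np.log(1.5))
    panel_waste_age: float = 0.0
    panel_waste_lag_stunt: float = float(np.log(1.5))
    panel_waste_lag_waste: float = float(np.log(2.9))
    panel_re_sd: float = 0.5
    panel_init_stunt_prob: float = 0.08
    panel_init_waste_prob: float = 0.09
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_subjects < 1:
            problems.append("n_subjects must be >= 1")
        if not 0.0 <= self.attendance_prob <= 1.0:
            problems.append("attendance_prob must be in [0, 1]")
        if not 0.0 <= self.outlier_rate <= 0.1:
            problems.append("outlier_rate must be in [0, 0.1]")
        for name in (
            "laz_intercept_sd", "laz_slope_sd", "laz_residual_sd",
            "re_intercept_sd", "re_slope_sd", "re_seasonal_sd", "residual_sd",
            "jitter_sd_days", "panel_re_sd",
        ):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not 0.0 <= self.deficit_persistence <= 1.0:
            problems.append("deficit_persistence must be in [0, 1]")
        if not -1.0 <= self.frailty_corr <= 1.0:
            problems.append("frailty_corr must be in [-1, 1]")
        if self.birth_end < self.birth_start:
            problems.append("birth_end before birth_start")
        for p in ("panel_init_stunt_prob", "panel_init_waste_prob"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                problems.append(f"{p} must be in [0, 1]")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["birth_start"] = self.birth_start.isoformat()
        d["birth_end"] = self.birth_end.isoformat()
        return d


@dataclass
class TruthManifest:
    """Ground truth accompanying a generated cohort."""

    params: dict
    subjects: pd.DataFrame  # per-subject true random effects and amplitude
    visits_true: pd.DataFrame  # per-visit noise-free and realised z-scores
    planted: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["visit_id", "kind", "axis", "z_before", "z_after"]
        )
    )


def _schedule_ages_days(cfg: SyntheticConfig) -> np.ndarray:
    ages = [0.0, 42.0]
    t = 91.0
    while t <= cfg.followup_days:
        ages.append(t)
        t += 91.0
    return np.asarray(ages)


def _wlz_mean_curve(cfg: SyntheticConfig):
    interp = PchipInterpolator(
        np.asarray(cfg.wlz_anchor_ages, float),
        np.asarray(cfg.wlz_anchor_values, float),
    )
    hi = cfg.wlz_anchor_ages[-1]
    return lambda age_mo: interp(np.clip(age_mo, 0.0, hi))


def _agescale(age_months: np.ndarray, enabled: bool) -> np.ndarray:
    """Seasonal vulnerability ramp: partial buffering in early infancy."""
    if not enabled:
        return np.ones_like(np.asarray(age_months, float))
    return np.clip((np.asarray(age_months, float) + 3.0) / 9.0, 0.0, 1.0)


def seasonal_forcing(cfg: SyntheticConfig, doy, age_months) -> np.ndarray:
    """Population seasonal WLZ term at a day-of-year and age."""
    ang = 2.0 * np.pi * (np.asarray(doy, float) - cfg.wlz_seasonal_peak_doy) / 365.25
    return (
        cfg.wlz_seasonal_amplitude
        * _agescale(age_months, cfg.seasonal_age_scaling)
        * np.cos(ang)
    )


def generate_cohort(cfg: SyntheticConfig, refs=None):
    """Generate a visit table plus its :class:`TruthManifest`.

    Returns ``(visits, manifest)``.  The visit table carries raw
    anthropometry (weight, length, MUAC) and the derived age columns, but
    *not* z-scores: those are recomputed downstream by the z-scoring
    module, closing the loop through the LMS reference.  If
    ``cfg.outlier_rate > 0`` the table is corrupted by
    :func:`plant_outliers` before being returned.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lfa, wfl = refs if refs is not None else lms_mod.toy_reference()
    wlz_mean = _wlz_mean_curve(cfg)

    n = cfg.n_subjects
    sexes = np.where(rng.random(n) < 0.5, "M", "F")
    span = (cfg.birth_end - cfg.birth_start).days
    dobs = [
        cfg.birth_start + timedelta(days=int(d))
        for d in rng.integers(0, span + 1, size=n)
    ]

    # subject random effects
    u0 = rng.normal(0.0, cfg.re_intercept_sd, n)
    u1 = rng.normal(0.0, cfg.re_slope_sd, n)
    a_i = rng.normal(0.0, cfg.re_seasonal_sd, n)
    b_i = rng.normal(0.0, cfg.re_seasonal_sd, n)
    rho = cfg.frailty_corr
    z_shared = u0 / cfg.re_intercept_sd if cfg.re_intercept_sd > 0 else rng.normal(size=n)
    v0 = cfg.laz_intercept_sd * (
        rho * z_shared + np.sqrt(1.0 - rho**2) * rng.normal(size=n)
    )
    v1 = rng.normal(0.0, cfg.laz_slope_sd, n)

    base_ages = _schedule_ages_days(cfg)
    laz_slope_mean = (cfg.laz_24m_mean - cfg.laz_birth_mean) / 24.0

    visit_rows = []
    true_rows = []
    visit_id = 0
    for i in range(n):
        attend = rng.random(len(base_ages)) < cfg.attendance_prob
        attend[0] = True  # birth visit always recorded
        jitter = np.clip(
            rng.normal(0.0, cfg.jitter_sd_days, len(base_ages)),
            -cfg.jitter_max_days,
            cfg.jitter_max_days,
        )
        jitter[0] = 0.0
        ages_days = np.round(base_ages + jitter)[attend]
        ages_days = np.unique(np.clip(ages_days, 0, None))
        ages_mo = ages_days / DAYS_PER_MONTH
        dates = pd.to_datetime(dobs[i]) + pd.to_timedelta(ages_days, unit="D")
        doy = dates.dayofyear.to_numpy(float)

        wlz_true = (
            np.asarray(wlz_mean(ages_mo), float)
            + seasonal_forcing(cfg, doy, ages_mo)
            + (cfg.boy_wlz_shift if sexes[i] == "M" else 0.0)
            + u0[i]
            + u1[i] * ages_mo
            + a_i[i] * np.sin(2 * np.pi * doy / 365.25)
            + b_i[i] * np.cos(2 * np.pi * doy / 365.25)
        )
        wlz_obs = wlz_true + rng.normal(0.0, cfg.residual_sd, len(ages_mo))

        # lagged wasting -> stunting: decaying deficit driven by prior wasted visits
        deficit = np.zeros(len(ages_mo))
        for k in range(1, len(ages_mo)):
            dt_mo = ages_mo[k] - ages_mo[k - 1]
            decay = cfg.deficit_persistence ** (dt_mo / 3.0)
            deficit[k] = decay * deficit[k - 1] + cfg.laz_wasting_deficit * float(
                wlz_obs[k - 1] < -2.0
            )
        laz_seasonal = (
            cfg.laz_seasonal_amplitude
            * _agescale(ages_mo, cfg.seasonal_age_scaling)
            * np.cos(
                2.0
                * np.pi
                * (doy - cfg.wlz_seasonal_peak_doy - cfg.laz_seasonal_lag_days)
                / 365.25
            )
        )
        laz_true = (
            cfg.laz_birth_mean
            + laz_slope_mean * ages_mo
            + (cfg.boy_laz_shift if sexes[i] == "M" else 0.0)
            + laz_seasonal
            + v0[i]
            + v1[i] * ages_mo
            - deficit
        )
        laz_obs = laz_true + rng.normal(0.0, cfg.laz_residual_sd, len(ages_mo))

        # back-compute raw anthropometry through the LMS reference
        sex = sexes[i]
        grid_lo, grid_hi = lfa.range(sex)
        age_idx = np.clip(ages_days, grid_lo, grid_hi)
        L, M, S = lms_mod.lookup_lms(lfa, sex, age_idx)
        length = lms_mod.invert_zscore(laz_obs, L, M, S)
        wlo, whi = wfl.range(sex)
        len_idx = np.clip(length, wlo, whi)
        Lw, Mw, Sw = lms_mod.lookup_lms(wfl, sex, len_idx)
        weight = lms_mod.invert_zscore(wlz_obs, Lw, Mw, Sw)
        muac = (
            10.8
            + 3.5 * (1.0 - np.exp(-ages_mo / 8.0))
            + 0.45 * wlz_obs
            + rng.normal(0.0, 0.4, len(ages_mo))
        )

        for k in range(len(ages_mo)):
            visit_rows.append(
                {
                    "visit_id": visit_id,
                    "subject_id": f"S{i:05d}",
                    "sex": sex,
                    "dob": pd.Timestamp(dobs[i]),
                    "visit_date": dates[k],
                    "weight_kg": round(float(weight[k]), 3),
                    "length_cm": round(float(length[k]), 2),
                    "muac_cm": round(float(muac[k]), 2),
                }
            )
            true_rows.append(
                {
                    "visit_id": visit_id,
                    "subject_id": f"S{i:05d}",
                    "laz_mean_true": float(laz_true[k]),
                    "wlz_mean_true": float(wlz_true[k]),
                    "laz_realised": float(laz_obs[k]),
                    "wlz_realised": float(wlz_obs[k]),
                }
            )
            visit_id += 1

    visits = add_age_columns(pd.DataFrame(visit_rows))
    subjects = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "sex": sexes,
            "dob": pd.to_datetime(dobs),
            "wlz_u0": u0,
            "wlz_u1": u1,
            "wlz_a": a_i,
            "wlz_b": b_i,
            "wlz_seasonal_amplitude": np.hypot(a_i, b_i),
            "laz_v0": v0,
            "laz_v1": v1,
        }
    ).set_index("subject_id")
    manifest = TruthManifest(
        params=cfg.to_dict(),
        subjects=subjects,
        visits_true=pd.DataFrame(true_rows),
    )
    if cfg.outlier_rate > 0:
        visits, manifest = plant_outliers(
            visits, manifest, cfg.outlier_rate, refs=(lfa, wfl),
            rng=np.random.default_rng(cfg.seed + 1_000_003),
        )
    return visits, manifest


def plant_outliers(visits, manifest, rate, refs=None, rng=None):
    """Corrupt a fraction of visits with implausible z's and single-visit spikes.

    Half of the planted records get an implausible z-score (|LAZ| in
    6.5-7.5 or |WLZ| in 5.5-6.5, sign chosen to keep the raw measurement
    inside the reference grid); the rest get a WLZ spike of 3.8-5.2 SD
    relative to their own level (at most one per subject, never the first
    visit), which creates a >3 SD consecutive change while staying inside
    the plausible range.  The raw weight/length is rewritten so the
    corruption survives re-scoring.  Returns ``(visits, manifest)`` with
    the planted table filled in.
    """
    if not 0.0 <= rate <= 0.1:
        raise ValueError("rate must be in [0, 0.1]")
    if rate == 0.0:
        return visits, manifest
    rng = np.random.default_rng(0) if rng is None else rng
    lfa, wfl = refs if refs is not None else lms_mod.toy_reference()
    df = visits.copy().reset_index(drop=True)
    truth = manifest.visits_true.set_index("visit_id")

    n_plant = int(np.floor(rate * len(df)))
    n_implaus = n_plant // 2
    n_spike = n_plant - n_implaus
    order = rng.permutation(len(df))
    planted = []
    used_rows: set[int] = set()
    spike_subjects: set = set()

    def z_now(row, axis):
        sex = row["sex"]
        if axis == "laz":
            L, M, S = lms_mod.lookup_lms(
                lfa, sex, float(np.clip(row["age_days"], *lfa.range(sex)))
            )
            return lms_mod.compute_zscore(row["length_cm"], L, M, S), (L, M, S)
        L, M, S = lms_mod.lookup_lms(
            wfl, sex, float(np.clip(row["length_cm"], *wfl.range(sex)))
        )
        return lms_mod.compute_zscore(row["weight_kg"], L, M, S), (L, M, S)

    # --- implausible z records ---
    count = 0
    for pos in order:
        if count >= n_implaus:
            break
        row = df.loc[pos]
        axis = "laz" if count % 2 == 0 else "wlz"
        mag = rng.uniform(6.5, 7.5) if axis == "laz" else rng.uniform(5.5, 6.5)
        z_old, (L, M, S) = z_now(row, axis)
        target = None
        for sign in rng.permutation([1.0, -1.0]):
            try:
                x = lms_mod.invert_zscore(sign * mag, L, M, S)
            except ValueError:
                continue
            if axis == "laz":
                lo, hi = wfl.range(row["sex"])
                if not (lo <= x <= hi):
                    continue
            target = sign * mag
            break
        if target is None:
            continue
        x_new = lms_mod.invert_zscore(target, L, M, S)
        if axis == "laz":
            df.loc[pos, "length_cm"] = round(float(x_new), 2)
        else:
            df.loc[pos, "weight_kg"] = round(float(x_new), 3)
        planted.append(
            {
                "visit_id": int(row["visit_id"]),
                "kind": "implausible",
                "axis": axis,
                "z_before": float(z_old),
                "z_after": float(target),
            }
        )
        used_rows.add(int(pos))
        count += 1

    # --- consecutive-change spikes on WLZ (via weight) ---
    counts = df.groupby("subject_id")["visit_id"].transform("size")
    first = df.groupby("subject_id")["visit_date"].transform("min")
    count = 0
    for pos in order:
        if count >= n_spike:
            break
        if int(pos) in used_rows:
            continue
        row = df.loc[pos]
        if counts[pos] < 2 or row["visit_date"] == first[pos]:
            continue
        if row["subject_id"] in spike_subjects:
            continue
        z_old, (L, M, S) = z_now(row, "wlz")
        if not np.isfinite(z_old):
            continue
        delta = rng.uniform(3.8, 5.2)
        sign = 1.0 if (4.7 - z_old) >= (z_old + 4.7) else -1.0
        z_new = z_old + sign * delta
        if abs(z_new) > 4.7:  # keep inside the plausible band
            z_new = np.clip(z_new, -4.7, 4.7)
            if abs(z_new - z_old) <= 3.2:
                continue
        try:
            w_new = lms_mod.invert_zscore(float(z_new), L, M, S)
        except ValueError:
            continue
        df.loc[pos, "weight_kg"] = round(float(w_new), 3)
        planted.append(
            {
                "visit_id": int(row["visit_id"]),
                "kind": "spike",
                "axis": "wlz",
                "z_before": float(z_old),
                "z_after": float(z_new),
            }
        )
        used_rows.add(int(pos))
        spike_subjects.add(row["subject_id"])
        count += 1

    manifest.planted = pd.DataFrame(
        planted, columns=["visit_id", "kind", "axis", "z_before", "z_after"]
    )
    _ = truth  # manifest truth table unchanged: corruption is on raw values
    return df, manifest


def generate_binary_panel(cfg: SyntheticConfig):
    """Simulate 3-monthly binary (stunted, wasted) chains per subject.

    States evolve by the time-lagged random-intercept logistic transition
    model whose coefficients live in the config; initial states are drawn
    independently of the random intercepts.  Returns ``(panel, truth)``
    where ``truth`` maps each model term to its generative log-odds.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, waves = cfg.n_subjects, cfg.panel_waves
    sex_boy = (rng.random(n) < 0.5).astype(float)
    u_s = rng.normal(0.0, cfg.panel_re_sd, n)
    u_w = rng.normal(0.0, cfg.panel_re_sd, n)
    ages = 3.0 * np.arange(waves)

    S = np.empty((n, waves)); W = np.empty((n, waves))
    S[:, 0] = rng.random(n) < cfg.panel_init_stunt_prob
    W[:, 0] = rng.random(n) < cfg.panel_init_waste_prob
    for t in range(1, waves):
        age_lag = ages[t - 1]
        eta_s = (
            cfg.panel_stunt_intercept
            + cfg.panel_stunt_sex * sex_boy
            + cfg.panel_stunt_age * age_lag
            + cfg.panel_stunt_lag_stunt * S[:, t - 1]
            + cfg.panel_stunt_lag_waste * W[:, t - 1]
            + u_s
        )
        eta_w = (
            cfg.panel_waste_intercept
            + cfg.panel_waste_sex * sex_boy
            + cfg.panel_waste_age * age_lag
            + cfg.panel_waste_lag_stunt * S[:, t - 1]
            + cfg.panel_waste_lag_waste * W[:, t - 1]
            + u_w
        )
        S[:, t] = rng.random(n) < expit(eta_s)
        W[:, t] = rng.random(n) < expit(eta_w)

    panel = pd.DataFrame(
        {
            "subject_id": np.repeat([f"P{i:05d}" for i in range(n)], waves),
            "sex": np.repeat(np.where(sex_boy == 1, "M", "F"), waves),
            "wave": np.tile(np.arange(waves), n),
            "age_months": np.tile(ages, n),
            "stunted": S.ravel().astype(int),
            "wasted": W.ravel().astype(int),
        }
    )
    truth = {
        "stunting": {
            "intercept": cfg.panel_stunt_intercept,
            "sex_boy": cfg.panel_stunt_sex,
            "age_lagged": cfg.panel_stunt_age,
            "stunted_lagged": cfg.panel_stunt_lag_stunt,
            "wasted_lagged": cfg.panel_stunt_lag_waste,
        },
        "wasting": {
            "intercept": cfg.panel_waste_intercept,
            "sex_boy": cfg.panel_waste_sex,
            "age_lagged": cfg.panel_waste_age,
            "stunted_lagged": cfg.panel_waste_lag_stunt,
            "wasted_lagged": cfg.panel_waste_lag_waste,
        },
        "re_sd": cfg.panel_re_sd,
    }
    return panel, truth


def panel_to_pairs(panel: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-wave lagged pairs from a binary panel (lag exactly 3 mo)."""
    df = panel.sort_values(["subject_id", "wave"])
    prev = df.groupby("subject_id").shift(1)
    ok = prev["wave"].notna()
    return pd.DataFrame(
        {
            "subject_id": df.loc[ok, "subject_id"],
            "sex": df.loc[ok, "sex"],
            "age_now_months": df.loc[ok, "age_months"],
            "age_prior_months": prev.loc[ok, "age_months"],
            "lag_months": df.loc[ok, "age_months"] - prev.loc[ok, "age_months"],
            "stunted_now": df.loc[ok, "stunted"].astype(float),
            "wasted_now": df.loc[ok, "wasted"].astype(float),
            "stunted_prior": prev.loc[ok, "stunted"].astype(float),
            "wasted_prior": prev.loc[ok, "wasted"].astype(float),
        }
    ).reset_index(drop=True)
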