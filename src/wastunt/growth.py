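"""Mixed-effects seasonal growth curves for anthropometric z-scores.

The population trajectory of a z-score (WLZ or LAZ) over the first two
years is modelled as

    z_ij = f(age_ij) + sum_k [ alpha_k sin(2 pi k t_ij / P) + beta_k cos(.) ]
           + age_ij * [ gamma_s sin(2 pi t_ij / P) + gamma_c cos(.) ]
           + u0_i + u1_i age_ij + a_i sin(2 pi t_ij / P) + b_i cos(.) + e_ij

where ``f`` is a natural cubic spline in age (months), ``t`` is the
day-of-year of the visit and ``P = 365.25`` days.  Fixed seasonality uses
second-order Fourier (cosinor) terms; the age interaction and the subject
random effects use the annual harmonic only, so each child carries a
personal seasonal pair ``(a_i, b_i)`` on top of a random intercept and age
slope.  The amplitude ``sqrt(a_i^2 + b_i^2)`` of that pair is the
coefficient of cyclic variation (CCV): the child's own seasonal swing, in
z-score units, above or below the seasonal swing of the mean curve.

Estimation is by REML through :class:`statsmodels` ``MixedLM`` with an
unstructured random-effect covariance; if that fails to converge the model
is refitted with a diagonal covariance and the fallback is recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

from .visits import DAYS_PER_MONTH

__all__ = [
    "GrowthDesignSpec",
    "GrowthModelFit",
    "ModelFrame",
    "fourier_basis",
    "natural_cubic_spline_basis",
    "build_design",
    "fit_growth_model",
    "fit_by_outcome_group",
    "predict_trajectory",
    "compute_ccv",
    "seasonal_peak_doy",
    "subject_seasonal_summary",
    "ConvergenceFailure",
]

PERIOD_DAYS = 365.25


class ConvergenceFailure(RuntimeError):
    """Mixed-model estimation failed after all fallbacks."""


def fourier_basis(t, order: int, period: float = PERIOD_DAYS) -> np.ndarray:
    """Seasonal sin/cos regressors at harmonics 1..order of ``period``.

    ``t`` is time within the cycle (here: day-of-year).  Columns are
    ordered ``sin_1, cos_1, sin_2, cos_2, ...``.
    """
    if order not in (1, 2):
        raise ValueError("Fourier order must be 1 or 2")
    t = np.atleast_1d(np.asarray(t, float))
    cols = []
    for k in range(1, order + 1):
        ang = 2.0 * np.pi * k * t / period
        cols.extend([np.sin(ang), np.cos(ang)])
    return np.column_stack(cols)


def natural_cubic_spline_basis(
    x, interior_knots, boundary_knots=(0.0, 24.0)
) -> np.ndarray:
    """Natural cubic spline basis (no intercept column).

    Cubic between the boundary knots with continuous second derivatives,
    constrained to be linear beyond them (second derivative zero at the
    boundaries), so evaluation outside the boundary range extrapolates
    linearly.  Column count = number of interior knots + 1; together with
    an intercept the columns span the full natural-spline space on the
    given knots.
    """
    x = np.atleast_1d(np.asarray(x, float))
    lo, hi = boundary_knots
    knots = np.asarray([lo, *np.asarray(interior_knots, float), hi])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing within the boundaries")
    K = len(knots)

    def d(k):
        num = np.clip(x - knots[k], 0, None) ** 3 - np.clip(x - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[k])

    d_last = d(K - 2)
    cols = [x] + [d(k) - d_last for k in range(K - 2)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class GrowthDesignSpec:
    """Design choices for the seasonal growth model.

    Ages are in months; interior knots default to the 25/50/75 age
    percentiles of the data at build time (``None``).  The random-effect
    Fourier order may not exceed the fixed order.
    """

    interior_knots: Optional[tuple] = None
    boundary_knots: tuple = (0.0, 24.0)
    fourier_order_fixed: int = 2
    fourier_order_random: int = 1
    interaction: bool = True
    period: float = PERIOD_DAYS

    def __post_init__(self):
        if self.fourier_order_random > self.fourier_order_fixed:
            raise ValueError("random Fourier order must not exceed fixed order")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.interior_knots is not None:
            ks = np.asarray(self.interior_knots, float)
            lo, hi = self.boundary_knots
            if np.any(np.diff(ks) <= 0) or np.any((ks <= lo) | (ks >= hi)):
                raise ValueError("interior knots must be increasing inside boundaries")


@dataclass
class ModelFrame:
    """Assembled regression frame for one growth-model fit."""

    y: np.ndarray
    X: pd.DataFrame  # fixed-effect columns (named)
    Z: pd.DataFrame  # random-effect columns (named)
    groups: np.ndarray
    spec: GrowthDesignSpec
    knots: tuple  # resolved interior knots
    response: str


def _resolve_knots(age_months: np.ndarray, spec: GrowthDesignSpec) -> tuple:
    if spec.interior_knots is not None:
        return tuple(float(k) for k in spec.interior_knots)
    qs = np.percentile(age_months, [25, 50, 75])
    # collapse duplicates defensively (degenerate age distributions)
    ks = np.unique(np.round(qs, 6))
    lo, hi = spec.boundary_knots
    ks = ks[(ks > lo) & (ks < hi)]
    return tuple(float(k) for k in ks)


def build_design(
    visits: pd.DataFrame, spec: GrowthDesignSpec = GrowthDesignSpec(), response: str = "wlz"
) -> ModelFrame:
    """Build the fixed and random design matrices from a cleaned visit table.

    Fixed part: intercept + natural spline in age + Fourier terms of order
    ``fourier_order_fixed`` in day-of-year + (optionally) linear-age x
    annual-harmonic interaction.  Random part per subject: intercept, age,
    annual sin/cos.  Rows with a missing response are dropped.
    """
    if len(visits) == 0:
        raise ValueError("empty visit table")
    df = visits.dropna(subset=[response]).copy()
    if len(df) == 0:
        raise ValueError(f"no non-missing {response!r} values")
    age = df["age_months"].to_numpy(float)
    doy = pd.to_datetime(df["visit_date"]).dt.dayofyear.to_numpy(float)
    knots = _resolve_knots(age, spec)

    ns = natural_cubic_spline_basis(age, knots, spec.boundary_knots)
    four = fourier_basis(doy, spec.fourier_order_fixed, spec.period)
    cols = {"intercept": np.ones(len(df))}
    for j in range(ns.shape[1]):
        cols[f"ns_{j + 1}"] = ns[:, j]
    names = ["sin_1", "cos_1", "sin_2", "cos_2"][: four.shape[1]]
    for name, col in zip(names, four.T):
        cols[name] = col
    if spec.interaction:
        cols["age_sin_1"] = age * cols["sin_1"]
        cols["age_cos_1"] = age * cols["cos_1"]
    X = pd.DataFrame(cols, index=df.index)

    zf = fourier_basis(doy, spec.fourier_order_random, spec.period)
    Z = pd.DataFrame(
        {"u0": np.ones(len(df)), "u1_age": age, "a_sin": zf[:, 0], "b_cos": zf[:, 1]},
        index=df.index,
    )
    return ModelFrame(
        y=df[response].to_numpy(float),
        X=X,
        Z=Z,
        groups=df["subject_id"].to_numpy(),
        spec=spec,
        knots=knots,
        response=response,
    )


@dataclass
class GrowthModelFit:
    """Fitted seasonal growth model with per-subject shrunken random effects."""

    fe_params: pd.Series
    fe_se: pd.Series
    cov_re: pd.DataFrame
    resid_var: float
    random_effects: pd.DataFrame  # index subject_id; columns u0,u1_age,a_sin,b_cos
    converged: bool
    method: str
    llf: float
    spec: GrowthDesignSpec
    knots: tuple
    response: str
    n_subjects: int
    n_obs: int
    messages: list = field(default_factory=list)

    def summary_dict(self) -> dict:
        return {
            "response": self.response,
            "n_subjects": self.n_subjects,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "method": self.method,
            "llf": self.llf,
            "fixed_effects": self.fe_params.to_dict(),
            "random_effect_sds": {
                k: float(np.sqrt(self.cov_re.loc[k, k])) for k in self.cov_re.index
            },
            "resid_sd": float(np.sqrt(self.resid_var)),
            "knots": list(self.knots),
            "messages": self.messages,
        }


def fit_growth_model(frame: ModelFrame, reml: bool = True) -> GrowthModelFit:
    """REML fit of the linear mixed model defined by a :class:`ModelFrame`.

    Requires at least 10 subjects with two or more visits.  Tries an
    unstructured random-effect covariance first, then a diagonal structure;
    raises :class:`ConvergenceFailure` (with optimizer diagnostics) if
    neither converges.
    """
    counts = pd.Series(frame.groups).value_counts()
    if (counts >= 2).sum() < 10:
        raise ValueError("need >= 2 visits for >= 10 subjects to fit the growth model")

    model = MixedLM(frame.y, frame.X, groups=frame.groups, exog_re=frame.Z)
    k_re = frame.Z.shape[1]
    messages: list[str] = []
    diag_free = MixedLMParams.from_components(
        fe_params=np.ones(frame.X.shape[1]), cov_re=np.eye(k_re)
    )
    attempts = [
        ("unstructured-reml-bfgs", dict(reml=reml, method="bfgs", maxiter=500)),
        ("unstructured-reml-lbfgs", dict(reml=reml, method="lbfgs", maxiter=500)),
        # derivative-free fallback: robust when a variance sits on the boundary
        ("unstructured-reml-powell", dict(reml=reml, method="powell", maxiter=2000)),
        ("diagonal-reml-bfgs", dict(reml=reml, method="bfgs", maxiter=500, free=diag_free)),
        ("diagonal-reml-powell", dict(reml=reml, method="powell", maxiter=2000, free=diag_free)),
    ]
    result = None
    used = None
    for name, kwargs in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(**kwargs)
        except Exception as exc:  # noqa: BLE001 - optimizer failures vary
            messages.append(f"{name}: {exc}")
            continue
        if res.converged and np.isfinite(res.llf):
            result = res
            used = name
            break
        messages.append(f"{name}: did not converge")
    if result is None:
        raise ConvergenceFailure(
            "growth model failed to converge; attempts: " + "; ".join(messages)
        )
    if "diagonal" in used:
        messages.append("fell back to diagonal random-effect covariance")

    re_df = pd.DataFrame.from_dict(
        {g: np.asarray(v, float) for g, v in result.random_effects.items()},
        orient="index",
        columns=list(frame.Z.columns),
    )
    re_df.index.name = "subject_id"
    k_fe = frame.X.shape[1]
    fe_se = np.sqrt(np.diag(np.asarray(result.cov_params()))[:k_fe])
    return GrowthModelFit(
        fe_params=pd.Series(np.asarray(result.fe_params), index=frame.X.columns),
        fe_se=pd.Series(fe_se, index=frame.X.columns),
        cov_re=pd.DataFrame(
            np.asarray(result.cov_re), index=frame.Z.columns, columns=frame.Z.columns
        ),
        resid_var=float(result.scale),
        random_effects=re_df.sort_index(),
        converged=bool(result.converged),
        method=used,
        llf=float(result.llf),
        spec=frame.spec,
        knots=frame.knots,
        response=frame.response,
        n_subjects=len(counts),
        n_obs=len(frame.y),
        messages=messages,
    )


def fit_by_outcome_group(
    visits: pd.DataFrame,
    outcome: pd.Series,
    spec: GrowthDesignSpec = GrowthDesignSpec(),
    response: str = "wlz",
    by_sex: bool = True,
    min_subjects: int = 10,
) -> dict:
    """Independent growth fits per (sex x outcome-group) stratum.

    ``outcome`` is a subject_id-indexed binary series (e.g. stunted at
    20-24 months).  Strata with fewer than ``min_subjects`` subjects are
    skipped with a warning.  Returns ``{(sex, group): GrowthModelFit}``
    (``sex`` is ``"all"`` when ``by_sex`` is false).
    """
    if outcome.index.name != "subject_id":
        raise ValueError("outcome must be indexed by subject_id")
    df = visits.copy()
    df["_group"] = df["subject_id"].map(outcome)
    df = df.dropna(subset=["_group"])
    fits = {}
    sex_levels = sorted(df["sex"].unique()) if by_sex else ["all"]
    for sex in sex_levels:
        sub_sex = df if sex == "all" else df.loc[df["sex"] == sex]
        for level, sub in sub_sex.groupby("_group"):
            if sub["subject_id"].nunique() < min_subjects:
                warnings.warn(
                    f"stratum (sex={sex}, group={level}) has fewer than "
                    f"{min_subjects} subjects; skipped"
                )
                continue
            frame = build_design(sub, spec, response)
            fits[(sex, bool(level))] = fit_growth_model(frame)
    return fits


def predict_trajectory(
    fit: GrowthModelFit, dob, age_grid_months
) -> pd.DataFrame:
    """Population-level predicted z(age) for a child born on ``dob``.

    Random effects are set to zero; the calendar date of each point is
    ``dob + age``, so the prediction carries the seasonal imprint of the
    birth date.
    """
    dob = pd.Timestamp(dob)
    ages = np.atleast_1d(np.asarray(age_grid_months, float))
    dates = dob + pd.to_timedelta(np.round(ages * DAYS_PER_MONTH), unit="D")
    doy = dates.dayofyear.to_numpy(float)
    spec = fit.spec
    ns = natural_cubic_spline_basis(ages, fit.knots, spec.boundary_knots)
    four = fourier_basis(doy, spec.fourier_order_fixed, spec.period)
    cols = {"intercept": np.ones(len(ages))}
    for j in range(ns.shape[1]):
        cols[f"ns_{j + 1}"] = ns[:, j]
    names = ["sin_1", "cos_1", "sin_2", "cos_2"][: four.shape[1]]
    for name, col in zip(names, four.T):
        cols[name] = col
    if spec.interaction:
        cols["age_sin_1"] = ages * cols["sin_1"]
        cols["age_cos_1"] = ages * cols["cos_1"]
    X = pd.DataFrame(cols)[fit.fe_params.index]
    pred = X.to_numpy() @ fit.fe_params.to_numpy()
    return pd.DataFrame(
        {"dob": dob, "age_months": ages, "date": dates, "predicted_z": pred}
    )


def seasonal_peak_doy(fit: GrowthModelFit) -> float:
    """Day-of-year at which the fitted annual harmonic peaks.

    The annual term a sin(t) + b cos(t) equals R cos(t - phi) with
    phi = atan2(a, b); the peak falls at doy = phi * P / (2 pi), folded
    into [0, P).
    """
    a = float(fit.fe_params["sin_1"])
    b = float(fit.fe_params["cos_1"])
    phi = np.arctan2(a, b)
    return float((phi * fit.spec.period / (2.0 * np.pi)) % fit.spec.period)


def compute_ccv(a, b):
    """Coefficient of cyclic variation: amplitude of the subject's annual pair.

    ``sqrt(a^2 + b^2)`` in z-score units; invariant to seasonal phase.
    """
    return np.hypot(a, b)


def subject_seasonal_summary(fit: GrowthModelFit) -> pd.DataFrame:
    """Per-subject random effects with the CCV column attached."""
    out = fit.random_effects.copy()
    out["ccv"] = compute_ccv(out["a_sin"], out["b_cos"])
    return out
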