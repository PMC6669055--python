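"""Plain logistic risk models and their classification diagnostics.

Covers the two cross-sectional analyses: (i) wasting in the second wet
season of life regressed on wasting in the first wet season and in the
intervening dry season, and (ii) stunting at 20-24 months regressed on a
nested sequence of predictors (model I: sex + ever stunted before 20 mo;
model II: + ever wasted; model III: + the subject's random-effect features
from the seasonal growth model, including the CCV).  Estimates are
maximum-likelihood; odds ratios carry Wald 95% CIs.  In-sample error,
false-negative and false-positive rates are reported at a configurable
probability threshold (default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LogisticFitResult",
    "ClassificationDiagnostics",
    "SeparationError",
    "fit_logistic",
    "season_repeat_model",
    "build_stunting_features",
    "fit_stunting_models",
    "classification_diagnostics",
]

_Z95 = 1.959963984540054


class SeparationError(RuntimeError):
    """Perfect (or quasi-perfect) separation in a logistic fit."""


@dataclass
class LogisticFitResult:
    """Logistic-regression fit reported on the odds-ratio scale."""

    terms: list
    coef: np.ndarray  # log-odds
    se: np.ndarray
    n: int
    llf: float
    dropped_terms: list = field(default_factory=list)
    fitted_prob: np.ndarray = None

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        return np.exp(self.coef - _Z95 * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        return np.exp(self.coef + _Z95 * self.se)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "se": self.se,
                "odds_ratio": self.odds_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(X[self.terms].to_numpy(float) @ self.coef)))


def fit_logistic(y, X: pd.DataFrame, drop_constant: bool = True) -> LogisticFitResult:
    """Maximum-likelihood logistic regression with separation detection.

    Rows with any missing value are dropped (complete case).  Constant
    non-intercept columns are dropped with a warning.  Perfect separation
    (fitted linear predictor completely splits the outcome classes) is
    reported as :class:`SeparationError` naming the dominant term.
    """
    X = pd.DataFrame(X).copy()
    y = pd.Series(np.asarray(y, float), index=X.index)
    keep = y.notna() & X.notna().all(axis=1)
    X, y = X.loc[keep], y.loc[keep]
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")

    dropped = []
    for col in list(X.columns):
        if col != "intercept" and X[col].nunique() <= 1:
            dropped.append(col)
            X = X.drop(columns=col)
    if dropped:
        warnings.warn(f"dropped constant predictor column(s): {dropped}")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y.to_numpy(), X.to_numpy(float)).fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # Newton's Hessian goes singular under separation; refit
            # derivative-only and let the separation check decide
            res = sm.Logit(y.to_numpy(), X.to_numpy(float)).fit(
                disp=0, maxiter=500, method="bfgs"
            )
        except Exception as exc:
            if "separation" in str(exc).lower():
                raise SeparationError(str(exc)) from exc
            raise
    coef = np.asarray(res.params)
    prob = np.asarray(res.predict())
    sep_warned = any("separation" in str(w.message).lower() for w in caught)
    both_classes = (y == 1).any() and (y == 0).any()
    complete_sep = both_classes and (
        prob[y == 1].min() > prob[y == 0].max() + 1e-12
    )
    if sep_warned or complete_sep:
        # name the term dominating the linear predictor spread
        spread = np.nan_to_num(np.abs(coef) * X.to_numpy(float).std(axis=0))
        worst = X.columns[int(np.argmax(spread))]
        raise SeparationError(f"perfect separation in logistic fit (term {worst!r})")
    return LogisticFitResult(
        terms=list(X.columns),
        coef=coef,
        se=np.asarray(res.bse),
        n=int(len(y)),
        llf=float(res.llf),
        dropped_terms=dropped,
        fitted_prob=np.asarray(res.predict()),
    )


def season_repeat_model(episodes: pd.DataFrame, min_eligible: int = 50) -> LogisticFitResult:
    """Consecutive-wet-season wasting model on eligible subjects.

    Outcome: wasted in the second wet season; predictors: intercept,
    wasted in the first wet season, wasted in the intervening dry season.
    """
    elig = episodes.loc[episodes["eligible"].astype(bool)]
    if len(elig) == 0:
        raise ValueError("no eligible subjects (need >=1 visit in all three windows)")
    if len(elig) < min_eligible:
        warnings.warn(
            f"only {len(elig)} eligible subjects (< {min_eligible}); estimates unstable"
        )
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "wasted_wet1": elig["wasted_wet1"].astype(float),
            "wasted_dry": elig["wasted_dry"].astype(float),
        },
        index=elig.index,
    )
    return fit_logistic(elig["wasted_wet2"].astype(float), X)


def build_stunting_features(
    monthly: pd.DataFrame,
    random_effects: pd.DataFrame,
    outcome: pd.Series,
    sex: pd.Series,
) -> pd.DataFrame:
    """Per-subject feature rows for the stunting-at-20-24-months models.

    ``monthly`` is the subject-month classification table; ever-stunted /
    ever-wasted flags use completed months 0-19 only.  ``random_effects``
    is the subject-indexed output of the growth model (with ``ccv``);
    ``outcome`` the 20-24-month stunting outcome; ``sex`` a subject-indexed
    "F"/"M" series.  Rows are returned only for subjects with a
    non-missing outcome.
    """
    early = monthly.loc[monthly["month"] <= 19]
    ever = early.groupby("subject_id").agg(
        ever_stunted=("stunted", lambda s: float(s.fillna(0).astype(bool).any())),
        ever_wasted=("wasted", lambda s: float(s.fillna(0).astype(bool).any())),
    )
    feats = pd.DataFrame(index=outcome.dropna().index)
    feats["sex_boy"] = (sex.reindex(feats.index) == "M").astype(float)
    feats["ever_stunted"] = ever["ever_stunted"].reindex(feats.index).fillna(0.0)
    feats["ever_wasted"] = ever["ever_wasted"].reindex(feats.index).fillna(0.0)
    for col, name in (("u0", "re_intercept"), ("u1_age", "re_slope"), ("ccv", "ccv")):
        feats[name] = random_effects[col].reindex(feats.index)
    feats["stunted_20_24"] = outcome.dropna().astype(float)
    feats.index.name = "subject_id"
    return feats


MODEL_TERMS = {
    "I": ["intercept", "sex_boy", "ever_stunted"],
    "II": ["intercept", "sex_boy", "ever_stunted", "ever_wasted"],
    "III": [
        "intercept",
        "sex_boy",
        "ever_stunted",
        "ever_wasted",
        "re_intercept",
        "re_slope",
        "ccv",
    ],
}


def fit_stunting_models(features: pd.DataFrame) -> dict:
    """Fit the nested models I-III on a common complete-case row set."""
    union = sorted(set(sum(MODEL_TERMS.values(), [])) - {"intercept"})
    df = features.dropna(subset=union + ["stunted_20_24"]).copy()
    df["intercept"] = 1.0
    y = df["stunted_20_24"].astype(float)
    return {
        name: fit_logistic(y, df[terms]) for name, terms in MODEL_TERMS.items()
    }


@dataclass
class ClassificationDiagnostics:
    """In-sample confusion-matrix rates, in percent."""

    threshold: float
    error_rate: float
    false_negative_rate: float
    false_positive_rate: float
    n: int


def classification_diagnostics(
    fit: LogisticFitResult, y, X: pd.DataFrame = None, threshold: float = 0.5
) -> ClassificationDiagnostics:
    """Error / FNR / FPR at a probability threshold (classify when p >= t).

    FNR is the share of observed positives classified negative; FPR the
    share of observed negatives classified positive.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be strictly inside (0, 1)")
    prob = fit.fitted_prob if X is None else fit.predict(X)
    y = np.asarray(y, float)
    if len(y) != len(prob):
        raise ValueError("outcome length does not match fitted probabilities")
    pred = prob >= threshold
    pos, neg = y == 1, y == 0
    return ClassificationDiagnostics(
        threshold=threshold,
        error_rate=100.0 * float(np.mean(pred != pos)),
        false_negative_rate=(
            100.0 * float(np.mean(~pred[pos])) if pos.any() else np.nan
        ),
        false_positive_rate=(
            100.0 * float(np.mean(pred[neg])) if neg.any() else np.nan
        ),
        n=int(len(y)),
    )
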