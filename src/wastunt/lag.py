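"""Time-lagged pairing of visits and multilevel logistic prediction.

Each visit is matched 1-to-1 with a prior visit of the same child as close
as possible to 3 months earlier; if no prior visit falls between 2.5 and
3.5 months before, the current visit is dropped.  On the matched pairs a
random-intercept (subject-level) logistic model relates the current state
(stunted, or wasted for the reciprocal model) to sex and the *lagged* age,
stunting and wasting.  The marginal likelihood over the Gaussian random
intercept is integrated by Gauss-Hermite quadrature and maximised
numerically; Wald CIs come from the numerical Hessian at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_hess1

from .visits import DAYS_PER_MONTH

__all__ = [
    "match_lagged",
    "MixedLogisticFit",
    "fit_mixed_logistic",
    "fit_lagged_model",
    "predict_scenarios",
    "MixedConvergenceError",
]

_Z95 = 1.959963984540054

LAG_TARGET_MONTHS = 3.0
LAG_WINDOW_MONTHS = (2.5, 3.5)


class MixedConvergenceError(RuntimeError):
    pass


def _select_prior(lags: np.ndarray, target: float) -> int:
    """Index of the candidate lag minimising |lag - target|.

    Exact ties break toward the longer lag (the earlier prior visit).
    """
    dist = np.abs(np.asarray(lags, float) - target)
    best = dist.min()
    tied = np.flatnonzero(np.isclose(dist, best, rtol=0.0, atol=1e-9))
    return int(tied[np.argmax(np.asarray(lags, float)[tied])])


def match_lagged(
    visits: pd.DataFrame,
    target_lag: float = LAG_TARGET_MONTHS,
    window: tuple = LAG_WINDOW_MONTHS,
) -> pd.DataFrame:
    """Match each visit to the prior visit of the same child closest to 3 mo back.

    Lags are in months of 365.25/12 days.  Among candidates inside
    ``window`` the one minimising ``|lag - target|`` wins; exact ties break
    toward the longer lag.  Visits with no candidate are dropped.  A prior
    visit may serve several current visits; each current visit appears in
    at most one pair.
    """
    lo, hi = window
    df = visits.sort_values(["subject_id", "visit_date"], kind="mergesort")
    out = []
    for sid, sub in df.groupby("subject_id", sort=False):
        days = (
            pd.to_datetime(sub["visit_date"])
            - pd.to_datetime(sub["visit_date"]).iloc[0]
        ).dt.days.to_numpy(float)
        ages = sub["age_months"].to_numpy(float)
        laz = sub["laz"].to_numpy(float)
        wlz = sub["wlz"].to_numpy(float)
        n = len(sub)
        for i in range(1, n):
            lags = (days[i] - days[:i]) / DAYS_PER_MONTH
            ok = (lags >= lo) & (lags <= hi)
            if not ok.any():
                continue
            cand = np.flatnonzero(ok)
            j = int(cand[_select_prior(lags[cand], target_lag)])
            with np.errstate(invalid="ignore"):
                out.append(
                    {
                        "subject_id": sid,
                        "sex": sub["sex"].iloc[0],
                        "date_now": sub["visit_date"].iloc[i],
                        "date_prior": sub["visit_date"].iloc[j],
                        "age_now_months": ages[i],
                        "age_prior_months": ages[j],
                        "lag_months": lags[j],
                        "stunted_now": laz[i] < -2 if np.isfinite(laz[i]) else np.nan,
                        "wasted_now": wlz[i] < -2 if np.isfinite(wlz[i]) else np.nan,
                        "stunted_prior": laz[j] < -2 if np.isfinite(laz[j]) else np.nan,
                        "wasted_prior": wlz[j] < -2 if np.isfinite(wlz[j]) else np.nan,
                    }
                )
    return pd.DataFrame(out)


@dataclass
class MixedLogisticFit:
    """Random-intercept logistic fit (fixed effects on the odds-ratio scale)."""

    terms: list
    coef: np.ndarray
    se: np.ndarray
    sigma_u: float  # SD of the subject-level random intercept
    n_obs: int
    n_subjects: int
    llf: float
    method: str
    converged: bool

    @property
    def odds_ratios(self):
        return np.exp(self.coef)

    @property
    def ci_low(self):
        return np.exp(self.coef - _Z95 * self.se)

    @property
    def ci_high(self):
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


def _marginal_loglik(params, X, y, group_idx, n_groups, nodes, weights):
    """Gauss-Hermite marginal log-likelihood of the random-intercept logit."""
    beta, sigma = params[:-1], params[-1]
    eta0 = X @ beta
    # loglik per group per node
    ll = np.empty((n_groups, len(nodes)))
    for q, (x_q, logw_q) in enumerate(zip(nodes, weights)):
        eta = eta0 + np.sqrt(2.0) * sigma * x_q
        obs_ll = y * eta - np.logaddexp(0.0, eta)
        ll[:, q] = np.bincount(group_idx, weights=obs_ll, minlength=n_groups) + logw_q
    return float(np.sum(logsumexp(ll, axis=1)))


def fit_mixed_logistic(
    y,
    X: pd.DataFrame,
    groups,
    n_quad: int = 25,
    start=None,
) -> MixedLogisticFit:
    """ML fit of a logistic model with a Gaussian subject random intercept.

    The marginal likelihood integrates the random intercept by ``n_quad``-
    point Gauss-Hermite quadrature and is maximised by L-BFGS-B with the
    random-intercept SD bounded at zero (so a degenerate fit collapses to
    plain logistic regression).  Standard errors are Wald, from the
    numerical Hessian; when the SD sits on the boundary the Hessian is
    taken over the fixed effects alone.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, float)
    groups = np.asarray(groups)
    codes, uniques = pd.factorize(groups)
    n_groups = len(uniques)
    Xm = X.to_numpy(float)

    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)
    log_w = np.log(gh_w) - 0.5 * np.log(np.pi)

    def negll(p):
        return -_marginal_loglik(p, Xm, y, codes, n_groups, gh_x, log_w)

    if start is None:
        # plain-logistic start for beta, modest sigma
        from statsmodels.api import Logit

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                b0 = np.asarray(Logit(y, Xm).fit(disp=0, maxiter=100).params)
            except Exception:
                b0 = np.zeros(Xm.shape[1])
        start = np.r_[b0, 0.5]
    bounds = [(None, None)] * Xm.shape[1] + [(0.0, None)]
    res = minimize(negll, start, method="L-BFGS-B", bounds=bounds)
    if not res.success:
        warnings.warn(
            f"quadrature ML did not report convergence ({res.message}); "
            "retrying with more nodes"
        )
        gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad * 2)
        log_w = np.log(gh_w) - 0.5 * np.log(np.pi)
        res = minimize(negll, res.x, method="L-BFGS-B", bounds=bounds)
        if not res.success:
            raise MixedConvergenceError(str(res.message))

    params = res.x
    sigma = float(params[-1])
    k = Xm.shape[1]
    try:
        if sigma > 1e-4:
            H = approx_hess1(params, negll)
            cov = np.linalg.inv(H)[:k, :k]
        else:
            H = approx_hess1(params[:k], lambda b: negll(np.r_[b, sigma]))
            cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return MixedLogisticFit(
        terms=list(X.columns),
        coef=params[:k],
        se=se,
        sigma_u=sigma,
        n_obs=len(y),
        n_subjects=n_groups,
        llf=-float(res.fun),
        method=f"gauss-hermite quadrature ({n_quad} nodes)",
        converged=bool(res.success),
    )


LAGGED_TERMS = ["intercept", "sex_boy", "age_lagged", "stunted_lagged", "wasted_lagged"]


def fit_lagged_model(pairs: pd.DataFrame, outcome: str = "stunting") -> MixedLogisticFit:
    """Random-intercept logistic fit of current state on lagged predictors.

    ``outcome="stunting"`` models current stunting, ``"wasting"`` the
    reciprocal model; both share the design: intercept, sex (boy = 1),
    lagged age in months, lagged stunted, lagged wasted.  No interaction
    terms are included.
    """
    ycol = {"stunting": "stunted_now", "wasting": "wasted_now"}.get(outcome)
    if ycol is None:
        raise ValueError("outcome must be 'stunting' or 'wasting'")
    df = pairs.dropna(
        subset=[ycol, "stunted_prior", "wasted_prior", "age_prior_months"]
    )
    if len(df) < 100:
        raise ValueError(f"need >= 100 matched pairs, have {len(df)}")
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "sex_boy": (df["sex"] == "M").astype(float),
            "age_lagged": df["age_prior_months"].astype(float),
            "stunted_lagged": df["stunted_prior"].astype(float),
            "wasted_lagged": df["wasted_prior"].astype(float),
        },
        index=df.index,
    )
    return fit_mixed_logistic(df[ycol].astype(float), X, df["subject_id"].to_numpy())


def predict_scenarios(
    fit: MixedLogisticFit, ages, sexes=(0.0, 1.0)
) -> pd.DataFrame:
    """Predicted probabilities at the random-intercept median (u = 0).

    One row per sex x lagged-state group (neither / stunted only / wasted
    only / both) x lagged age.
    """
    groups = {
        "neither": (0.0, 0.0),
        "stunted_only": (1.0, 0.0),
        "wasted_only": (0.0, 1.0),
        "both": (1.0, 1.0),
    }
    rows = []
    coef = dict(zip(fit.terms, fit.coef))
    for sex in sexes:
        for label, (s_lag, w_lag) in groups.items():
            for age in np.atleast_1d(ages):
                eta = (
                    coef["intercept"]
                    + coef["sex_boy"] * sex
                    + coef["age_lagged"] * age
                    + coef["stunted_lagged"] * s_lag
                    + coef["wasted_lagged"] * w_lag
                )
                rows.append(
                    {
                        "sex_boy": sex,
                        "group": label,
                        "age_lagged": float(age),
                        "probability": float(expit(eta)),
                    }
                )
    return pd.DataFrame(rows)
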