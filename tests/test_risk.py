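"""Logistic risk models, nested stunting models, classification diagnostics."""

import numpy as np
import pandas as pd
import pytest

from wastunt import prevalence, risk, seasons


def logistic_data(rng, n=500, beta=(0.5, 1.0)):
    x = rng.normal(size=n)
    eta = beta[0] + beta[1] * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    X = pd.DataFrame({"intercept": np.ones(n), "x": x})
    return y, X


class TestFitLogistic:
    def test_or_ci_internal_consistency(self, rng):
        y, X = logistic_data(rng)
        fit = risk.fit_logistic(y, X)
        np.testing.assert_allclose(fit.odds_ratios, np.exp(fit.coef), rtol=1e-12)
        np.testing.assert_allclose(
            fit.ci_low, np.exp(fit.coef - 1.959963984540054 * fit.se), rtol=1e-10
        )

    def test_separation_detected_and_named(self, rng):
        y = np.r_[np.zeros(20), np.ones(20)]
        X = pd.DataFrame({"intercept": 1.0, "copy": y})
        with pytest.raises(risk.SeparationError, match="copy"):
            risk.fit_logistic(y, X)

    def test_constant_predictor_dropped(self, rng):
        y, X = logistic_data(rng, n=200)
        X["flat"] = 3.0
        with pytest.warns(UserWarning, match="flat"):
            fit = risk.fit_logistic(y, X)
        assert "flat" in fit.dropped_terms and "flat" not in fit.terms

    def test_recovers_known_coefficient(self, rng):
        y, X = logistic_data(rng, n=4000, beta=(0.2, 0.8))
        fit = risk.fit_logistic(y, X)
        assert fit.coef[1] == pytest.approx(0.8, abs=3.5 * fit.se[1])

    def test_nonbinary_outcome_rejected(self, rng):
        y, X = logistic_data(rng, n=50)
        with pytest.raises(ValueError):
            risk.fit_logistic(y + 0.5, X)


class TestSeasonRepeatModel:
    def make_episodes(self, rng, n=400, b_wet1=np.log(3.2), b_dry=np.log(2.0)):
        wet1 = (rng.random(n) < 0.25).astype(float)
        dry = (rng.random(n) < 0.15).astype(float)
        eta = np.log(0.12) + b_wet1 * wet1 + b_dry * dry
        wet2 = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "wasted_wet1": wet1,
                "wasted_dry": dry,
                "wasted_wet2": wet2,
                "eligible": True,
            }
        )

    def test_three_term_shape_and_direction(self, rng):
        fit = risk.season_repeat_model(self.make_episodes(rng, n=2000))
        assert fit.terms == ["intercept", "wasted_wet1", "wasted_dry"]
        tab = fit.table().set_index("term")
        assert tab.loc["wasted_wet1", "odds_ratio"] > 1
        assert tab.loc["wasted_dry", "odds_ratio"] > 1

    def test_dry_persistence_only(self, rng):
        ep = self.make_episodes(rng, n=3000, b_wet1=0.0, b_dry=np.log(4.0))
        tab = risk.season_repeat_model(ep).table().set_index("term")
        assert tab.loc["wasted_dry", "odds_ratio"] > 2.0
        lo, hi = tab.loc["wasted_wet1", ["ci_low", "ci_high"]]
        assert lo < 1.0 < hi

    def test_zero_eligible_errors(self, rng):
        ep = self.make_episodes(rng, n=10)
        ep["eligible"] = False
        with pytest.raises(ValueError):
            risk.season_repeat_model(ep)

    def test_few_eligible_warns(self, rng):
        ep = self.make_episodes(rng, n=30)
        with pytest.warns(UserWarning, match="eligible"):
            risk.season_repeat_model(ep)


class TestStuntingFeatures:
    def make_inputs(self):
        monthly = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "c"],
                "sex": ["F", "F", "M", "F"],
                "month": [7, 21, 3, 10],
                "stunted": [0.0, 1.0, 0.0, 0.0],
                "wasted": [1.0, 0.0, 0.0, 0.0],
            }
        )
        re = pd.DataFrame(
            {
                "u0": [0.1, -0.2, 0.0],
                "u1_age": [0.01, 0.0, -0.01],
                "a_sin": [0.2, 0.0, 0.1],
                "b_cos": [0.0, 0.1, -0.1],
                "ccv": [0.2, 0.1, 0.141],
            },
            index=pd.Index(["a", "b", "c"], name="subject_id"),
        )
        outcome = pd.Series(
            [1.0, 0.0, np.nan], index=pd.Index(["a", "b", "c"], name="subject_id"),
            name="stunted_20_24",
        )
        sex = pd.Series(["F", "M", "F"], index=outcome.index)
        return monthly, re, outcome, sex

    def test_window_boundary_and_row_count(self):
        monthly, re, outcome, sex = self.make_inputs()
        feats = risk.build_stunting_features(monthly, re, outcome, sex)
        assert len(feats) == 2  # only subjects with non-missing outcome
        # subject a: stunted only at month 21 -> not "ever stunted < 20 mo"
        assert feats.loc["a", "ever_stunted"] == 0.0
        assert feats.loc["a", "ever_wasted"] == 1.0  # wasted at month 7
        assert feats.loc["b", "sex_boy"] == 1.0


@pytest.fixture(scope="module")
def features():
    rng = np.random.default_rng(12)
    n = 2500
    sex = (rng.random(n) < 0.5).astype(float)
    ever_w = (rng.random(n) < 0.3).astype(float)
    ever_s = (rng.random(n) < 0.35 + 0.2 * ever_w).astype(float)
    ccv = np.abs(rng.normal(0.2, 0.12, n))
    eta = -2.2 + 0.1 * sex + 2.3 * ever_s + 0.5 * ever_w + 1.2 * ccv
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return pd.DataFrame(
        {
            "sex_boy": sex,
            "ever_stunted": ever_s,
            "ever_wasted": ever_w,
            "re_intercept": rng.normal(0, 0.5, n),
            "re_slope": rng.normal(0, 0.02, n),
            "ccv": ccv,
            "stunted_20_24": y,
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
    )


class TestStuntingModels:
    def test_nested_loglikelihoods(self, features):
        models = risk.fit_stunting_models(features)
        assert models["I"].llf <= models["II"].llf <= models["III"].llf
        assert models["I"].n == models["II"].n == models["III"].n

    def test_ever_wasted_or_above_one_under_coupling(self, features):
        models = risk.fit_stunting_models(features)
        tab = models["II"].table().set_index("term")
        assert tab.loc["ever_wasted", "odds_ratio"] > 1.0

    def test_null_coupling_ci_covers_one(self):
        rng = np.random.default_rng(5)
        n = 3000
        ever_w = (rng.random(n) < 0.3).astype(float)
        ever_s = (rng.random(n) < 0.35).astype(float)
        eta = -1.5 + 2.0 * ever_s
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        feats = pd.DataFrame(
            {
                "sex_boy": (rng.random(n) < 0.5).astype(float),
                "ever_stunted": ever_s,
                "ever_wasted": ever_w,
                "re_intercept": rng.normal(0, 0.5, n),
                "re_slope": rng.normal(0, 0.02, n),
                "ccv": np.abs(rng.normal(0.2, 0.1, n)),
                "stunted_20_24": y,
            }
        )
        tab = risk.fit_stunting_models(feats)["II"].table().set_index("term")
        lo, hi = tab.loc["ever_wasted", ["ci_low", "ci_high"]]
        assert lo < 1.0 < hi


def brute_force_rates(y, pred):
    tp = sum(1 for a, b in zip(y, pred) if a == 1 and b)
    fn = sum(1 for a, b in zip(y, pred) if a == 1 and not b)
    fp = sum(1 for a, b in zip(y, pred) if a == 0 and b)
    tn = sum(1 for a, b in zip(y, pred) if a == 0 and not b)
    return (
        100 * (fn + fp) / len(y),
        100 * fn / (tp + fn) if tp + fn else np.nan,
        100 * fp / (fp + tn) if fp + tn else np.nan,
    )


class TestDiagnostics:
    def test_perfect_predictor_all_zero(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = risk.LogisticFitResult(
            terms=["intercept"], coef=np.array([0.0]), se=np.array([1.0]),
            n=20, llf=0.0, fitted_prob=np.where(y == 1, 0.99, 0.01),
        )
        d = risk.classification_diagnostics(fit, y)
        assert (d.error_rate, d.false_negative_rate, d.false_positive_rate) == (0, 0, 0)

    def test_constant_predictor_degenerate_case(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = risk.LogisticFitResult(
            terms=["intercept"], coef=np.array([np.log(0.3 / 0.7)]),
            se=np.array([1.0]), n=100, llf=0.0, fitted_prob=np.full(100, 0.3),
        )
        d = risk.classification_diagnostics(fit, y, threshold=0.5)
        assert d.error_rate == pytest.approx(30.0)
        assert d.false_negative_rate == pytest.approx(100.0)
        assert d.false_positive_rate == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_confusion_matrix(self, seed):
        rng = np.random.default_rng(seed)
        y, X = logistic_data(rng, n=300)
        fit = risk.fit_logistic(y, X)
        thr = rng.uniform(0.2, 0.8)
        d = risk.classification_diagnostics(fit, y, threshold=thr)
        want = brute_force_rates(y, fit.fitted_prob >= thr)
        got = (d.error_rate, d.false_negative_rate, d.false_positive_rate)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_threshold_bounds(self):
        fit = risk.LogisticFitResult(
            terms=["intercept"], coef=np.array([0.0]), se=np.array([1.0]),
            n=2, llf=0.0, fitted_prob=np.array([0.4, 0.6]),
        )
        with pytest.raises(ValueError):
            risk.classification_diagnostics(fit, np.array([0, 1]), threshold=1.5)

    def test_intercept_only_error_bounded_by_base_rate(self, rng):
        y = (rng.random(500) < 0.35).astype(float)
        X = pd.DataFrame({"intercept": np.ones(500)})
        fit = risk.fit_logistic(y, X)
        d = risk.classification_diagnostics(fit, y)
        prevalence_ = y.mean()
        assert d.error_rate <= 100 * max(prevalence_, 1 - prevalence_) + 1e-9
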