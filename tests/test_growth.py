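"""Spline/Fourier design, mixed-model fitting, trajectories and the CCV."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline

from wastunt import growth, lms
from wastunt.simulate import SyntheticConfig, generate_cohort


class TestFourierBasis:
    def test_quarter_period(self):
        out = growth.fourier_basis(365.25 / 4, order=1)
        np.testing.assert_allclose(out, [[1.0, 0.0]], atol=1e-12)

    def test_second_order_has_four_columns(self):
        assert growth.fourier_basis([10.0, 40.0], order=2).shape == (2, 4)

    def test_periodicity(self):
        t = np.array([3.0, 100.0, 300.0])
        a = growth.fourier_basis(t, order=2)
        b = growth.fourier_basis(t + 365.25, order=2)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            growth.fourier_basis([1.0], order=3)


class TestNaturalSpline:
    KNOTS = (6.0, 12.0, 18.0)

    def test_column_count(self):
        B = growth.natural_cubic_spline_basis(np.linspace(0, 24, 10), self.KNOTS)
        assert B.shape[1] == len(self.KNOTS) + 1

    def test_continuity_at_boundary(self):
        eps = 1e-7
        inside = growth.natural_cubic_spline_basis([24.0 - eps], self.KNOTS)
        at = growth.natural_cubic_spline_basis([24.0], self.KNOTS)
        np.testing.assert_allclose(inside, at, atol=1e-4)

    def test_second_derivative_zero_at_boundaries(self):
        h = 1e-4
        for x0 in (0.0, 24.0):
            pts = growth.natural_cubic_spline_basis([x0 - h, x0, x0 + h], self.KNOTS)
            second = (pts[0] - 2 * pts[1] + pts[2]) / h**2
            np.testing.assert_allclose(second, 0.0, atol=1e-3)

    def test_linear_extrapolation(self):
        B = growth.natural_cubic_spline_basis([26.0, 28.0, 30.0], self.KNOTS)
        slopes = np.diff(B, axis=0) / 2.0
        np.testing.assert_allclose(slopes[0], slopes[1], atol=1e-8)

    def test_spans_natural_spline_space(self, rng):
        """Basis reproduces an arbitrary natural cubic spline exactly."""
        all_knots = np.array([0.0, *self.KNOTS, 24.0])
        values = rng.normal(size=len(all_knots))
        ref = CubicSpline(all_knots, values, bc_type="natural")
        x = np.linspace(0, 24, 200)
        B = np.column_stack(
            [np.ones_like(x), growth.natural_cubic_spline_basis(x, self.KNOTS)]
        )
        coef, res, *_ = np.linalg.lstsq(B, ref(x), rcond=None)
        resid = B @ coef - ref(x)
        assert np.max(np.abs(resid)) < 1e-8


class TestBuildDesign:
    def make_visits(self, dates, subject="s1", wlz=None):
        dates = pd.to_datetime(dates)
        dob = dates.min() - pd.Timedelta(days=30)
        return pd.DataFrame(
            {
                "subject_id": subject,
                "sex": "F",
                "dob": dob,
                "visit_date": dates,
                "age_months": (dates - dob).days / (365.25 / 12),
                "wlz": wlz if wlz is not None else np.zeros(len(dates)),
                "laz": 0.0,
            }
        )

    def test_shapes_and_groups(self):
        v = self.make_visits(["1990-02-01", "1990-05-01", "1990-08-01"])
        frame = growth.build_design(v, growth.GrowthDesignSpec(interior_knots=(6.0,)))
        assert len(frame.y) == 3
        assert (frame.groups == "s1").all()
        assert list(frame.Z.columns) == ["u0", "u1_age", "a_sin", "b_cos"]

    def test_fourier_column_values_on_fixed_date(self):
        v = self.make_visits(["1990-03-01"] * 3)
        frame = growth.build_design(v, growth.GrowthDesignSpec(interior_knots=(6.0,)))
        doy = pd.Timestamp("1990-03-01").dayofyear
        want = np.sin(2 * np.pi * doy / 365.25)
        np.testing.assert_allclose(frame.X["sin_1"], want, atol=1e-12)

    def test_interaction_is_elementwise_product(self):
        v = self.make_visits(["1990-02-01", "1990-07-01", "1991-01-15"])
        frame = growth.build_design(v, growth.GrowthDesignSpec(interior_knots=(6.0,)))
        ages = frame.Z["u1_age"]
        np.testing.assert_allclose(
            frame.X["age_sin_1"], ages * frame.X["sin_1"], atol=1e-12
        )

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            growth.build_design(self.make_visits([]).iloc[:0])

    def test_random_order_not_exceeding_fixed(self):
        with pytest.raises(ValueError):
            growth.GrowthDesignSpec(fourier_order_fixed=1, fourier_order_random=2)


class TestFit:
    def test_zero_seasonal_amplitude_recovers_null(self, refs):
        cfg = SyntheticConfig(
            n_subjects=250,
            seed=3,
            wlz_seasonal_amplitude=0.0,
            laz_seasonal_amplitude=0.0,
            re_seasonal_sd=0.0,
        )
        lfa, wfl = refs
        visits, _ = generate_cohort(cfg, refs=refs)
        visits = lms.add_zscores(visits, lfa, wfl)
        fit = growth.fit_growth_model(growth.build_design(visits))
        for term in ("sin_1", "cos_1", "sin_2", "cos_2"):
            assert abs(fit.fe_params[term]) < 3 * fit.fe_se[term] + 0.02

    def test_deterministic_refit(self, small_cohort):
        frame = growth.build_design(small_cohort["visits"])
        f1 = growth.fit_growth_model(frame)
        f2 = growth.fit_growth_model(frame)
        pd.testing.assert_series_equal(f1.fe_params, f2.fe_params)

    def test_too_few_subjects_rejected(self):
        v = TestBuildDesign().make_visits(["1990-02-01", "1990-05-01"])
        with pytest.raises(ValueError):
            growth.fit_growth_model(
                growth.build_design(v, growth.GrowthDesignSpec(interior_knots=(6.0,)))
            )

    def test_shrinkage_of_random_effects(self, small_growth_fit):
        fit = small_growth_fit
        for col in fit.random_effects.columns:
            assert fit.random_effects[col].var() <= fit.cov_re.loc[col, col] * 1.05

    def test_seasonal_prediction_integrates_to_zero(self, small_growth_fit):
        doy = np.linspace(0, 365.25, 2000, endpoint=False)
        four = growth.fourier_basis(doy, 2)
        seas = four @ small_growth_fit.fe_params[
            ["sin_1", "cos_1", "sin_2", "cos_2"]
        ].to_numpy()
        assert abs(seas.mean()) < 1e-3


class TestByOutcomeGroup:
    def test_two_strata_two_fits(self, small_cohort):
        from wastunt import prevalence

        visits = small_cohort["visits"]
        outcome = prevalence.outcome_stunted_20_24(visits)
        fits = growth.fit_by_outcome_group(visits, outcome, by_sex=False)
        assert set(fits) == {("all", False), ("all", True)}

    def test_sparse_stratum_skipped_with_warning(self, small_cohort):
        visits = small_cohort["visits"]
        subjects = visits["subject_id"].unique()
        outcome = pd.Series(0.0, index=pd.Index(subjects, name="subject_id"))
        outcome.iloc[:3] = 1.0  # tiny stratum
        with pytest.warns(UserWarning, match="skipped"):
            fits = growth.fit_by_outcome_group(visits, outcome, by_sex=False)
        assert ("all", True) not in fits

    def test_stunted_group_lower_wlz_mid_infancy(self, small_cohort):
        from wastunt import prevalence

        visits = small_cohort["visits"]
        outcome = prevalence.outcome_stunted_20_24(visits)
        fits = growth.fit_by_outcome_group(visits, outcome, by_sex=False)
        ages = np.linspace(5, 10, 11)
        lo = growth.predict_trajectory(fits[("all", True)], "1990-03-01", ages)
        hi = growth.predict_trajectory(fits[("all", False)], "1990-03-01", ages)
        assert lo["predicted_z"].mean() < hi["predicted_z"].mean()


class TestPredict:
    def test_periodic_dobs_identical(self, small_growth_fit):
        ages = np.linspace(0, 20, 41)
        a = growth.predict_trajectory(small_growth_fit, "1990-03-01", ages)
        b = growth.predict_trajectory(small_growth_fit, "1991-03-01", ages)
        # one year apart: same day-of-year pattern up to leap-day rounding
        np.testing.assert_allclose(
            a["predicted_z"], b["predicted_z"], atol=5e-3
        )

    def test_zero_amplitude_fit_dob_independent(self, small_growth_fit):
        fit = small_growth_fit
        neutered = growth.GrowthModelFit(
            fe_params=fit.fe_params.copy(),
            fe_se=fit.fe_se,
            cov_re=fit.cov_re,
            resid_var=fit.resid_var,
            random_effects=fit.random_effects,
            converged=True,
            method=fit.method,
            llf=fit.llf,
            spec=fit.spec,
            knots=fit.knots,
            response=fit.response,
            n_subjects=fit.n_subjects,
            n_obs=fit.n_obs,
        )
        for term in ("sin_1", "cos_1", "sin_2", "cos_2", "age_sin_1", "age_cos_1"):
            neutered.fe_params[term] = 0.0
        ages = np.linspace(0, 20, 21)
        a = growth.predict_trajectory(neutered, "1990-03-01", ages)["predicted_z"]
        b = growth.predict_trajectory(neutered, "1990-08-20", ages)["predicted_z"]
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCCV:
    @pytest.mark.parametrize("a,b,expected", [(0, 0, 0.0), (3, 4, 5.0)])
    def test_amplitude(self, a, b, expected):
        assert growth.compute_ccv(a, b) == pytest.approx(expected)

    def test_phase_rotation_invariant(self, rng):
        a, b = rng.normal(size=2)
        assert growth.compute_ccv(a, b) == pytest.approx(growth.compute_ccv(b, -a))

    def test_summary_columns(self, small_growth_fit):
        summ = growth.subject_seasonal_summary(small_growth_fit)
        assert {"u0", "u1_age", "a_sin", "b_cos", "ccv"} <= set(summ.columns)
        assert (summ["ccv"] >= 0).all()
        zero = summ["ccv"] == 0
        assert (zero == ((summ["a_sin"] == 0) & (summ["b_cos"] == 0))).all()


class TestSeasonalPhase:
    def test_laz_phase_lags_wlz_phase(self, refs):
        """Planted 90-day length-after-weight lag is recoverable from the fits."""
        lfa, wfl = refs
        cfg = SyntheticConfig(n_subjects=400, seed=9, laz_seasonal_amplitude=0.25)
        visits, _ = generate_cohort(cfg, refs=refs)
        visits = lms.add_zscores(visits, lfa, wfl)
        fw = growth.fit_growth_model(growth.build_design(visits, response="wlz"))
        fl = growth.fit_growth_model(growth.build_design(visits, response="laz"))
        lag = (growth.seasonal_peak_doy(fl) - growth.seasonal_peak_doy(fw)) % 365.25
        assert 30.0 < lag < 160.0
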