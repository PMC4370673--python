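"""Censored time-to-detection model: fit, selection, prediction, curves."""

import numpy as np
import pandas as pd
import pytest

from bellwether.survival import (
    CENSOR_MINUTES,
    SurveyRecord,
    fit_ttd_model,
    filter_ever_detected,
    select_model_aic,
    survival_curves,
)
from bellwether.synthetic import GeneratorParams, generate_field_surveys, true_log_acceleration

from conftest import make_exponential_surveys


class TestFilterEverDetected:
    def test_partitions_by_any_detection(self):
        rows = []
        for pond, any_det in [("a", True), ("b", False)]:
            for i in range(6):
                det = any_det and i == 0
                rows.append(
                    SurveyRecord(pond, 2009, "early", "dipnet", "o",
                                 10.0 if det else 30.0, det)
                )
        inc, exc = filter_ever_detected(rows)
        assert set(inc["pond"]) == {"a"} and set(exc["pond"]) == {"b"}
        assert len(inc) == len(exc) == 6

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_ever_detected([])

    def test_fieldlike_split_roughly_half(self, fieldlike_surveys):
        inc, exc = filter_ever_detected(fieldlike_surveys)
        n_inc = inc["pond"].nunique()
        assert 12 <= n_inc <= 22
        assert n_inc + exc["pond"].nunique() == 32


class TestCensoredExponentialOracle:
    def test_intercept_only_mle_closed_form(self):
        """The censored-exponential MLE of the mean is
        (total observed time) / (number of events)."""
        rng = np.random.default_rng(3)
        df = make_exponential_surveys(80, 12.0, rng)
        fit = fit_ttd_model(df, set(), family="exponential")
        closed_form = df["time_min"].sum() / df["detected"].sum()
        assert np.exp(fit.params[0]) == pytest.approx(closed_form, rel=1e-6)
        # AIC from the closed-form log-likelihood: events contribute
        # log(1/m) - t/m, censored records -t/m
        m = closed_form
        loglik = -df["detected"].sum() * np.log(m) - df["time_min"].sum() / m
        assert fit.aic == pytest.approx(2 * 1 - 2 * loglik, rel=1e-9)

    def test_exponential_curve_closed_form(self):
        rng = np.random.default_rng(4)
        df = make_exponential_surveys(60, 15.0, rng)
        fit = fit_ttd_model(df, set(), family="exponential")
        curves = survival_curves(fit, "year", times=np.array([0.0, 5.0, 20.0]))
        m = np.exp(fit.params[0])
        # no covariates: both year columns equal exp(-t/m)
        for col in curves.columns:
            assert curves[col].to_numpy() == pytest.approx(
                np.exp(-np.array([0.0, 5.0, 20.0]) / m)
            )


class TestAgainstLifelines:
    def test_weibull_fit_matches_independent_implementation(self):
        """Coefficients, scale and AIC agree with lifelines'
        WeibullAFTFitter on the same censored data."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        df = make_exponential_surveys(150, 10.0, rng, year_ratio=2.0)
        fit = fit_ttd_model(df, {"year"}, family="weibull")
        ldf = pd.DataFrame(
            {
                "T": df["time_min"],
                "E": df["detected"].astype(int),
                "y2010": (df["year"] == 2010).astype(float),
            }
        )
        aft = lifelines.WeibullAFTFitter().fit(ldf, "T", "E", formula="y2010")
        lam = aft.params_["lambda_"]
        assert fit.params[0] == pytest.approx(lam["Intercept"], abs=1e-4)
        assert fit.coefficients()["year[2010]"] == pytest.approx(
            lam["y2010"], abs=1e-4
        )
        assert fit.scale == pytest.approx(1.0 / np.exp(aft.params_["rho_"]["Intercept"]), abs=1e-4)
        assert fit.aic == pytest.approx(aft.AIC_, abs=1e-4)
        # delta-method SEs agree too
        se = fit.coefficient_se()["year[2010]"]
        lse = aft.standard_errors_["lambda_"]["y2010"]
        assert se == pytest.approx(lse, rel=0.02)


class TestParameterRecovery:
    def test_known_coefficients_recovered_at_study_size(self):
        """Fits on generated data recover the true log-acceleration
        factors within 2 SE in >= 90% of 100 replicates (n = 192)."""
        params = GeneratorParams(
            baseline_mean_ttd=10.0,
            year_factors={"2009": 2.5, "2010": 1.0},
            method_factors={"day_visual": 1.6, "dipnet": 1.2, "night_visual": 1.0},
            window_factors={"early": 1.0, "middle": 1.0, "late": 1.0},
            shape=1.2,
        )
        truth = true_log_acceleration(params)["year[2010]"]
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(100):
            df = generate_field_surveys(params=params, rng=rng)
            fit = fit_ttd_model(df, {"year", "method"})
            est = fit.coefficients()["year[2010]"]
            se = fit.coefficient_se()["year[2010]"]
            hits += abs(est - truth) <= 2 * se
        assert hits >= 90


class TestModelSelection:
    def test_single_candidate_returned_unchanged(self):
        rng = np.random.default_rng(5)
        df = make_exponential_surveys(60, 10.0, rng, year_ratio=2.0)
        best, table = select_model_aic(df, main_effects=("year",))
        assert len(table) == 2  # intercept-only and year
        assert set(best.terms) <= {"year"}

    def test_noise_covariate_never_reduces_deviance(self):
        """Adding a pure-noise covariate cannot decrease -2 logL."""
        rng = np.random.default_rng(6)
        df = make_exponential_surveys(100, 10.0, rng, year_ratio=2.0)
        df["observer"] = rng.choice(["obs_a", "obs_b"], size=len(df))
        small = fit_ttd_model(df, {"year"})
        big = fit_ttd_model(df, {"year", "observer"})
        assert -2 * big.loglik <= -2 * small.loglik + 1e-6

    def test_strong_year_effect_selected_without_spurious_interaction(self):
        """On data generated with only a year effect, selection keeps
        'year' and drops the year:method interaction >= 90% of the time."""
        params = GeneratorParams(
            baseline_mean_ttd=8.0,
            year_factors={"2009": 3.0, "2010": 1.0},
            method_factors={"day_visual": 1.0, "dipnet": 1.0, "night_visual": 1.0},
            window_factors={"early": 1.0, "middle": 1.0, "late": 1.0},
            shape=1.2,
        )
        rng = np.random.default_rng(99)
        good = 0
        for _ in range(100):
            df = generate_field_surveys(params=params, rng=rng)
            best, _ = select_model_aic(df, main_effects=("year", "method"))
            good += ("year" in best.terms) and (("method", "year") not in best.terms)
        assert good >= 90


@pytest.fixture(scope="module")
def fieldlike_fit(fieldlike_surveys):
    inc, _ = filter_ever_detected(fieldlike_surveys)
    return fit_ttd_model(inc, {"year", "method"})


class TestPredictionAndCurves:
    def test_predicted_means_positive_with_se(self, fieldlike_fit):
        for var in ("year", "method"):
            tab = fieldlike_fit.predicted_mean_ttd(var)
            assert (tab["mean_ttd"] > 0).all()
            assert (tab["se"] > 0).all()

    def test_ratio_statistic_at_least_one(self, fieldlike_fit):
        assert fieldlike_fit.ratio_statistic("year") >= 1.0
        assert fieldlike_fit.ratio_statistic("method") >= 1.0

    def test_curves_start_at_one_and_decrease(self, fieldlike_fit):
        curves = survival_curves(fieldlike_fit, "year")
        assert np.allclose(curves.iloc[0], 1.0)
        assert (curves.diff().iloc[1:] <= 1e-12).all().all()

    def test_faster_category_has_lower_curve(self, fieldlike_fit):
        curves = survival_curves(fieldlike_fit, "year")
        means = fieldlike_fit.predicted_mean_ttd("year", with_se=False)["mean_ttd"]
        fast, slow = means.idxmin(), means.idxmax()
        inner = curves.iloc[1:]
        assert (inner[fast] <= inner[slow] + 1e-12).all()

    def test_all_pond_fit_scales_up_but_preserves_order(self, fieldlike_surveys):
        """Keeping never-detected ponds inflates predicted mean TTD for
        every category but does not change the category ordering."""
        inc, _ = filter_ever_detected(fieldlike_surveys)
        fit17 = fit_ttd_model(inc, {"year", "method"})
        fit32 = fit_ttd_model(fieldlike_surveys, {"year", "method"})
        for var in ("year", "method"):
            m17 = fit17.predicted_mean_ttd(var, with_se=False)["mean_ttd"]
            m32 = fit32.predicted_mean_ttd(var, with_se=False)["mean_ttd"]
            assert (m32 > m17).all()
            assert list(m17.sort_values().index) == list(m32.sort_values().index)


class TestValidation:
    def test_all_censored_input_rejected(self):
        rows = [SurveyRecord("a", 2009, "early", "dipnet", "o", 30.0, False)] * 4
        with pytest.raises(ValueError):
            fit_ttd_model(rows, set())

    def test_interaction_without_parents_rejected(self):
        rng = np.random.default_rng(8)
        df = make_exponential_surveys(40, 10.0, rng)
        with pytest.raises(ValueError):
            fit_ttd_model(df, {("year", "method")})

    def test_record_invariants(self):
        with pytest.raises(ValueError):
            SurveyRecord("a", 2009, "early", "dipnet", "o", 31.0, True)
        with pytest.raises(ValueError):
            SurveyRecord("a", 2009, "early", "dipnet", "o", 12.0, False)
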