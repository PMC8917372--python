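"""Survey-weighted logistic models: specs, fitting, GOF, margins."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import nurselabor as nl
from nurselabor.exceptions import ConfigurationError, SeparationError
from nurselabor.models import design_matrix


class TestModelSpec:
    def test_level_one_terms(self):
        spec = nl.build_model_spec("employed_only", 1)
        assert set(spec.terms) == {"quarter", "year", "sector", "sector:year"}

    def test_level_two_adds_individual_covariates(self):
        spec = nl.build_model_spec("underemployed_plus_employed", 2)
        assert {"sex", "age_band", "marital", "university", "n_jobs"} \
            <= set(spec.terms)
        assert "residence" not in spec.terms and "region" not in spec.terms

    def test_nesting(self):
        for sample in ("employed_only", "underemployed_plus_employed"):
            t1 = set(nl.build_model_spec(sample, 1).terms)
            t2 = set(nl.build_model_spec(sample, 2).terms)
            t3 = set(nl.build_model_spec(sample, 3).terms)
            assert t1 < t2 < t3

    def test_unknown_level_or_sample(self):
        with pytest.raises(ConfigurationError):
            nl.build_model_spec("employed_only", 4)
        with pytest.raises(ConfigurationError):
            nl.build_model_spec("everyone", 1)


def _mle_fixture(n=200, seed=3):
    """Random covariates + logistic outcome; equal weights, SRS design."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "quarter": rng.integers(1, 5, n),
        "year": rng.integers(2005, 2007, n),
        "sector": rng.choice(["public", "private"], n),
        "stratum_id": 0, "psu_id": np.arange(n), "weight": 1.0,
        "labor_status": "employed_health",
    })
    spec = nl.build_model_spec("employed_only", 1)
    X, names = design_matrix(df, spec)
    beta = rng.normal(0, 0.5, X.shape[1])
    df["non_precarious_employment"] = (
        rng.random(n) < expit(X @ beta)).astype(int)
    return df, spec, X


class TestFitSurveyLogit:
    def test_equal_weight_fit_matches_mle_oracle(self):
        """With equal weights and a degenerate design the pseudo-MLE must
        agree with an ordinary GLM maximum-likelihood fit to 1e-6."""
        sm = pytest.importorskip("statsmodels.api")
        df, spec, X = _mle_fixture()
        fit = nl.fit_survey_logit(df, spec, nl.SurveyDesign())
        oracle = sm.GLM(df["non_precarious_employment"].to_numpy(float), X,
                        family=sm.families.Binomial()).fit()
        assert np.abs(fit.beta.to_numpy() - oracle.params).max() < 1e-6

    def test_constant_outcome_raises(self):
        df, spec, _ = _mle_fixture()
        df["non_precarious_employment"] = 1
        with pytest.raises(SeparationError):
            nl.fit_survey_logit(df, spec, nl.SurveyDesign())

    def test_perfect_separation_detected(self):
        df, spec, _ = _mle_fixture()
        df["non_precarious_employment"] = (df["sector"] == "public").astype(int)
        with pytest.raises(SeparationError):
            nl.fit_survey_logit(df, spec, nl.SurveyDesign())

    def test_collinear_columns_reported(self):
        n = 50
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        X = np.column_stack([X, X[:, 1]])  # duplicate
        y = rng.integers(0, 2, n).astype(float)
        with pytest.raises(ConfigurationError, match="collinear"):
            nl.fit_logit_arrays(X, y, np.ones(n),
                                np.zeros(n).astype(str),
                                np.arange(n).astype(str),
                                names=["intercept", "x", "x_copy"])

    def test_nested_loglikelihood_monotone(self, small_sample, design):
        sample, _ = small_sample
        sub = nl.select_sample(sample, "employed_only")
        lls = []
        for level in (1, 2, 3):
            spec = nl.build_model_spec("employed_only", level)
            lls.append(nl.fit_survey_logit(sub, spec, design).loglik)
        assert lls[0] <= lls[1] + 1e-6 <= lls[2] + 2e-6

    def test_missing_term_values_rejected(self, small_sample, design):
        sample, _ = small_sample
        sub = nl.select_sample(sample, "employed_only").copy()
        sub.loc[sub.index[:5], "sex"] = pd.NA
        with pytest.raises(ConfigurationError, match="sex"):
            nl.fit_survey_logit(sub, nl.build_model_spec("employed_only", 2),
                                design)


class TestAdjustedOddsRatios:
    def test_zero_coefficient_gives_unit_aor(self):
        n = 500
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        y = (rng.random(n) < 0.5).astype(float)
        fit = nl.fit_logit_arrays(X, y, np.ones(n), np.zeros(n).astype(str),
                                  np.arange(n).astype(str),
                                  names=["intercept", "x"])
        fit.beta["x"] = 0.0
        aor = nl.adjusted_odds_ratios(fit, "x")
        assert aor["aor"] == pytest.approx(1.0)
        assert aor["ci_low"] < 1.0 < aor["ci_high"]

    def test_closed_form_exponentiation(self):
        """beta = log 2 with a +/-1.96 se margin of log 1.5 gives a CI of
        about (2/1.5, 2*1.5) on a large-df fit."""
        n = 4000
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = (rng.random(n) < expit(X @ np.array([0.0, 0.7]))).astype(float)
        fit = nl.fit_logit_arrays(X, y, np.ones(n), np.zeros(n).astype(str),
                                  np.arange(n).astype(str),
                                  names=["intercept", "x"])
        fit.beta["x"] = math.log(2.0)
        se = math.log(1.5) / 1.96
        fit.vcov.loc["x", "x"] = se ** 2
        aor = nl.adjusted_odds_ratios(fit, "x")
        assert aor["aor"] == pytest.approx(2.0)
        assert aor["ci_low"] == pytest.approx(2 / 1.5, rel=1e-3)
        assert aor["ci_high"] == pytest.approx(2 * 1.5, rel=1e-3)

    def test_unknown_term_lookup_error(self):
        df, spec, _ = _mle_fixture()
        fit = nl.fit_survey_logit(df, spec, nl.SurveyDesign())
        with pytest.raises(KeyError):
            nl.adjusted_odds_ratios(fit, "no_such_term")


class TestArcherLemeshow:
    def test_identical_fitted_probabilities_rejected(self):
        n = 200
        rng = np.random.default_rng(5)
        X = np.ones((n, 1))
        y = (rng.random(n) < 0.4).astype(float)
        fit = nl.fit_logit_arrays(X, y, np.ones(n), np.zeros(n).astype(str),
                                  np.arange(n).astype(str),
                                  names=["intercept"])
        with pytest.raises(ConfigurationError):
            nl.archer_lemeshow_gof(fit, n_groups=10)

    def test_invalid_group_count(self, small_sample, design):
        sample, _ = small_sample
        sub = nl.select_sample(sample, "employed_only")
        fit = nl.fit_survey_logit(sub, nl.build_model_spec("employed_only", 2),
                                  design)
        with pytest.raises(ConfigurationError):
            nl.archer_lemeshow_gof(fit, n_groups=1)

    def test_well_specified_model_not_rejected(self, small_sample, design):
        sample, _ = small_sample
        sub = nl.select_sample(sample, "employed_only")
        fit = nl.fit_survey_logit(sub, nl.build_model_spec("employed_only", 3),
                                  design)
        gof = nl.archer_lemeshow_gof(fit)
        assert gof.f_statistic >= 0
        assert 0 <= gof.p_value <= 1
        assert gof.df1 == 9


class TestAdjustedPrevalence:
    def _srs_fit(self, df, spec):
        return nl.fit_survey_logit(df, spec, nl.SurveyDesign())

    def test_intercept_only_margin_is_overall_prevalence(self):
        n = 400
        rng = np.random.default_rng(6)
        y = (rng.random(n) < 0.35).astype(float)
        w = rng.lognormal(0, 0.3, n)
        fit = nl.fit_logit_arrays(np.ones((n, 1)), y, w,
                                  np.zeros(n).astype(str),
                                  np.arange(n).astype(str),
                                  names=["intercept"])
        data = pd.DataFrame({"period": ["2005-2006"] * (n // 2)
                             + ["2019"] * (n - n // 2),
                             "region": 1})
        table = nl.adjusted_prevalence(fit, data, by=["period", "region"])
        overall = float(np.average(y, weights=w))
        assert np.allclose(table["estimate"], overall, atol=1e-12)

    def test_margins_invariant_to_weight_rescaling(self, small_sample, design):
        sample, _ = small_sample
        sub = nl.select_sample(sample, "employed_only")
        spec = nl.build_model_spec("employed_only", 3)
        fit1 = nl.fit_survey_logit(sub, spec, design)
        t1 = nl.adjusted_prevalence(fit1, sub)
        scaled = sub.copy()
        scaled["weight"] = scaled["weight"] * 11.0
        fit2 = nl.fit_survey_logit(scaled, spec, design)
        t2 = nl.adjusted_prevalence(fit2, scaled)
        assert np.allclose(t1["estimate"], t2["estimate"], rtol=1e-9)
        assert np.allclose(t1["se"], t2["se"], rtol=1e-7)

    def test_margins_track_generator_truth(self, small_sample, design):
        """Period-level margins stay close to the sector-mix-weighted
        ground-truth zero-score probability."""
        sample, _ = small_sample
        sub = nl.select_sample(sample, "employed_only")
        spec = nl.build_model_spec("employed_only", 3)
        fit = nl.fit_survey_logit(sub, spec, design)
        table = nl.adjusted_prevalence(fit, sub, by=["period"])
        params = nl.SimulationParams()
        truth = nl.expected_truth(params, n_draws=50_000)
        tbl = truth.p_nonprecarious.set_index(["sector", "year"])
        for _, row in table.iterrows():
            years = [b for b in nl.PERIOD_BINS if b.label == row["period"]][0]
            mids = list(range(years.start, years.end + 1))
            p_mix = np.mean([
                params.p_public_employed * tbl.loc[("public", y)].iloc[0]
                + (1 - params.p_public_employed) * tbl.loc[("private", y)].iloc[0]
                for y in mids])
            assert abs(row["estimate"] - p_mix) < max(4 * row["se"], 0.04)
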