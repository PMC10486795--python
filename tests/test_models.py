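"""Logistic model families, subset selection, and the random-intercept
mixed model with its variance partition coefficient."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from perirad.models import (
    LOGISTIC_RESIDUAL_VAR,
    backward_select,
    fit_logistic,
    fit_mem,
    forward_select,
    screen_clinical,
    select_model,
    univariate_screen,
    vpc_from_sigma2,
)
from perirad.phantom import CohortConfig, make_cohort


class TestFitLogistic:
    def test_two_by_two_closed_form_odds_ratio(self):
        # exposed: 20 events / 10 non-events; unexposed: 10 / 20 -> OR = 4
        y = [1] * 20 + [0] * 10 + [1] * 10 + [0] * 20
        x = [1] * 30 + [0] * 30
        t = pd.DataFrame({"y": y, "x": x})
        fit = fit_logistic(t, "y", ["x"])
        assert fit.terms.loc["x", "odds_ratio"] == pytest.approx(4.0, rel=1e-6)
        assert fit.terms.loc["x", "ci_low"] < 4.0 < fit.terms.loc["x", "ci_high"]

    def test_odds_ratio_is_exp_coefficient(self):
        t = make_cohort(CohortConfig(n_patients=400, seed=0,
                                     beta_clinical={"major_hepatectomy": 0.5}))
        fit = fit_logistic(t, "G3", ["major_hepatectomy", "cirrhosis"])
        np.testing.assert_allclose(fit.terms["odds_ratio"], np.exp(fit.terms["coef"]))

    def test_null_model_coefficients_small(self):
        t = make_cohort(CohortConfig(n_patients=4000, center_sd=0.0, seed=1,
                                     feature_names=("f1", "f2", "f3")))
        fit = fit_logistic(t, "G3", ["f1", "f2", "f3"])
        assert np.abs(fit.terms["coef"]).max() < 0.12
        assert (fit.terms["p_value"] > 0.001).all()

    def test_ridge_large_penalty_shrinks_coefficients(self):
        from sklearn.linear_model import LogisticRegression

        t = make_cohort(CohortConfig(n_patients=500, seed=2,
                                     beta_features={"f1": 1.0},
                                     feature_names=("f1",)))
        X = t[["f1"]].to_numpy()
        y = t["G3"].to_numpy()
        big = LogisticRegression(penalty="l2", C=1e-6).fit(X, y).coef_.ravel()
        assert np.abs(big).max() < 0.01

    def test_single_class_outcome_rejected(self):
        t = pd.DataFrame({"y": [1, 1, 1], "x": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(t, "y", ["x"])

    def test_separation_flagged(self):
        t = pd.DataFrame({"y": [0] * 10 + [1] * 10,
                          "x": list(range(10)) + list(range(20, 30))})
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(t, "y", ["x"])
        assert fit.separation

    def test_lasso_zeroes_out_noise(self):
        t = make_cohort(CohortConfig(n_patients=1500, center_sd=0.0, seed=3,
                                     beta_features={"f1": 1.2},
                                     feature_names=("f1", "n1", "n2", "n3")))
        fit = fit_logistic(t, "G3", ["f1", "n1", "n2", "n3"], family="lasso")
        assert fit.terms.loc["f1", "coef"] > 0.5


class TestSubsetSelection:
    def test_candidate_set_of_one_matches_plain_fit(self):
        t = make_cohort(CohortConfig(n_patients=400, seed=4,
                                     beta_clinical={"major_hepatectomy": 0.8}))
        plain = fit_logistic(t, "G3", ["major_hepatectomy"])
        selected = backward_select(t, "G3", ["major_hepatectomy"])
        if selected.predictors:  # term survived elimination
            assert selected.terms.loc["major_hepatectomy", "coef"] == pytest.approx(
                plain.terms.loc["major_hepatectomy", "coef"])

    def test_backward_returns_subset_with_lower_or_equal_loglik(self):
        t = make_cohort(CohortConfig(n_patients=600, seed=5,
                                     beta_features={"f1": 0.9},
                                     feature_names=("f1", "n1", "n2", "n3", "n4")))
        cands = ["f1", "n1", "n2", "n3", "n4"]
        full = fit_logistic(t, "G3", cands)
        sel = backward_select(t, "G3", cands)
        assert set(sel.predictors) <= set(cands)
        assert full.llf >= sel.llf - 1e-8

    def test_strong_predictor_retained(self):
        t = make_cohort(CohortConfig(n_patients=1000, center_sd=0.0, seed=6,
                                     beta_features={"f1": np.log(3.0)},
                                     feature_names=tuple(["f1"] + [f"n{i}" for i in range(5)])))
        sel = backward_select(t, "G3", ["f1"] + [f"n{i}" for i in range(5)])
        assert "f1" in sel.predictors

    def test_intercept_only_final_model_permitted(self):
        t = make_cohort(CohortConfig(n_patients=2000, center_sd=0.0, seed=7,
                                     feature_names=("n1", "n2")))
        sel = backward_select(t, "G3", ["n1", "n2"])
        assert isinstance(sel.predictors, list)  # may legitimately be empty
        probs = sel.predict_proba(t.head(5))
        assert probs.shape == (5,)

    def test_forward_and_stepwise_find_signal(self):
        t = make_cohort(CohortConfig(n_patients=1200, center_sd=0.0, seed=8,
                                     beta_features={"f1": 1.0},
                                     feature_names=("f1", "n1", "n2")))
        for family in ("forward", "stepwise"):
            fit = select_model(t, "G3", ["f1", "n1", "n2"], family=family)
            assert "f1" in fit.predictors


class TestUnivariateScreen:
    def test_detects_binary_and_continuous_associations(self):
        rng = np.random.default_rng(9)
        n = 600
        x_bin = rng.integers(0, 2, n)
        x_cont = rng.normal(size=n)
        noise = rng.normal(size=n)
        y = rng.binomial(1, expit(1.2 * x_bin + 0.8 * x_cont))
        t = pd.DataFrame({"y": y, "x_bin": x_bin, "x_cont": x_cont, "noise": noise})
        pvals = univariate_screen(t, "y", ["x_bin", "x_cont", "noise"])
        assert pvals["x_bin"] < 0.01
        assert pvals["x_cont"] < 0.01
        assert pvals["noise"] > 0.01

    def test_a_priori_variables_always_kept(self):
        rng = np.random.default_rng(10)
        t = pd.DataFrame({"y": rng.integers(0, 2, 100),
                          "noise": rng.normal(size=100)})
        keep = screen_clinical(t, "y", ["noise"], a_priori=("noise",))
        assert keep == ["noise"]


class TestMixedModel:
    def test_vpc_closed_forms(self):
        assert vpc_from_sigma2(0.0) == 0.0
        assert vpc_from_sigma2(LOGISTIC_RESIDUAL_VAR) == pytest.approx(0.5)
        grid = [vpc_from_sigma2(s) for s in (0.0, 0.5, 1.0, 2.0, 5.0)]
        assert all(a < b for a, b in zip(grid, grid[1:]))  # monotone

    def test_zero_center_variance_recovered_near_zero(self):
        t = make_cohort(CohortConfig(n_patients=2000, n_centers=10,
                                     center_sd=0.0, seed=11))
        fit = fit_mem(t, "G3", [])
        assert fit.vpc < 0.02

    def test_single_center_rejected(self):
        t = make_cohort(CohortConfig(n_patients=100, n_centers=1, seed=12))
        with pytest.raises(ValueError, match="2 groups"):
            fit_mem(t, "G3", [])

    def test_agrees_with_lme4_glmer(self, tmp_path):
        """Independent oracle: R lme4 adaptive-quadrature ML on the same data."""
        t = make_cohort(CohortConfig(n_patients=1500, n_centers=15, center_sd=1.0,
                                     intercept=-0.5, seed=42,
                                     beta_clinical={"major_hepatectomy": 0.7}))
        csv = tmp_path / "mem.csv"
        t[["G3", "major_hepatectomy", "center"]].to_csv(csv, index=False)
        fit = fit_mem(t, "G3", ["major_hepatectomy"])
        r_code = (
            f'd<-read.csv("{csv}");'
            "suppressMessages(library(lme4));"
            "m<-glmer(G3~major_hepatectomy+(1|center),data=d,family=binomial,nAGQ=15);"
            'cat(as.numeric(VarCorr(m)$center),fixef(m),sep="\\n")'
        )
        res = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                             text=True, check=True)
        sigma2_r, b0_r, b1_r = map(float, res.stdout.strip().split("\n"))
        assert fit.sigma2_u == pytest.approx(sigma2_r, abs=0.01)
        assert fit.fe_params["intercept"] == pytest.approx(b0_r, abs=0.01)
        assert fit.fe_params["major_hepatectomy"] == pytest.approx(b1_r, abs=0.01)
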