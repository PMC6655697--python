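"""Logistic case-mix model: screening, selection, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import kstest
from sklearn.metrics import roc_auc_score

import smrkit as sk
from smrkit.riskmodel import (c_statistic, fit_model, hosmer_lemeshow,
                              hosmer_lemeshow_pvalue, linear_gradient_check,
                              nagelkerke_r2, univariate_screen, FittedRiskModel)

from conftest import make_registry

RNG = np.random.default_rng(2024)


def _toy(n, rate=0.05, female=0.4, effect=0.0, seed=None):
    rng = np.random.default_rng(seed if seed is not None else RNG.integers(2**31))
    female_flag = rng.random(n) < female
    lp = np.log(rate / (1 - rate)) + effect * female_flag
    return pd.DataFrame({
        "age": rng.normal(60, 10, n),
        "sex": np.where(female_flag, "F", "M"),
        "death": (rng.random(n) < expit(lp)).astype(int),
    })


class TestCStatistic:
    def test_hand_case(self):
        # death-survivor pairs: (.9,.8)+, (.9,.1)+, (.7,.8)-, (.7,.1)+ -> 3/4
        assert c_statistic([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_constant_predictions_give_half(self):
        assert c_statistic([0.2] * 6, [1, 0, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_perfect_separation_gives_one(self):
        assert c_statistic([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_undefined_without_both_outcomes(self):
        with pytest.raises(ValueError):
            c_statistic([0.1, 0.2], [0, 0])

    def test_matches_sklearn_on_random_data(self):
        rng = np.random.default_rng(3)
        p = rng.random(500)
        y = (rng.random(500) < p).astype(int)
        assert c_statistic(p, y) == pytest.approx(roc_auc_score(y, p), abs=1e-12)


class TestHosmerLemeshow:
    def test_reference_pvalues_validate_df_convention(self):
        # chi-square with groups-2 df reproduces the printed pairs
        assert round(hosmer_lemeshow_pvalue(4.47, groups=10), 2) == 0.81
        assert round(hosmer_lemeshow_pvalue(6.4, groups=10), 2) == 0.60

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.1, 0.2, 0.3], [0, 0, 1], g=2)

    def test_pvalues_uniform_under_correct_model(self):
        """In-sample HL p-values are ~U(0,1) when the model is true."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(100):
            n = 3000
            x = rng.normal(size=n)
            f = rng.binomial(1, 0.3, n).astype(bool)
            y = (rng.random(n) < expit(-2.5 + 0.8 * x + 0.6 * f)).astype(int)
            data = pd.DataFrame({"age": x * 10 + 60,
                                 "sex": np.where(f, "F", "M"), "death": y})
            pvals.append(fit_model(data, ["age", "sex"], select="none").hl_pvalue)
        assert kstest(pvals, "uniform").pvalue > 0.005


class TestNagelkerke:
    def test_null_model_scores_zero(self):
        assert nagelkerke_r2(-50.0, -50.0, 100) == pytest.approx(0.0)

    def test_perfect_model_scores_one(self):
        assert nagelkerke_r2(0.0, -60.0, 100) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # n=4, ll0 = 4 ln 1/2, ll1 = -2: CS = 1-exp(-0.386294), max = 0.75
        ll0 = 4 * np.log(0.5)
        expected = (1 - np.exp(2 * (ll0 - (-2.0)) / 4)) / (1 - np.exp(2 * ll0 / 4))
        assert nagelkerke_r2(-2.0, ll0, 4) == pytest.approx(expected)


class TestUnivariateScreen:
    def test_null_covariate_excluded_about_ninety_percent(self):
        rng = np.random.default_rng(7)
        excluded = 0
        for _ in range(100):
            data = pd.DataFrame({"age": rng.normal(60, 10, 2000),
                                 "death": rng.binomial(1, 0.03, 2000)})
            excluded += "age" not in univariate_screen(data, ["age"], alpha=0.1)
        assert 0.78 <= excluded / 100 <= 0.97

    def test_strong_covariate_included(self):
        data = _toy(4000, effect=1.5, seed=8)
        assert "sex" in univariate_screen(data, ["sex"], alpha=0.1)

    def test_constant_covariate_excluded_with_warning(self):
        data = _toy(200, seed=9)
        data["sex"] = "M"
        with pytest.warns(UserWarning, match="constant"):
            kept = univariate_screen(data, ["sex"], alpha=0.1)
        assert kept == []


class TestLinearGradient:
    @staticmethod
    def _asa_data(rng, n, lp_fn):
        asa = rng.choice([1, 2, 3], n, p=[0.2, 0.5, 0.3])
        y = (rng.random(n) < expit(lp_fn(asa))).astype(int)
        return pd.DataFrame({"asa": asa, "death": y})

    def test_linear_effect_called_linear(self):
        rng = np.random.default_rng(11)
        calls = sum(
            linear_gradient_check(self._asa_data(rng, 10_000, lambda a: -4 + 0.5 * a),
                                  "asa") == "linear"
            for _ in range(20))
        assert calls >= 16

    def test_threshold_effect_called_categorical(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            data = self._asa_data(rng, 10_000, lambda a: -4 + 2.0 * (a == 3))
            assert linear_gradient_check(data, "asa") == "categorical"

    def test_two_levels_not_applicable(self):
        data = pd.DataFrame({"asa": [1, 2] * 50, "death": [0, 1] * 50})
        with pytest.raises(ValueError, match="not applicable"):
            linear_gradient_check(data, "asa")


class TestFitModel:
    def test_single_binary_covariate_equals_contingency_log_or(self):
        data = _toy(3000, effect=1.0, seed=13)
        fit = fit_model(data, ["sex"], age_center=60.0, select="none")
        tab = pd.crosstab(data["sex"], data["death"])
        log_or = np.log(tab.loc["F", 1] * tab.loc["M", 0]
                        / (tab.loc["F", 0] * tab.loc["M", 1]))
        assert fit.coefficients["female"] == pytest.approx(log_or, abs=1e-6)

    def test_calibration_in_the_large(self):
        data = make_registry(5000, seed=14)
        fit = fit_model(data, ["age", "sex", "asa"], select="none")
        assert abs(fit.predict_proba(data).sum() - data["death"].sum()) < 1e-6 * len(data)

    def test_stepdown_never_increases_aic(self):
        data = make_registry(4000, seed=15)
        variables = ["age", "sex", "asa", "diabetes", "stroke"]
        full = fit_model(data, variables, select="none")
        stepped = fit_model(data, variables, select="backward_aic")
        assert stepped.aic <= full.aic + 1e-9
        assert set(stepped.variables) <= set(variables)

    def test_null_data_usually_reduces_to_intercept_only(self):
        rng = np.random.default_rng(16)
        wins = 0
        for _ in range(25):
            n = 1500
            data = pd.DataFrame({
                "age": rng.normal(60, 10, n),
                "sex": np.where(rng.random(n) < 0.4, "F", "M"),
                "death": rng.binomial(1, 0.05, n)})
            fit = fit_model(data, ["age", "sex"], select="backward_aic")
            wins += len(fit.variables) == 0
        assert wins >= 13

    def test_interaction_admitted_when_real(self):
        rng = np.random.default_rng(17)
        n = 20_000
        f = rng.random(n) < 0.5
        old = rng.random(n) < 0.5
        lp = -3.5 + 0.3 * f + 0.3 * old + 1.4 * (f & old)
        data = pd.DataFrame({"age": np.where(old, 75.0, 55.0),
                             "sex": np.where(f, "F", "M"),
                             "death": (rng.random(n) < expit(lp)).astype(int)})
        fit = fit_model(data, ["age", "sex"], select="none", interactions=True)
        assert any(":" in t for t in fit.terms)

    def test_recovers_known_coefficients(self, casemix):
        model = sk.TrueModel({"female": -0.9, "asa": 0.4, "age_c": 0.04},
                             intercept=-4.0, age_center=64.0)
        data = sk.simulate_patients(8000, casemix, model, seed=18)
        fit = fit_model(data, ["sex", "asa", "age"], age_center=64.0, select="none")
        for term, truth in model.coefficients.items():
            assert abs(fit.coefficients[term] - truth) < 3 * fit.standard_errors[term]

    def test_json_round_trip(self):
        data = _toy(1000, effect=1.0, seed=19)
        fit = fit_model(data, ["age", "sex"], age_center=60.0, select="none")
        clone = FittedRiskModel.from_json(fit.to_json())
        assert clone == fit
        assert np.allclose(clone.predict_proba(data), fit.predict_proba(data))
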