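"""SMR computation, Faris-style standard errors and outlier flagging."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import smrkit as sk
from smrkit.riskmodel import FittedRiskModel
from smrkit.smr import (STATUS_HIGH, STATUS_LOW, STATUS_NON,
                        expected_deaths_internal, expected_deaths_transferred,
                        outlier_test, smr_dispersion, smr_table, smr_with_se)

from conftest import make_registry


def _prob_model():
    """Model whose prediction equals expit(age): lets tests pick exact probs."""
    return FittedRiskModel(
        variables=("age",), terms=("age_c",), coefficients={"age_c": 1.0},
        standard_errors={"age_c": 0.1}, intercept=0.0, intercept_se=0.1,
        age_center=0.0, c_statistic=0.7, r2=0.1, hl_statistic=1.0,
        hl_pvalue=0.9, n=10, deaths=2, aic=1.0, loglik=-1.0)


def _patients(probs, fid="H000", deaths=0):
    death = np.zeros(len(probs), dtype=int)
    death[:deaths] = 1
    return pd.DataFrame({"facility_id": fid, "age": logit(np.asarray(probs)),
                         "death": death})


def test_expected_deaths_sum_patient_probabilities():
    table = _patients([0.1, 0.2, 0.3])
    e = expected_deaths_internal(_prob_model(), table)
    assert e["H000"] == pytest.approx(0.6)
    single = _patients([0.02])
    assert expected_deaths_internal(_prob_model(), single)["H000"] == pytest.approx(0.02)


def test_transfer_to_own_training_group_is_identity(fast_study):
    from smrkit.imputation import add_missing_categories
    lqd = fast_study.clinical[
        fast_study.clinical["facility_id"].isin(fast_study.lqd_ids)]
    scored = add_missing_categories(lqd)
    e1 = expected_deaths_internal(fast_study.model_lqd, scored)
    e2 = expected_deaths_transferred(fast_study.model_lqd, scored)
    assert np.array_equal(e1.to_numpy(), e2.to_numpy())


def test_reference_patient_probability_from_intercept():
    """All-reference patient under the reference coefficients: expit(-4.4)."""
    tm = sk.default_true_model()
    fit = FittedRiskModel(
        variables=(), terms=tuple(tm.coefficients),
        coefficients=dict(tm.coefficients),
        standard_errors={t: 0.1 for t in tm.coefficients},
        intercept=tm.intercept, intercept_se=0.1, age_center=tm.age_center,
        c_statistic=0.78, r2=0.12, hl_statistic=4.47, hl_pvalue=0.81,
        n=10597, deaths=300, aic=0.0, loglik=0.0)
    patient = pd.DataFrame({
        "facility_id": ["H000"], "age": [64.0], "sex": ["M"], "asa": [0],
        "performance_status": [0], "dyspnea": [0], "fev": [90.0], "bmi": [20.0],
        "procedure": ["lobectomy"], "approach": ["thoracotomy"],
        "ptumor": ["I"], "pnodes": ["0"], "resection": ["R0"], "death": [0],
        **{c: [0] for c in sk.COMORBIDITIES}})
    p = fit.predict_proba(patient)[0]
    assert p == pytest.approx(expit(-4.4), abs=1e-12)
    assert p == pytest.approx(0.0121, abs=5e-4)


def test_transfer_rejects_unmappable_levels():
    table = _patients([0.1, 0.2])
    table["age"] = [1.0, 2.0]
    model = FittedRiskModel(
        variables=("procedure",), terms=("pneumonectomy",),
        coefficients={"pneumonectomy": 0.8}, standard_errors={"pneumonectomy": 0.1},
        intercept=-4.0, intercept_se=0.1, age_center=64.0, c_statistic=0.7,
        r2=0.1, hl_statistic=1.0, hl_pvalue=0.9, n=10, deaths=2, aic=1.0, loglik=-1.0)
    table["procedure"] = ["lobectomy", "transplant"]
    with pytest.raises(ValueError, match="transplant"):
        expected_deaths_transferred(model, table)


def test_undercoded_comorbidities_lower_transferred_expectation(casemix, true_model):
    data = make_registry(2000, seed=31)
    zeroed = data.copy()
    positive = [t for t in sk.COMORBIDITIES
                if true_model.coefficients.get(t, 0) > 0]
    zeroed[positive] = 0
    fit = FittedRiskModel(
        variables=(), terms=tuple(true_model.coefficients),
        coefficients=dict(true_model.coefficients),
        standard_errors={t: 0.1 for t in true_model.coefficients},
        intercept=true_model.intercept, intercept_se=0.1,
        age_center=true_model.age_center, c_statistic=0.78, r2=0.12,
        hl_statistic=4.47, hl_pvalue=0.81, n=2000, deaths=50, aic=0.0, loglik=0.0)
    e_full = expected_deaths_transferred(fit, data)
    e_zero = expected_deaths_transferred(fit, zeroed)
    assert (e_zero <= e_full + 1e-12).all()
    assert e_zero.sum() < e_full.sum()


class TestSmrWithSe:
    def test_hand_case(self):
        # E = 2, Var = 4*0.25 = 1, se = 1/2
        r = smr_with_se(2, [0.5, 0.5, 0.5, 0.5])
        assert r["smr"] == pytest.approx(1.0)
        assert r["se"] == pytest.approx(0.5)

    def test_observed_equal_expected_gives_unit_smr(self):
        r = smr_with_se(3, [1.0, 1.0, 1.0])
        assert r["smr"] == pytest.approx(1.0)

    def test_zero_observed_gives_zero_smr(self):
        assert smr_with_se(0, [0.1, 0.3])["smr"] == 0.0

    def test_zero_expected_with_deaths_is_error(self):
        with pytest.raises(ValueError):
            smr_with_se(2, [])
        r = smr_with_se(0, [])
        assert r["smr"] == 0.0 and r["E"] == 0.0


class TestOutlierTest:
    def test_observed_equals_expected_is_non_outlier(self):
        assert outlier_test(5, 5.0, 4.0) == STATUS_NON

    def test_hand_high_outlier(self):
        # z = (12-3)/sqrt(2.9) ~ 5.3 > 1.96
        assert outlier_test(12, 3.0, 2.9) == STATUS_HIGH

    def test_low_outlier(self):
        assert outlier_test(0, 12.0, 11.0) == STATUS_LOW

    def test_zero_variance_warns_non_outlier(self):
        with pytest.warns(UserWarning):
            assert outlier_test(1, 1.0, 0.0) == STATUS_NON

    def test_midp_exact_option(self):
        assert outlier_test(12, 3.0, 2.9, method="midp") == STATUS_HIGH
        assert outlier_test(3, 3.0, 2.9, method="midp") == STATUS_NON

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            outlier_test(1, 1.0, 1.0, alpha=1.5)


def test_status_consistent_with_smr_direction(fast_study):
    for tab in (fast_study.smr1, fast_study.smr2):
        high = tab[tab["status"] == STATUS_HIGH]
        low = tab[tab["status"] == STATUS_LOW]
        assert (high["smr"] > 1).all()
        assert (low["smr"] < 1).all()
        assert (tab["E"] >= 0).all()


def test_smr_table_zero_expected_with_deaths_raises():
    table = _patients([0.5, 0.5], deaths=1)
    table["age"] = [-800.0, -800.0]  # expit underflows to exactly 0
    with pytest.raises(ValueError, match="E=0"):
        smr_table(_prob_model(), table, "SMR1")


class TestDispersion:
    def test_constant_values_zero_width(self):
        q1, q3 = smr_dispersion([1.2, 1.2, 1.2])
        assert q1 == q3 == pytest.approx(1.2)

    def test_hand_quartiles(self):
        assert smr_dispersion([0, 0, 1, 2]) == (0.0, 1.25)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            smr_dispersion([])

    def test_clean_scenario_estimators_agree(self, clean_registries):
        """No degradation: transferring the model across identical groups
        leaves every expected count, hence the IQR, unchanged."""
        from smrkit.riskmodel import fit_model
        _, _, clinical = clean_registries
        fit = fit_model(clinical, ["age", "sex", "asa"], select="none")
        tab1 = smr_table(fit, clinical, "SMR1")
        tab2 = smr_table(fit, clinical, "SMR2")
        assert smr_dispersion(tab1["smr"]) == smr_dispersion(tab2["smr"])
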