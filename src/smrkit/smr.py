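"""Standardized mortality ratios, their standard errors and outlier status.

For each hospital the expected death count E is the sum of model-predicted
probabilities over its patients (indirect standardization), so SMR = O/E.
Two estimators differ only in where the model comes from:

* internal (SMR1): the model is fitted on the same group being profiled,
  which forces group-level calibration (sum E = sum O);
* transferred (SMR2): the linear predictor of a reference model fitted on
  another group is applied without refitting, so any systematic recording
  difference between the groups shows up as a shift in E.

The SMR standard error uses the binomial-variance form
Var(O) = sum p_i (1 - p_i), se(SMR) = sqrt(Var(O)) / E, and the outlier
test is the normal deviate z = (O - E) / sqrt(Var(O)) against +-z_{1-a/2};
an exact mid-p Poisson test is available for small expected counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, poisson

from .riskmodel import FittedRiskModel

__all__ = [
    "STATUS_LOW", "STATUS_NON", "STATUS_HIGH", "STATUSES",
    "expected_deaths_internal", "expected_deaths_transferred",
    "smr_with_se", "outlier_test", "smr_table", "smr_dispersion",
]

STATUS_LOW = "low-outlier"
STATUS_NON = "non-outlier"
STATUS_HIGH = "high-outlier"
STATUSES = (STATUS_LOW, STATUS_NON, STATUS_HIGH)


def _per_hospital_expected(fit: FittedRiskModel, data: pd.DataFrame) -> pd.Series:
    probs = pd.Series(fit.predict_proba(data), index=data.index)
    return probs.groupby(data["facility_id"]).sum().rename("E")


def expected_deaths_internal(fit_on_group: FittedRiskModel,
                             group_data: pd.DataFrame) -> pd.Series:
    """E per hospital from a model fitted on this same group (E1)."""
    return _per_hospital_expected(fit_on_group, group_data)


def expected_deaths_transferred(reference_fit: FittedRiskModel,
                                target_data: pd.DataFrame) -> pd.Series:
    """E per hospital by transferring a reference linear predictor (E2).

    The reference coefficients and age centring are applied unchanged; the
    coder raises if the target holds levels the reference cannot map.
    """
    return _per_hospital_expected(reference_fit, target_data)


def smr_with_se(O: int, per_patient_probs) -> dict:
    """SMR = O/E with Faris-style binomial-variance standard error."""
    p = np.asarray(per_patient_probs, dtype=float)
    E = float(p.sum())
    var_o = float((p * (1.0 - p)).sum())
    if E <= 0:
        if O > 0:
            raise ValueError("SMR undefined: observed deaths with zero expected")
        return {"O": 0, "E": 0.0, "smr": 0.0, "se": np.nan, "var_o": 0.0}
    return {"O": int(O), "E": E, "smr": O / E,
            "se": np.sqrt(var_o) / E, "var_o": var_o}


def outlier_test(O: float, E: float, var_o: float, alpha: float = 0.05,
                 method: str = "normal") -> str:
    """Flag a hospital whose SMR departs significantly from 1 (two-sided)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha outside (0, 1)")
    if var_o <= 0:
        warnings.warn("zero outcome variance; hospital treated as non-outlier")
        return STATUS_NON
    if method == "normal":
        z = (O - E) / np.sqrt(var_o)
        zcrit = norm.ppf(1.0 - alpha / 2.0)
        if z > zcrit:
            return STATUS_HIGH
        if z < -zcrit:
            return STATUS_LOW
        return STATUS_NON
    if method == "midp":
        # exact mid-p Poisson tail probabilities around E
        p_hi = poisson.sf(O, E) + 0.5 * poisson.pmf(O, E)
        p_lo = poisson.cdf(O - 1, E) + 0.5 * poisson.pmf(O, E)
        if p_hi < alpha / 2.0 and O > E:
            return STATUS_HIGH
        if p_lo < alpha / 2.0 and O < E:
            return STATUS_LOW
        return STATUS_NON
    raise ValueError(f"unknown method {method!r}")


def smr_table(fit: FittedRiskModel, data: pd.DataFrame, estimator: str,
              alpha: float = 0.05, method: str = "normal") -> pd.DataFrame:
    """Per-hospital SMR profile under one estimator.

    ``estimator`` is a label ("SMR1" for internal, "SMR2" for transferred);
    the computation is identical — what differs is which data the ``fit``
    was trained on.  Hospitals with zero patients simply do not appear.
    """
    probs = pd.Series(fit.predict_proba(data), index=data.index)
    grp = data.assign(_p=probs, _v=probs * (1 - probs)).groupby("facility_id")
    out = grp.agg(O=("death", "sum"), E=("_p", "sum"), var_o=("_v", "sum")).reset_index()
    out["smr"] = np.where(out["E"] > 0, out["O"] / out["E"], 0.0)
    bad = (out["E"] <= 0) & (out["O"] > 0)
    if bad.any():
        raise ValueError(f"SMR undefined (E=0, O>0) for "
                         f"{out.loc[bad, 'facility_id'].tolist()}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["se"] = np.where(out["E"] > 0, np.sqrt(out["var_o"]) / out["E"], np.nan)
        out["z"] = np.where(out["var_o"] > 0,
                            (out["O"] - out["E"]) / np.sqrt(out["var_o"]), 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["status"] = [outlier_test(o, e, v, alpha=alpha, method=method)
                         for o, e, v in zip(out["O"], out["E"], out["var_o"])]
    out["estimator"] = estimator
    return out


def smr_dispersion(smrs) -> tuple[float, float]:
    """25th and 75th percentiles of hospital SMRs (linear interpolation)."""
    values = np.asarray(smrs, dtype=float)
    if values.size == 0:
        raise ValueError("no SMR values")
    q25, q75 = np.percentile(values, [25, 75])
    return float(q25), float(q75)
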