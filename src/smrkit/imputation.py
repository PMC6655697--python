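"""Missing-data handling before model fitting.

Two mechanisms, matching how thoracic-surgery registries are analysed:
TNM/resection blanks become an explicit ``"Missing"`` category (missingness
itself is informative about registry quality and is modelled as a level),
while missing FEV is completed by proper multiple imputation — Bayesian
linear regression of FEV on the coded model covariates plus the outcome,
with posterior draws for both the residual variance and the coefficients.
Per-dataset fits are combined with Rubin's rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .coding import ALL_TERMS, MISSING_CATEGORY, STAGE_COLUMNS, encode
from .riskmodel import FittedRiskModel

__all__ = ["ImputationSet", "add_missing_categories", "impute_fev", "pool_estimates"]

#: physiological bounds for imputed FEV (% predicted)
FEV_BOUNDS = (10.0, 160.0)


@dataclass
class ImputationSet:
    """``m`` completed copies of a registry table (FEV filled in)."""

    m: int
    completed_tables: list[pd.DataFrame]
    imputation_model_terms: tuple[str, ...]


def add_missing_categories(clinical: pd.DataFrame) -> pd.DataFrame:
    """Replace blank TNM/resection fields with an explicit ``"Missing"`` level."""
    out = clinical.copy()
    for col in STAGE_COLUMNS:
        filled = out[col].astype(object).where(out[col].notna(), MISSING_CATEGORY)
        if filled.nunique() == 1:
            warnings.warn(f"column {col!r} is single-level after missing-coding; "
                          "degenerate for modelling")
        out[col] = filled
    return out


def impute_fev(clinical: pd.DataFrame, m: int = 5, seed=0) -> ImputationSet:
    """Multiply impute missing FEV by stochastic regression.

    The imputation model regresses observed FEV on all coded case-mix terms
    plus the death flag (including the outcome is standard multiple-
    imputation practice).  Each of the ``m`` draws samples the residual
    variance from its scaled inverse-chi-square posterior and the
    coefficients from their normal posterior, then draws missing values
    with residual noise, truncated to physiological bounds.  Non-FEV
    columns are left untouched.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    fev = clinical["fev"].to_numpy(dtype=float)
    missing = np.isnan(fev)
    if missing.all():
        raise ValueError("FEV entirely missing; cannot build an imputation model")
    if not missing.any():
        return ImputationSet(m, [clinical.copy() for _ in range(m)], ())

    categorized = add_missing_categories(clinical)
    terms = tuple(t for t in ALL_TERMS if t != "fev")
    X = encode(categorized, float(categorized["age"].mean()), terms=terms)
    X = X.loc[:, X.nunique() > 1]
    used = tuple(X.columns) + ("death",)
    D = np.column_stack([np.ones(len(X)), X.to_numpy(),
                         clinical["death"].to_numpy(dtype=float)])

    obs = ~missing
    Xo, yo = D[obs], fev[obs]
    n_obs, k = Xo.shape
    if n_obs <= k:
        raise ValueError("too few observed FEV values for the imputation model")
    XtX = Xo.T @ Xo
    beta_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta_hat
    sse = float(resid @ resid)
    df = n_obs - k
    XtX_inv = np.linalg.pinv(XtX)
    L = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(k))

    rng = np.random.default_rng(seed)
    Xm = D[missing]
    completed = []
    for _ in range(m):
        sigma2 = sse / rng.chisquare(df)
        beta = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(k))
        draws = Xm @ beta + np.sqrt(sigma2) * rng.standard_normal(Xm.shape[0])
        table = clinical.copy()
        filled = fev.copy()
        filled[missing] = np.clip(draws, *FEV_BOUNDS)
        table["fev"] = filled
        completed.append(table)
    return ImputationSet(m, completed, used)


def pool_estimates(per_dataset_fits: list[FittedRiskModel]) -> FittedRiskModel:
    """Combine fits across completed datasets with Rubin's rules.

    Pooled coefficient = mean across datasets; pooled variance =
    within-imputation variance + (1 + 1/m) x between-imputation variance.
    Fit diagnostics are averaged across datasets.
    """
    if not per_dataset_fits:
        raise ValueError("no fits to pool")
    first = per_dataset_fits[0]
    m = len(per_dataset_fits)
    for fit in per_dataset_fits[1:]:
        if fit.terms != first.terms:
            raise ValueError("mismatched term sets across imputed datasets")
    if m == 1:
        return replace(first)

    names = ("const",) + first.terms
    est = np.array([[f.intercept] + [f.coefficients[t] for t in f.terms]
                    for f in per_dataset_fits])
    se = np.array([[f.intercept_se] + [f.standard_errors[t] for t in f.terms]
                   for f in per_dataset_fits])
    pooled = est.mean(axis=0)
    within = (se ** 2).mean(axis=0)
    between = est.var(axis=0, ddof=1)
    total_se = np.sqrt(within + (1.0 + 1.0 / m) * between)

    mean = lambda attr: float(np.mean([getattr(f, attr) for f in per_dataset_fits]))
    return FittedRiskModel(
        variables=first.variables,
        terms=first.terms,
        coefficients=dict(zip(first.terms, map(float, pooled[1:]))),
        standard_errors=dict(zip(first.terms, map(float, total_se[1:]))),
        intercept=float(pooled[0]),
        intercept_se=float(total_se[0]),
        age_center=first.age_center,
        c_statistic=mean("c_statistic"),
        r2=mean("r2"),
        hl_statistic=mean("hl_statistic"),
        hl_pvalue=mean("hl_pvalue"),
        n=first.n,
        deaths=first.deaths,
        aic=mean("aic"),
        loglik=mean("loglik"),
    )
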