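"""Case-mix logistic risk-adjustment model and its diagnostics.

The modelling recipe: candidate covariates pass a univariate screen
(likelihood-ratio p <= 0.1), ordinal covariates are checked against a
linear gradient by LRT, a multivariable logistic model is pruned by
backward AIC step-down, pairwise interactions among retained terms are
admitted only when they lower AIC, and the final model is summarised by the
C-statistic (rank-based AUC), Nagelkerke R2 and the Hosmer-Lemeshow test on
deciles of predicted risk with groups-2 degrees of freedom.

Fitting itself is ordinary maximum likelihood via :mod:`statsmodels`; the
selection loops and diagnostics are implemented here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2, rankdata
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .coding import VARIABLE_TERMS, encode, terms_for

__all__ = [
    "FittedRiskModel",
    "SeparationWarning",
    "univariate_screen",
    "linear_gradient_check",
    "fit_model",
    "c_statistic",
    "hosmer_lemeshow",
    "hosmer_lemeshow_pvalue",
    "nagelkerke_r2",
]


class SeparationWarning(UserWarning):
    """A covariate separated the outcome; estimates may be unstable."""


@dataclass
class FittedRiskModel:
    """A fitted (or pooled) case-mix logistic model.

    Coefficients are log-odds per coded term (see :mod:`smrkit.coding`);
    ``age_center`` records the centring used at fit time so the model can be
    transferred to another population without refitting.
    """

    variables: tuple[str, ...]
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    intercept: float
    intercept_se: float
    age_center: float
    c_statistic: float
    r2: float
    hl_statistic: float
    hl_pvalue: float
    n: int
    deaths: int
    aic: float
    loglik: float

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        main = [t for t in self.terms if ":" not in t]
        X = encode(table, self.age_center, terms=main)
        lp = np.full(len(table), self.intercept)
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":")
                col = X[a].to_numpy() * X[b].to_numpy()
            else:
                col = X[t].to_numpy()
            lp += self.coefficients[t] * col
        return lp

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(table))

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        doc["variables"] = list(self.variables)
        doc["terms"] = list(self.terms)
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FittedRiskModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        doc["variables"] = tuple(doc["variables"])
        doc["terms"] = tuple(doc["terms"])
        return cls(**doc)


def _design(data: pd.DataFrame, terms, age_center: float) -> pd.DataFrame:
    main = sorted({p for t in terms for p in t.split(":")})
    X = encode(data, age_center, terms=[t for t in main if ":" not in t])
    cols = {}
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            cols[t] = X[a].to_numpy() * X[b].to_numpy()
        else:
            cols[t] = X[t].to_numpy()
    out = pd.DataFrame(cols, index=data.index)
    out.insert(0, "const", 1.0)
    return out


def _mle(y: np.ndarray, X: pd.DataFrame):
    """Logistic MLE with a quasi-Newton fallback on Newton failure."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, method="newton", maxiter=200, tol=1e-10)
            if res.mle_retvals.get("converged", False):
                return res
        except (PerfectSeparationError, np.linalg.LinAlgError):
            pass
        res = model.fit(disp=0, method="bfgs", maxiter=1000, gtol=1e-8)
        try:  # polish with Newton so the score equations hold tightly
            polished = model.fit(disp=0, method="newton", maxiter=50, tol=1e-10,
                                 start_params=res.params)
            if polished.mle_retvals.get("converged", False):
                return polished
        except (PerfectSeparationError, np.linalg.LinAlgError):
            pass
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError(f"logistic fit failed to converge for terms {list(X.columns[1:])}")
    return res


def _loglik_null(y: np.ndarray) -> float:
    n, d = len(y), y.sum()
    if d in (0, n):
        return 0.0
    p = d / n
    return d * np.log(p) + (n - d) * np.log(1 - p)


def univariate_screen(data: pd.DataFrame, candidates=None, alpha: float = 0.1,
                      outcome: str = "death", age_center: float | None = None):
    """Single-variable likelihood-ratio screen.

    Returns the candidate variables whose univariate logistic LRT against
    the intercept-only model has p <= ``alpha``.  Constant covariates are
    excluded with a warning; a separating covariate is flagged but retained
    for multivariable consideration.
    """
    if candidates is None:
        candidates = list(VARIABLE_TERMS)
    if age_center is None:
        age_center = float(data["age"].mean())
    y_all = data[outcome].to_numpy(dtype=float)
    kept = []
    for var in candidates:
        X = _design(data, terms_for([var]), age_center)
        mask = ~X.isna().any(axis=1).to_numpy()
        Xv, yv = X[mask], y_all[mask]
        informative = [c for c in Xv.columns if c == "const" or Xv[c].nunique() > 1]
        if len(informative) == 1:
            warnings.warn(f"candidate {var!r} is constant; excluded from screening")
            continue
        Xv = Xv[informative]
        try:
            res = _mle(yv, Xv)
        except (RuntimeError, PerfectSeparationError):
            warnings.warn(f"separation in univariate fit of {var!r}; retained",
                          SeparationWarning)
            kept.append(var)
            continue
        lr = 2.0 * (res.llf - _loglik_null(yv))
        p = chi2.sf(max(lr, 0.0), df=len(informative) - 1)
        if p <= alpha:
            kept.append(var)
    return kept


def linear_gradient_check(data: pd.DataFrame, column: str, outcome: str = "death",
                          level: float = 0.05) -> str:
    """Test an ordinal covariate for conformity with a linear log-odds gradient.

    Compares the saturated categorical coding against the linear-score coding
    by likelihood ratio (df = levels - 2); returns ``"linear"`` when
    linearity is not rejected at ``level``, else ``"categorical"``.
    """
    values = data[column].to_numpy(dtype=float)
    levels = np.unique(values)
    if len(levels) < 3:
        raise ValueError(f"{column!r} has {len(levels)} levels; "
                         "linear-gradient check not applicable")
    y = data[outcome].to_numpy(dtype=float)
    Xlin = pd.DataFrame({"const": 1.0, column: values})
    lin = _mle(y, Xlin)
    dummies = {f"{column}_{lv}": (values == lv).astype(float) for lv in levels[1:]}
    Xcat = pd.DataFrame({"const": 1.0, **dummies})
    cat = _mle(y, Xcat)
    lr = 2.0 * (cat.llf - lin.llf)
    p = chi2.sf(max(lr, 0.0), df=len(levels) - 2)
    return "linear" if p >= level else "categorical"


def c_statistic(probs, y) -> float:
    """Rank-based AUC: probability a random death outranks a random survivor."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("C-statistic undefined without both deaths and survivors")
    r = rankdata(probs)  # midranks handle ties as 1/2
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def hosmer_lemeshow(probs, y, g: int = 10):
    """Hosmer-Lemeshow goodness-of-fit over ``g`` groups of predicted risk.

    Groups are deciles of predicted probability; empty/duplicate-edge groups
    are merged with a warning.  Returns ``(statistic, pvalue)`` with the
    chi-square on ``g_effective - 2`` degrees of freedom.
    """
    if g < 3:
        raise ValueError("need at least 3 groups")
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    bins = pd.qcut(probs, g, labels=False, duplicates="drop")
    if np.isnan(bins).all() or len(np.unique(bins[~np.isnan(bins)])) < 3:
        warnings.warn("predicted risks too concentrated to form groups; "
                      "Hosmer-Lemeshow undefined")
        return float("nan"), float("nan")
    g_eff = int(np.nanmax(bins)) + 1
    if g_eff < g:
        warnings.warn(f"tied risk deciles merged: {g} -> {g_eff} groups")
    stat = 0.0
    for b in range(g_eff):
        m = bins == b
        ng = m.sum()
        O = y[m].sum()
        E = probs[m].sum()
        denom = E * (1.0 - E / ng)
        if denom <= 0:
            warnings.warn("degenerate risk group skipped in Hosmer-Lemeshow")
            continue
        stat += (O - E) ** 2 / denom
    return float(stat), hosmer_lemeshow_pvalue(stat, g_eff)


def hosmer_lemeshow_pvalue(statistic: float, groups: int = 10) -> float:
    """Upper-tail chi-square probability with groups - 2 degrees of freedom."""
    return float(chi2.sf(statistic, df=groups - 2))


def nagelkerke_r2(loglik: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's rescaled R2 from model and null log-likelihoods."""
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik) / n)
    denom = 1.0 - np.exp(2.0 * loglik_null / n)
    if denom <= 0:
        return 0.0
    return float(cox_snell / denom)


def _aic_stepdown(y, fit_vars, variables):
    """Remove, one variable at a time, the removal that most lowers AIC."""
    current = list(variables)
    res = fit_vars(current)
    while len(current) > 0:
        best_var, best_res, best_aic = None, None, res.aic
        for var in current:
            try:
                r = fit_vars([v for v in current if v != var])
            except RuntimeError:
                continue
            if r.aic < best_aic - 1e-9:
                best_var, best_res, best_aic = var, r, r.aic
        if best_var is None:
            break
        current.remove(best_var)
        res = best_res
    return current, res


def _interaction_search(y, fit_terms, base_terms):
    """Greedy forward search over pairwise products of retained terms."""
    main = list(base_terms)
    candidates = [f"{a}:{b}" for i, a in enumerate(main) for b in main[i + 1:]]
    kept: list[str] = []
    res = fit_terms(main)
    improved = True
    while improved and candidates:
        improved = False
        best, best_res, best_aic = None, None, res.aic
        for cand in candidates:
            try:
                r = fit_terms(main + kept + [cand])
            except RuntimeError:
                continue
            if r.aic < best_aic - 1e-9:
                best, best_res, best_aic = cand, r, r.aic
        if best is not None:
            kept.append(best)
            candidates.remove(best)
            res = best_res
            improved = True
    return kept, res


def fit_model(data: pd.DataFrame, variables, *, outcome: str = "death",
              age_center: float | None = None, select: str = "backward_aic",
              interactions: bool = False, hl_groups: int = 10) -> FittedRiskModel:
    """Fit the multivariable case-mix model.

    ``select`` is ``"backward_aic"`` (step-down with AIC as stopping rule,
    the default recipe), ``"forward_aic"``, or ``"none"`` (fit the given
    variables as-is).  With ``interactions=True`` pairwise products of the
    retained main-effect terms are admitted when they lower AIC.
    """
    if age_center is None:
        age_center = float(data["age"].mean())
    y = data[outcome].to_numpy(dtype=float)

    # map each variable to its informative coded terms; a degenerate dummy
    # (e.g. a stage level absent from this group) is dropped, not the variable
    var_terms: dict[str, list[str]] = {}
    for var in list(variables):
        X = _design(data, terms_for([var]), age_center)
        if X.isna().any().any():
            raise ValueError(f"variable {var!r} has missing values; impute first")
        keep = [c for c in X.columns if c != "const" and X[c].nunique() > 1]
        if keep:
            var_terms[var] = keep
        else:
            warnings.warn(f"variable {var!r} is constant; dropped")
    variables = list(var_terms)

    def fit_terms(terms):
        if not terms:
            return _mle(y, pd.DataFrame({"const": np.ones(len(y))}, index=data.index))
        return _mle(y, _design(data, terms, age_center))

    def fit_vars(vars_):
        return fit_terms([t for v in vars_ for t in var_terms[v]])

    if select == "backward_aic":
        variables, res = _aic_stepdown(y, fit_vars, variables)
    elif select == "forward_aic":
        remaining = list(variables)
        variables = []
        res = fit_vars([])
        improved = True
        while improved and remaining:
            improved = False
            best, best_res, best_aic = None, None, res.aic
            for var in remaining:
                r = fit_vars(variables + [var])
                if r.aic < best_aic - 1e-9:
                    best, best_res, best_aic = var, r, r.aic
            if best is not None:
                variables.append(best)
                remaining.remove(best)
                res = best_res
                improved = True
    elif select == "none":
        res = fit_vars(variables)
    else:
        raise ValueError(f"unknown selection mode {select!r}")

    terms = [t for v in variables for t in var_terms[v]]
    if interactions and terms:
        inter, res = _interaction_search(y, fit_terms, terms)
        terms = terms + inter

    params = dict(zip(res.params.index, res.params.to_numpy()))
    bse = dict(zip(res.bse.index, res.bse.to_numpy()))
    probs = np.asarray(res.predict())
    ll0 = _loglik_null(y)
    hl_stat, hl_p = hosmer_lemeshow(probs, y, g=hl_groups)
    return FittedRiskModel(
        variables=tuple(variables),
        terms=tuple(terms),
        coefficients={t: float(params[t]) for t in terms},
        standard_errors={t: float(bse[t]) for t in terms},
        intercept=float(params["const"]),
        intercept_se=float(bse["const"]),
        age_center=float(age_center),
        c_statistic=c_statistic(probs, y.astype(int)),
        r2=nagelkerke_r2(float(res.llf), ll0, len(y)),
        hl_statistic=hl_stat,
        hl_pvalue=hl_p,
        n=int(len(y)),
        deaths=int(y.sum()),
        aic=float(res.aic),
        loglik=float(res.llf),
    )
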