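"""End-to-end study driver: simulate, classify, adjust, profile, agree.

``run_study`` reproduces the whole analysis on synthetic registries:

1. draw hospitals and simulate the paired registries;
2. link by facility code, compute completeness ratios, classify GQD/LQD;
3. build a case-mix logistic model per group (missing-category coding,
   FEV multiple imputation, univariate screening, backward AIC step-down,
   Rubin pooling);
4. profile each LQD hospital twice — SMR1 from the LQD-fitted model and
   SMR2 from the GQD model's transferred linear predictor;
5. cross-classify outlier statuses and compute Cohen's kappa, group
   mortality rates and SMR dispersion.

``variables`` in the config switches between the full selection recipe
(``None``) and a fixed term set (a list), the latter being what replicate
studies use for speed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement, linkage, smr, synthetic
from .coding import DEFAULT_CANDIDATE_VARIABLES
from .imputation import add_missing_categories, impute_fev, pool_estimates
from .riskmodel import FittedRiskModel, fit_model, univariate_screen

__all__ = ["StudyConfig", "StudyResult", "build_risk_model", "run_study"]

#: Variables of the reference true model (used by fixed-variable runs).
TRUE_MODEL_VARIABLES = (
    "age", "sex", "asa", "performance_status", "dyspnea", "bmi",
    "procedure", "approach", "chronic_heart_failure", "alcoholism",
    "cirrhosis", "history_of_neoplasm", "respiratory_failure",
    "ptumor", "resection",
)


@dataclass
class StudyConfig:
    n_hospitals: int = 100
    seed: int = 0
    scenario: str = "paper-like"
    threshold: float = 0.7
    m_imputations: int = 5
    screen_alpha: float = 0.1
    selection: str = "backward_aic"
    interactions: bool = False
    hl_groups: int = 10
    alpha_outlier: float = 0.05
    outlier_method: str = "normal"
    variables: tuple | None = None  # fixed variable list; None = screen + select
    casemix: synthetic.CaseMixConfig = field(default_factory=synthetic.default_casemix)
    true_model: synthetic.TrueModel = field(default_factory=synthetic.default_true_model)


@dataclass
class StudyResult:
    truth: pd.DataFrame
    clinical: pd.DataFrame
    summaries: pd.DataFrame
    gqd_ids: list
    lqd_ids: list
    model_gqd: FittedRiskModel
    model_lqd: FittedRiskModel
    smr1: pd.DataFrame
    smr2: pd.DataFrame
    matrix: np.ndarray
    kappa: float
    kappa_band: str
    mortality_gqd: float
    mortality_lqd: float
    mortality_pvalue: float
    iqr_smr1: tuple
    iqr_smr2: tuple


def build_risk_model(clinical_group: pd.DataFrame, config: StudyConfig,
                     seed=0) -> FittedRiskModel:
    """Fit the group's case-mix model per the configured recipe.

    With ``config.variables`` set, that fixed set is fitted directly (FEV
    never enters, so no imputation is needed).  Otherwise: FEV is multiply
    imputed; screening runs per completed dataset and keeps variables
    passing in a majority; backward AIC step-down runs per dataset and
    variables retained in a majority form the final set, refitted per
    dataset and pooled by Rubin's rules.
    """
    data = add_missing_categories(clinical_group)
    age_center = float(data["age"].mean())

    if config.variables is not None:
        return fit_model(data, list(config.variables), age_center=age_center,
                         select="none", interactions=config.interactions,
                         hl_groups=config.hl_groups)

    imp = impute_fev(data, m=config.m_imputations, seed=seed)
    votes: Counter = Counter()
    for completed in imp.completed_tables:
        votes.update(univariate_screen(completed, DEFAULT_CANDIDATE_VARIABLES,
                                       alpha=config.screen_alpha,
                                       age_center=age_center))
    majority = imp.m / 2.0
    screened = [v for v in DEFAULT_CANDIDATE_VARIABLES if votes[v] > majority]

    retained: Counter = Counter()
    for completed in imp.completed_tables:
        fit = fit_model(completed, screened, age_center=age_center,
                        select=config.selection, interactions=False,
                        hl_groups=config.hl_groups)
        retained.update(fit.variables)
    final_vars = [v for v in screened if retained[v] > majority]

    fits = [fit_model(completed, final_vars, age_center=age_center,
                      select="none", interactions=config.interactions,
                      hl_groups=config.hl_groups)
            for completed in imp.completed_tables]
    return pool_estimates(fits)


def _scoring_table(model: FittedRiskModel, group: pd.DataFrame,
                   config: StudyConfig, seed) -> pd.DataFrame:
    data = add_missing_categories(group)
    if any(t == "fev" or t.startswith("fev:") for t in model.terms):
        # score on the first completed dataset if the model kept FEV
        data = impute_fev(data, m=1, seed=seed).completed_tables[0]
    return data


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full profiling study on one synthetic two-registry draw."""
    root = np.random.SeedSequence(config.seed)
    s_hosp, s_admin, s_degr, s_fit = root.spawn(4)

    hospitals = synthetic.generate_hospitals(config.n_hospitals, s_hosp,
                                             config.scenario)
    truth = synthetic.generate_admin_registry(hospitals, config.casemix,
                                              config.true_model, s_admin)
    fev_missing = 0.0 if config.scenario == "clean" else config.casemix.fev_missing_prob
    clinical = synthetic.degrade_to_clinical_registry(
        truth, hospitals, s_degr, fev_missing_prob=fev_missing)

    summaries = linkage.classify_quality(
        linkage.summarize_by_hospital(clinical, truth), threshold=config.threshold)
    gqd_ids = summaries.loc[summaries["quality_class"] == linkage.GQD,
                            "facility_id"].tolist()
    lqd_ids = summaries.loc[summaries["quality_class"] == linkage.LQD,
                            "facility_id"].tolist()

    gqd = clinical[clinical["facility_id"].isin(gqd_ids)].reset_index(drop=True)
    lqd = clinical[clinical["facility_id"].isin(lqd_ids)].reset_index(drop=True)
    if gqd.empty or lqd.empty:
        raise RuntimeError("a quality group is empty; cannot fit group models")

    seed_g, seed_l = (int(s.generate_state(1)[0] % 2**31) for s in s_fit.spawn(2))
    model_gqd = build_risk_model(gqd, config, seed=seed_g)
    model_lqd = build_risk_model(lqd, config, seed=seed_l)

    lqd_scored = _scoring_table(model_lqd, lqd, config, seed_l)
    smr1 = smr.smr_table(model_lqd, lqd_scored, "SMR1",
                         alpha=config.alpha_outlier, method=config.outlier_method)
    lqd_scored2 = _scoring_table(model_gqd, lqd, config, seed_l)
    smr2 = smr.smr_table(model_gqd, lqd_scored2, "SMR2",
                         alpha=config.alpha_outlier, method=config.outlier_method)

    matrix = agreement.cross_classify(smr1, smr2)
    kappa, band = agreement.cohen_kappa(matrix)
    rate_g, rate_l, pval = agreement.compare_group_mortality(gqd, lqd)

    return StudyResult(
        truth=truth, clinical=clinical, summaries=summaries,
        gqd_ids=gqd_ids, lqd_ids=lqd_ids,
        model_gqd=model_gqd, model_lqd=model_lqd,
        smr1=smr1, smr2=smr2, matrix=matrix, kappa=kappa, kappa_band=band,
        mortality_gqd=rate_g, mortality_lqd=rate_l, mortality_pvalue=pval,
        iqr_smr1=smr.smr_dispersion(smr1["smr"]),
        iqr_smr2=smr.smr_dispersion(smr2["smr"]),
    )
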