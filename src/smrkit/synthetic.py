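"""Paired clinical/administrative registry simulator with known ground truth.

The generator emulates a national thoracic-surgery setting: an exhaustive
administrative discharge database (the completeness reference) and a
voluntary clinical registry whose per-hospital data quality varies.  Every
patient is simulated once, with a true 30-day/in-hospital death drawn from a
known logistic case-mix model; the administrative registry sees everything,
while the clinical registry is produced by hospital-specific degradation:

* patient omission (a case never entered in the clinical registry),
* death under-recording (a recorded patient's death captured as alive),
* comorbidity under-coding (true flags dropped),
* TNM/resection blanking and FEV blanking.

Because truth is known, every downstream stage (completeness ratios, quality
classification, model fitting, SMR profiling) can be checked against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .coding import COMORBIDITIES, MISSING_CATEGORY, STAGE_COLUMNS, encode

__all__ = [
    "TrueModel",
    "HospitalProfile",
    "CaseMixConfig",
    "ConfigurationError",
    "LinkageError",
    "default_true_model",
    "default_casemix",
    "generate_hospitals",
    "generate_admin_registry",
    "simulate_patients",
    "degrade_to_clinical_registry",
    "admin_view",
    "ADMIN_COLUMNS",
]

HOSPITAL_TYPES = ("non-teaching", "private", "teaching")
HOSPITAL_TYPE_PROBS = (0.21, 0.46, 0.33)

#: Columns the administrative registry exposes (plus the death flag).
ADMIN_COLUMNS = ("facility_id", "patient_id", "procedure", "approach", "death")

SCENARIOS = ("clean", "paper-like")


class ConfigurationError(ValueError):
    """Invalid generator configuration (unknown scenario, bad probabilities)."""


class LinkageError(ValueError):
    """Registry rows reference a facility unknown to the hospital list."""


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth logistic mortality model on coded case-mix terms.

    ``coefficients`` maps coded covariate terms (see :mod:`smrkit.coding`)
    to log-odds contributions; ``intercept`` is the log-odds at reference
    levels (note ASA enters as a raw 1-3 score, so the intercept formally
    corresponds to ASA 0); ``age_center`` is the centring age in years.
    """

    coefficients: dict[str, float]
    intercept: float
    age_center: float

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        terms = tuple(self.coefficients)
        X = encode(table, self.age_center, terms=terms).to_numpy()
        beta = np.array([self.coefficients[t] for t in terms])
        return self.intercept + X @ beta

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(table))


@dataclass(frozen=True)
class HospitalProfile:
    """One facility and its data-quality mechanisms.

    ``volume`` is the expected two-year administrative case count.  The four
    probabilities control, respectively, whether a case reaches the clinical
    registry, whether a recorded case's true death is captured, whether a
    true comorbidity flag survives, and whether TNM/resection fields are
    blanked over and above baseline registry missingness.
    """

    facility_id: str
    hospital_type: str
    volume: float
    case_report_prob: float = 1.0
    death_report_prob: float = 1.0
    comorbidity_report_prob: float = 1.0
    tnm_missing_prob: float = 0.0

    def __post_init__(self):
        if self.volume <= 0:
            raise ConfigurationError(f"{self.facility_id}: volume must be > 0")
        for name in ("case_report_prob", "death_report_prob",
                     "comorbidity_report_prob", "tnm_missing_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{self.facility_id}: {name}={p} outside [0, 1]")


def _default_comorbidity_prevalence() -> dict[str, float]:
    return {
        "coronary_disease": 0.09,
        "tobacco": 0.255,
        "chronic_bronchitis": 0.22,
        "arrhythmia": 0.057,
        "chronic_heart_failure": 0.024,
        "peripheral_artery_disease": 0.019,
        "alcoholism": 0.05,
        "cirrhosis": 0.007,
        "stroke": 0.03,
        "diabetes": 0.103,
        "coagulation_disorder": 0.07,
        "hematologic_disease": 0.019,
        "history_of_neoplasm": 0.29,
        "surgical_history": 0.084,
        "severe_malnutrition": 0.007,
        "pulmonary_embolism": 0.013,
        "infectious_disease": 0.0254,
        "endocrine_disease": 0.035,
        "anemia": 0.002,
        "steroids": 0.004,
        "immunosuppression": 0.006,
        "cardiac_malformation": 0.0006,
        "chronic_renal_disease": 0.0182,
        "valvulopathy": 0.008,
        "neurological_disorder": 0.012,
        "psychiatric_disorder": 0.033,
        "asthma": 0.0125,
        "respiratory_failure": 0.06,
    }


@dataclass(frozen=True)
class CaseMixConfig:
    """Marginal case-mix distributions for patient simulation.

    Defaults reflect a well-documented clinical registry population
    (age ~ N(64, 10) years, 34% female, FEV ~ N(83, 21) % predicted,
    BMI ~ N(25.45, 4.5) kg/m2, mostly lobectomies, 28% VATS, stage and
    resection categories including an organic "Missing" level).
    """

    age_mean: float = 64.0
    age_sd: float = 10.0
    female_prob: float = 0.34
    asa_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.155, 2: 0.52, 3: 0.325})
    ps_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.44, 1: 0.46, 2: 0.10})
    dyspnea_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.425, 1: 0.36, 2: 0.18, 3: 0.035})
    fev_mean: float = 83.0
    fev_sd: float = 21.0
    fev_missing_prob: float = 0.10
    bmi_mean: float = 25.45
    bmi_sd: float = 4.5
    procedure_probs: dict[str, float] = field(
        default_factory=lambda: {"limited": 0.14, "lobectomy": 0.74,
                                 "bilobectomy": 0.035, "pneumonectomy": 0.085})
    approach_probs: dict[str, float] = field(
        default_factory=lambda: {"thoracotomy": 0.72, "vats": 0.28})
    ptumor_probs: dict[str, float] = field(
        default_factory=lambda: {"I": 0.394, "II": 0.303, "III": 0.151,
                                 "IV": 0.051, MISSING_CATEGORY: 0.101})
    pnodes_probs: dict[str, float] = field(
        default_factory=lambda: {"0": 0.63, "1": 0.12, "2": 0.13,
                                 MISSING_CATEGORY: 0.12})
    resection_probs: dict[str, float] = field(
        default_factory=lambda: {"R0": 0.86, "R1": 0.03, "R2": 0.02,
                                 MISSING_CATEGORY: 0.09})
    comorbidity_prevalence: dict[str, float] = field(
        default_factory=_default_comorbidity_prevalence)
    #: Optional positive dependence between ASA and comorbidity flags:
    #: each prevalence is tilted by (1 + dep * (asa - 2)), clipped to [0, 1].
    asa_comorbidity_dependence: float = 0.0

    def __post_init__(self):
        for name in ("asa_probs", "ps_probs", "dyspnea_probs", "procedure_probs",
                     "approach_probs", "ptumor_probs", "pnodes_probs",
                     "resection_probs"):
            probs = getattr(self, name)
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"{name} has a negative frequency")
        if not 0.0 <= self.fev_missing_prob <= 1.0:
            raise ConfigurationError("fev_missing_prob outside [0, 1]")
        for c, p in self.comorbidity_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence of {c} outside [0, 1]")


def default_casemix() -> CaseMixConfig:
    return CaseMixConfig()


def default_true_model() -> TrueModel:
    """Reference case-mix mortality model used by the generator.

    Coefficients follow the fitted model of a high-completeness registry
    population; covariates screened out of that model carry true
    coefficient 0 (they simply do not appear in the map).
    """
    return TrueModel(
        coefficients={
            "age_c": 0.044,
            "female": -0.944,
            "asa": 0.31,
            "ps_ge2": 0.6,
            "dyspnea_ge3": 0.62,
            "pneumonectomy": 0.77,
            "vats": -0.59,
            "bmi_24_28": -0.55,
            "bmi_gt28": -0.67,
            "chronic_heart_failure": 0.97,
            "alcoholism": 0.58,
            "cirrhosis": 0.94,
            "history_of_neoplasm": 0.33,
            "respiratory_failure": 0.79,
            "ptumor_II": 0.04,
            "ptumor_III": 0.5,
            "ptumor_IV": 0.75,
            "ptumor_Missing": 0.79,
            "resection_R1": -0.11,
            "resection_R2": 0.22,
            "resection_Missing": -0.74,
        },
        intercept=-4.4,
        age_center=64.0,
    )


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def generate_hospitals(n_hospitals: int, seed, degradation_scenario: str = "paper-like"):
    """Draw hospital profiles with per-hospital data-quality mechanisms.

    Scenario ``"clean"`` sets every report probability to 1 (no degradation);
    ``"paper-like"`` draws roughly a quarter of hospitals with near-complete
    reporting and the rest with at least one substantially degraded
    mechanism.  Profiles are drawn from per-hospital random streams split
    off the master seed, so extending the list leaves earlier hospitals
    unchanged.
    """
    if n_hospitals < 2:
        raise ConfigurationError("need at least 2 hospitals")
    if degradation_scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {degradation_scenario!r}; choose from {SCENARIOS}")
    children = _seedseq(seed).spawn(n_hospitals)
    profiles = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        htype = str(rng.choice(HOSPITAL_TYPES, p=HOSPITAL_TYPE_PROBS))
        volume = float(np.clip(rng.lognormal(np.log(140.0), 0.9), 20.0, 1500.0))
        if degradation_scenario == "clean":
            case_p = death_p = comorb_p = 1.0
            tnm_p = 0.0
        else:  # paper-like
            if rng.random() < 0.25:
                case_p = rng.uniform(0.93, 1.0)
                death_p = rng.uniform(0.95, 1.0)
                comorb_p = rng.uniform(0.90, 1.0)
                tnm_p = rng.uniform(0.05, 0.15)
            else:
                case_p = rng.uniform(0.20, 0.78)
                death_p = rng.uniform(0.20, 0.80)
                comorb_p = rng.uniform(0.40, 0.90)
                tnm_p = rng.uniform(0.10, 0.35)
        profiles.append(HospitalProfile(
            facility_id=f"H{i:03d}",
            hospital_type=htype,
            volume=volume,
            case_report_prob=case_p,
            death_report_prob=death_p,
            comorbidity_report_prob=comorb_p,
            tnm_missing_prob=tnm_p,
        ))
    return profiles


def _categorical(rng, n, probs: dict):
    levels = list(probs)
    p = np.array([probs[k] for k in levels], dtype=float)
    idx = rng.choice(len(levels), size=n, p=p / p.sum())
    return np.array(levels, dtype=object)[idx]


def _simulate_arrays(n: int, casemix: CaseMixConfig, rng) -> dict[str, np.ndarray]:
    d: dict[str, np.ndarray] = {}
    d["sex"] = np.where(rng.random(n) < casemix.female_prob, "F", "M").astype(object)
    d["age"] = rng.normal(casemix.age_mean, casemix.age_sd, n).clip(18, 95)
    d["asa"] = _categorical(rng, n, casemix.asa_probs).astype(int)
    d["performance_status"] = _categorical(rng, n, casemix.ps_probs).astype(int)
    d["dyspnea"] = _categorical(rng, n, casemix.dyspnea_probs).astype(int)
    d["fev"] = rng.normal(casemix.fev_mean, casemix.fev_sd, n).clip(10, 160)
    d["bmi"] = rng.normal(casemix.bmi_mean, casemix.bmi_sd, n).clip(12, 60)
    d["procedure"] = _categorical(rng, n, casemix.procedure_probs)
    d["approach"] = _categorical(rng, n, casemix.approach_probs)
    d["ptumor"] = _categorical(rng, n, casemix.ptumor_probs)
    d["pnodes"] = _categorical(rng, n, casemix.pnodes_probs)
    d["resection"] = _categorical(rng, n, casemix.resection_probs)
    dep = casemix.asa_comorbidity_dependence
    for c in COMORBIDITIES:
        p = casemix.comorbidity_prevalence.get(c, 0.0)
        if dep > 0:
            pc = np.clip(p * (1.0 + dep * (d["asa"] - 2)), 0.0, 1.0)
        else:
            pc = p
        d[c] = (rng.random(n) < pc).astype(int)
    return d


def simulate_patients(n: int, casemix: CaseMixConfig, model: TrueModel, seed,
                      facility_id: str = "H000") -> pd.DataFrame:
    """Simulate ``n`` patients of one facility with true deaths from ``model``."""
    rng = np.random.default_rng(_seedseq(seed))
    d = _simulate_arrays(n, casemix, rng)
    d["facility_id"] = np.repeat(facility_id, n).astype(object)
    d["patient_id"] = np.array([f"{facility_id}-{i:05d}" for i in range(n)], dtype=object)
    table = pd.DataFrame(d)
    p = model.predict_proba(table)
    table["death"] = (rng.random(n) < p).astype(int)
    cols = ["facility_id", "patient_id"] + [c for c in table.columns
                                            if c not in ("facility_id", "patient_id")]
    return table[cols]


def generate_admin_registry(hospitals, casemix: CaseMixConfig, model: TrueModel,
                            seed) -> pd.DataFrame:
    """Simulate the full patient truth table across hospitals.

    Returns one row per patient with every covariate and the true death
    flag; actual case counts are Poisson around each hospital's expected
    volume.  Use :func:`admin_view` for the administrative projection
    (facility, procedure, approach, death) written to CSV, and
    :func:`degrade_to_clinical_registry` to derive the clinical registry.
    """
    if not hospitals:
        raise ConfigurationError("empty hospital list")
    children = _seedseq(seed).spawn(len(hospitals))
    frames = []
    for prof, child in zip(hospitals, children):
        rng = np.random.default_rng(child)
        n = int(rng.poisson(prof.volume))
        n = max(n, 1)  # a participating facility contributes at least one case
        frames.append(simulate_patients(n, casemix, model, child.spawn(1)[0],
                                        facility_id=prof.facility_id))
    return pd.concat(frames, ignore_index=True)


def admin_view(truth: pd.DataFrame) -> pd.DataFrame:
    """Administrative projection: facility, procedure, approach, death only."""
    return truth.loc[:, list(ADMIN_COLUMNS)].copy()


def degrade_to_clinical_registry(admin: pd.DataFrame, hospitals, seed,
                                 fev_missing_prob: float = 0.0,
                                 selective_omission: float = 0.0,
                                 model: TrueModel | None = None) -> pd.DataFrame:
    """Derive the voluntary clinical registry from the full truth table.

    Per hospital: patients are retained with ``case_report_prob``; among
    retained true deaths the flag survives with ``death_report_prob``
    (otherwise recorded alive); each true comorbidity flag survives with
    ``comorbidity_report_prob``; TNM/resection fields are blanked with
    ``tnm_missing_prob``; FEV is blanked with ``fev_missing_prob``.

    ``selective_omission`` (log-odds units per SD of true risk) optionally
    makes sicker patients likelier to be omitted; it requires ``model`` and
    defaults to non-selective omission.
    """
    by_id = {p.facility_id: p for p in hospitals}
    orphans = sorted(set(admin["facility_id"]) - set(by_id))
    if orphans:
        raise LinkageError(f"facilities absent from the hospital list: {orphans}")

    lp_z = None
    if selective_omission != 0.0:
        if model is None:
            raise ConfigurationError("selective_omission requires the true model")
        lp = model.linear_predictor(admin)
        lp_z = (lp - lp.mean()) / (lp.std() or 1.0)

    children = _seedseq(seed).spawn(len(hospitals))
    rngs = {p.facility_id: np.random.default_rng(c)
            for p, c in zip(hospitals, children)}

    pieces = []
    for fid, idx in admin.groupby("facility_id", sort=False).indices.items():
        prof = by_id[fid]
        rng = rngs[fid]
        block = admin.iloc[idx]
        n = len(block)
        retain_p = np.full(n, prof.case_report_prob)
        if lp_z is not None:
            omit = 1.0 - retain_p
            with np.errstate(divide="ignore"):
                logit_omit = np.log(omit) - np.log1p(-omit)
            retain_p = 1.0 - expit(logit_omit + selective_omission * lp_z[idx])
        keep = rng.random(n) < retain_p
        kept = block[keep].copy()
        m = len(kept)
        if m == 0:
            continue
        dead = kept["death"].to_numpy() == 1
        reported = rng.random(m) < prof.death_report_prob
        kept["death"] = (dead & reported).astype(int)
        for c in COMORBIDITIES:
            flags = kept[c].to_numpy() == 1
            kept[c] = (flags & (rng.random(m) < prof.comorbidity_report_prob)).astype(int)
        blank = rng.random(m) < prof.tnm_missing_prob
        for col in STAGE_COLUMNS:
            vals = kept[col].astype(object).to_numpy()
            vals[blank] = np.nan
            kept[col] = vals
        if fev_missing_prob > 0:
            fev = kept["fev"].to_numpy(dtype=float).copy()
            fev[rng.random(m) < fev_missing_prob] = np.nan
            kept["fev"] = fev
        pieces.append(kept)
    if not pieces:
        warnings.warn("degradation removed every patient", stacklevel=2)
        return admin.iloc[0:0].copy()
    return pd.concat(pieces, ignore_index=True)
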