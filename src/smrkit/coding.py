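"""Covariate coding shared by the generator, the risk models and the transfer scorer.

One fixed coding map turns a patient-level registry table into the design
columns of the case-mix model:

* age centred at a stated reference mean (years),
* sex with male as reference,
* ASA entered as a raw linear score (1-3),
* performance status dichotomised {0-1} vs {>=2},
* dyspnea score dichotomised {0-2} vs {>=3},
* BMI in three classes (<24, 24-28, >28 kg/m2, reference <24),
* procedure {other} vs {pneumonectomy},
* surgical approach {thoracotomy} vs {VATS},
* pathological tumour stage {I (ref), II, III, IV, Missing},
* nodal stage {0 (ref), 1, 2, Missing},
* quality of resection {R0 (ref), R1, R2, Missing},
* one binary flag per comorbidity,
* FEV (% predicted) as a continuous candidate.

Having a single coder guarantees that a coefficient vector estimated on one
group can be applied unchanged to another group (linear-predictor transfer).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "COMORBIDITIES",
    "STAGE_COLUMNS",
    "MISSING_CATEGORY",
    "VARIABLE_TERMS",
    "ALL_TERMS",
    "DEFAULT_CANDIDATE_VARIABLES",
    "CodingError",
    "encode",
    "terms_for",
]

#: Comorbidity flag columns carried by the clinical registry.
COMORBIDITIES = (
    "coronary_disease",
    "tobacco",
    "chronic_bronchitis",
    "arrhythmia",
    "chronic_heart_failure",
    "peripheral_artery_disease",
    "alcoholism",
    "cirrhosis",
    "stroke",
    "diabetes",
    "coagulation_disorder",
    "hematologic_disease",
    "history_of_neoplasm",
    "surgical_history",
    "severe_malnutrition",
    "pulmonary_embolism",
    "infectious_disease",
    "endocrine_disease",
    "anemia",
    "steroids",
    "immunosuppression",
    "cardiac_malformation",
    "chronic_renal_disease",
    "valvulopathy",
    "neurological_disorder",
    "psychiatric_disorder",
    "asthma",
    "respiratory_failure",
)

MISSING_CATEGORY = "Missing"
#: Pathology columns that may be blank in a degraded registry.
STAGE_COLUMNS = ("ptumor", "pnodes", "resection")

SEX_LEVELS = frozenset({"M", "F"})
PROCEDURE_LEVELS = frozenset({"limited", "lobectomy", "bilobectomy", "pneumonectomy"})
APPROACH_LEVELS = frozenset({"thoracotomy", "vats"})
PTUMOR_LEVELS = frozenset({"I", "II", "III", "IV", MISSING_CATEGORY})
PNODES_LEVELS = frozenset({"0", "1", "2", MISSING_CATEGORY})
RESECTION_LEVELS = frozenset({"R0", "R1", "R2", MISSING_CATEGORY})

#: Model "variables" (selection units) -> coded design columns (terms).
VARIABLE_TERMS: dict[str, tuple[str, ...]] = {
    "age": ("age_c",),
    "sex": ("female",),
    "asa": ("asa",),
    "performance_status": ("ps_ge2",),
    "dyspnea": ("dyspnea_ge3",),
    "fev": ("fev",),
    "bmi": ("bmi_24_28", "bmi_gt28"),
    "procedure": ("pneumonectomy",),
    "approach": ("vats",),
    "ptumor": ("ptumor_II", "ptumor_III", "ptumor_IV", "ptumor_Missing"),
    "pnodes": ("pnodes_1", "pnodes_2", "pnodes_Missing"),
    "resection": ("resection_R1", "resection_R2", "resection_Missing"),
}
VARIABLE_TERMS.update({c: (c,) for c in COMORBIDITIES})

ALL_TERMS: tuple[str, ...] = tuple(
    t for terms in VARIABLE_TERMS.values() for t in terms
)

#: Every variable offered to univariate screening by default.
DEFAULT_CANDIDATE_VARIABLES: tuple[str, ...] = tuple(VARIABLE_TERMS)


class CodingError(ValueError):
    """A registry column holds a level the coding map cannot express."""


def _check_levels(series: pd.Series, allowed: frozenset, name: str) -> None:
    values = series.dropna().unique()
    unknown = sorted(set(map(str, values)) - set(allowed))
    if unknown:
        raise CodingError(f"column {name!r} has unmappable levels: {unknown}")
    if series.isna().any() and name in STAGE_COLUMNS:
        raise CodingError(
            f"column {name!r} has blank entries; apply add_missing_categories first"
        )
    if series.isna().any():
        raise CodingError(f"column {name!r} has blank entries")


def terms_for(variables) -> tuple[str, ...]:
    """Expand variable names to their coded design columns, preserving order."""
    out: list[str] = []
    for v in variables:
        if v not in VARIABLE_TERMS:
            raise KeyError(f"unknown variable {v!r}")
        out.extend(VARIABLE_TERMS[v])
    return tuple(out)


def encode(table: pd.DataFrame, age_center: float, terms=None) -> pd.DataFrame:
    """Build the coded design matrix for ``table``.

    Parameters
    ----------
    table
        Patient-level registry table (see the data dictionary).
    age_center
        Reference mean age in years; the coded age column is ``age - age_center``.
    terms
        Coded columns to produce (default: every term).  Requesting ``"fev"``
        passes FEV through as-is, possibly with missing values.
    """
    if terms is None:
        terms = ALL_TERMS
    terms = tuple(terms)
    unknown = [t for t in terms if t not in ALL_TERMS]
    if unknown:
        raise CodingError(f"unknown coded terms: {unknown}")

    cols: dict[str, np.ndarray] = {}
    need = set(terms)

    if "age_c" in need:
        cols["age_c"] = table["age"].to_numpy(dtype=float) - float(age_center)
    if "female" in need:
        _check_levels(table["sex"], SEX_LEVELS, "sex")
        cols["female"] = (table["sex"].to_numpy() == "F").astype(float)
    if "asa" in need:
        cols["asa"] = table["asa"].to_numpy(dtype=float)
    if "ps_ge2" in need:
        cols["ps_ge2"] = (table["performance_status"].to_numpy(dtype=float) >= 2).astype(float)
    if "dyspnea_ge3" in need:
        cols["dyspnea_ge3"] = (table["dyspnea"].to_numpy(dtype=float) >= 3).astype(float)
    if "fev" in need:
        cols["fev"] = table["fev"].to_numpy(dtype=float)
    if {"bmi_24_28", "bmi_gt28"} & need:
        bmi = table["bmi"].to_numpy(dtype=float)
        cols["bmi_24_28"] = ((bmi >= 24) & (bmi <= 28)).astype(float)
        cols["bmi_gt28"] = (bmi > 28).astype(float)
    if "pneumonectomy" in need:
        _check_levels(table["procedure"], PROCEDURE_LEVELS, "procedure")
        cols["pneumonectomy"] = (table["procedure"].to_numpy() == "pneumonectomy").astype(float)
    if "vats" in need:
        _check_levels(table["approach"], APPROACH_LEVELS, "approach")
        cols["vats"] = (table["approach"].to_numpy() == "vats").astype(float)
    if any(t.startswith("ptumor_") for t in need):
        _check_levels(table["ptumor"], PTUMOR_LEVELS, "ptumor")
        pt = table["ptumor"].astype(str).to_numpy()
        for level in ("II", "III", "IV", MISSING_CATEGORY):
            cols[f"ptumor_{level}"] = (pt == level).astype(float)
    if any(t.startswith("pnodes_") for t in need):
        _check_levels(table["pnodes"].astype(str).where(table["pnodes"].notna()), PNODES_LEVELS, "pnodes")
        pn = table["pnodes"].astype(str).to_numpy()
        for level in ("1", "2", MISSING_CATEGORY):
            cols[f"pnodes_{level}"] = (pn == level).astype(float)
    if any(t.startswith("resection_") for t in need):
        _check_levels(table["resection"], RESECTION_LEVELS, "resection")
        rs = table["resection"].astype(str).to_numpy()
        for level in ("R1", "R2", MISSING_CATEGORY):
            cols[f"resection_{level}"] = (rs == level).astype(float)
    for c in COMORBIDITIES:
        if c in need:
            cols[c] = table[c].to_numpy(dtype=float)

    return pd.DataFrame({t: cols[t] for t in terms}, index=table.index)
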