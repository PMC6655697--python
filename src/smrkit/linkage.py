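"""Facility-level registry linkage, completeness ratios and quality classes.

The clinical and administrative registries are linked only at the facility
level (aggregate counts by facility code, no patient-level record linkage).
For each facility two completeness ratios are formed, clinical/administrative
for case counts and for death counts, so that under-reporting yields ratios
below 1.  A facility is classified good-quality data (GQD) when both ratios
reach the threshold (default 0.7) and do not anomalously exceed 1;
otherwise low-quality data (LQD).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["summarize_by_hospital", "classify_quality", "GQD", "LQD"]

GQD = "GQD"
LQD = "LQD"


def summarize_by_hospital(clinical: pd.DataFrame, admin: pd.DataFrame) -> pd.DataFrame:
    """Per-facility case and death counts from both registries, with ratios.

    One row per facility present in the administrative registry; facilities
    absent from the clinical registry get zero clinical counts.  Facilities
    present only in the clinical registry are a linkage anomaly: they are
    excluded, warned about, and listed in ``result.attrs["linkage_anomalies"]``.

    Ratio conventions: ``ratio_deaths`` is 1 when both registries record
    zero deaths (no evidence of under-reporting); clinical deaths without
    administrative deaths yield an infinite ratio and an anomaly flag.
    """
    a = admin.groupby("facility_id").agg(n_admin=("death", "size"),
                                         d_admin=("death", "sum"))
    c = clinical.groupby("facility_id").agg(n_clinical=("death", "size"),
                                            d_clinical=("death", "sum"))
    orphans = sorted(set(c.index) - set(a.index))
    if orphans:
        warnings.warn(
            f"{len(orphans)} facility(ies) present only in the clinical registry "
            f"excluded from classification: {orphans}", stacklevel=2)
    out = a.join(c, how="left").fillna(0).astype(int).reset_index()
    out = out[["facility_id", "n_clinical", "n_admin", "d_clinical", "d_admin"]]

    out["ratio_cases"] = out["n_clinical"] / out["n_admin"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rd = out["d_clinical"].to_numpy(float) / out["d_admin"].to_numpy(float)
    both_zero = (out["d_clinical"] == 0) & (out["d_admin"] == 0)
    rd[both_zero.to_numpy()] = 1.0  # 0/0: no evidence of under-reporting
    out["ratio_deaths"] = rd
    out["anomaly"] = np.isinf(rd)
    out.attrs["linkage_anomalies"] = orphans
    return out


def classify_quality(summaries: pd.DataFrame, threshold: float = 0.7,
                     upper_tolerance: float = 0.05) -> pd.DataFrame:
    """Attach GQD/LQD classes to hospital summaries.

    GQD requires both completeness ratios in ``[threshold, 1 + upper_tolerance]``
    (closed lower bound).  Ratios above ``1 + upper_tolerance`` — the clinical
    registry materially exceeding the reference — are flagged anomalous and
    classified LQD.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    out = summaries.copy()
    upper = 1.0 + upper_tolerance
    rc = out["ratio_cases"].to_numpy(float)
    rd = out["ratio_deaths"].to_numpy(float)
    over = (rc > upper) | (rd > upper)
    good = (rc >= threshold) & (rd >= threshold) & ~over
    out["quality_class"] = np.where(good, GQD, LQD)
    out["anomaly"] = out.get("anomaly", False) | over
    out.attrs["linkage_anomalies"] = summaries.attrs.get("linkage_anomalies", [])
    return out
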