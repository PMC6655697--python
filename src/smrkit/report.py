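"""Assemble the study report from pipeline outputs.

Writes machine-readable artefacts (hospital summary CSV, model JSONs, SMR
profile CSV, agreement JSON) and a human-readable ``report.txt`` with the
group characteristics, model coefficients, SMR dispersion and the 3x3
outlier cross-classification.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import StudyResult
from .smr import STATUSES

__all__ = ["build_report"]


def _matrix_lines(matrix: np.ndarray) -> list[str]:
    labels = [s.replace("-outlier", "") for s in STATUSES]
    corner = "SMR1 / SMR2"
    head = f"{corner:>14} " + " ".join(f"{c:>6}" for c in labels) + f" {'total':>6}"
    lines = [head]
    for i, row in enumerate(matrix):
        lines.append(f"{labels[i]:>14} " + " ".join(f"{v:>6d}" for v in row)
                     + f" {row.sum():>6d}")
    lines.append(f"{'total':>14} " + " ".join(f"{v:>6d}" for v in matrix.sum(axis=0))
                 + f" {matrix.sum():>6d}")
    return lines


def build_report(result: StudyResult, outdir) -> Path:
    """Write all report artefacts into ``outdir``; returns the report path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    result.summaries.to_csv(outdir / "hospital_summary.csv", index=False)
    result.model_gqd.to_json(outdir / "model_gqd.json")
    result.model_lqd.to_json(outdir / "model_lqd.json")
    profiles = pd.concat([result.smr1, result.smr2], ignore_index=True)
    profiles.to_csv(outdir / "smr_profiles.csv", index=False)

    with open(outdir / "agreement.json", "w") as fh:
        json.dump({"matrix": result.matrix.tolist(),
                   "n": int(result.matrix.sum()),
                   "kappa": result.kappa,
                   "band": result.kappa_band}, fh, indent=2)

    cls = result.summaries
    lines = ["Hospital profiling report", "=" * 60, ""]
    lines.append("Registry linkage and data quality")
    lines.append(f"  hospitals linked: {len(cls)}  "
                 f"(GQD {len(result.gqd_ids)}, LQD {len(result.lqd_ids)})")
    for group, ids in (("GQD", result.gqd_ids), ("LQD", result.lqd_ids)):
        sub = cls[cls["facility_id"].isin(ids)]
        patients = result.clinical["facility_id"].isin(ids).sum()
        lines.append(f"  {group}: {len(sub)} hospitals, {patients} clinical patients, "
                     f"median case ratio {sub['ratio_cases'].median():.3f}, "
                     f"median death ratio {sub['ratio_deaths'].median():.3f}")
    lines.append("")
    lines.append("Group mortality (clinical registry)")
    lines.append(f"  GQD {100 * result.mortality_gqd:.1f}% vs "
                 f"LQD {100 * result.mortality_lqd:.1f}%  "
                 f"(chi-square p = {result.mortality_pvalue:.2e})")
    lines.append("")
    for name, model in (("GQD", result.model_gqd), ("LQD", result.model_lqd)):
        lines.append(f"Case-mix model, {name} group "
                     f"(n={model.n}, deaths={model.deaths})")
        lines.append(f"  intercept {model.intercept:+.3f}  "
                     f"C={model.c_statistic:.3f}  R2={model.r2:.3f}  "
                     f"HL={model.hl_statistic:.2f} (p={model.hl_pvalue:.2f})")
        for t in model.terms:
            lines.append(f"    {t:<24} {model.coefficients[t]:+.3f} "
                         f"({model.standard_errors[t]:.3f})")
        lines.append("")
    q1, q3 = result.iqr_smr1
    lines.append(f"SMR1 (internal LQD model)    IQR {q1:.3f}-{q3:.3f}, "
                 f"high outliers {(result.smr1['status'] == STATUSES[2]).sum()}")
    q1, q3 = result.iqr_smr2
    lines.append(f"SMR2 (transferred GQD model) IQR {q1:.3f}-{q3:.3f}, "
                 f"high outliers {(result.smr2['status'] == STATUSES[2]).sum()}")
    lines.append("")
    lines.append("Outlier status cross-classification (LQD hospitals)")
    lines.extend(_matrix_lines(result.matrix))
    lines.append("")
    lines.append(f"Cohen's kappa {result.kappa:.2f} ({result.kappa_band} agreement)")

    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
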