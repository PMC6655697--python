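"""Agreement between profiling methods and group-level comparisons.

Hospitals are cross-classified by outlier status (low/non/high) under two
SMR estimators; chance-corrected agreement is Cohen's unweighted kappa,
kappa = (Po - Pe)/(1 - Pe), read against the conventional bands
(>0.8 excellent, 0.6-0.8 satisfactory, 0.41-0.6 moderate, 0.21-0.4 low,
below that poor).  Group mortality rates are compared with a Pearson
chi-square on the 2x2 table (Fisher's exact when an expected cell is
small).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .smr import STATUSES

__all__ = ["cross_classify", "cohen_kappa", "kappa_band",
           "two_proportion_test", "compare_group_mortality"]


def cross_classify(smr1: pd.DataFrame, smr2: pd.DataFrame) -> np.ndarray:
    """3x3 cross-classification of hospital status under two estimators.

    Rows follow estimator 1, columns estimator 2, both ordered
    low/non/high.  Both inputs must cover exactly the same facilities.
    """
    if len(smr1) == 0 or len(smr2) == 0:
        raise ValueError("empty SMR profile")
    s1 = smr1.set_index("facility_id")["status"]
    s2 = smr2.set_index("facility_id")["status"]
    if set(s1.index) != set(s2.index):
        diff = sorted(set(s1.index) ^ set(s2.index))
        raise ValueError(f"facility sets differ between estimators: {diff}")
    s2 = s2.reindex(s1.index)
    matrix = np.zeros((3, 3), dtype=int)
    pos = {s: i for i, s in enumerate(STATUSES)}
    for a, b in zip(s1, s2):
        matrix[pos[a], pos[b]] += 1
    return matrix


def kappa_band(kappa: float) -> str:
    if kappa > 0.8:
        return "excellent"
    if kappa >= 0.6:
        return "satisfactory"
    if kappa >= 0.41:
        return "moderate"
    if kappa >= 0.21:
        return "low"
    return "poor"


def cohen_kappa(matrix) -> tuple[float, str]:
    """Unweighted Cohen's kappa and its interpretation band.

    ``matrix`` is a square contingency table of paired classifications.
    When chance agreement Pe = 1 (all mass in one cell pair) kappa is
    undefined; perfect observed agreement is then reported as kappa 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    n = m.sum()
    if n <= 0:
        raise ValueError("empty matrix")
    po = np.trace(m) / n
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / n ** 2
    if pe >= 1.0 - 1e-12:
        # degenerate margins: agreement is observed, not chance-correctable
        kappa = 1.0 if po >= 1.0 - 1e-12 else 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    return float(kappa), kappa_band(float(kappa))


def two_proportion_test(d1: int, n1: int, d2: int, n2: int):
    """Compare two mortality proportions on the implied 2x2 table.

    Returns ``(rate1, rate2, pvalue)``; Pearson chi-square without
    continuity correction, or Fisher's exact when any expected cell < 5.
    """
    table = np.array([[d1, n1 - d1], [d2, n2 - d2]], dtype=float)
    if (table < 0).any() or n1 <= 0 or n2 <= 0:
        raise ValueError("invalid 2x2 counts")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        _, p = fisher_exact(table.astype(int))
    elif table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        p = 1.0  # identical degenerate rates
    else:
        _, p, _, _ = chi2_contingency(table, correction=False)
    return d1 / n1, d2 / n2, float(p)


def compare_group_mortality(gqd: pd.DataFrame, lqd: pd.DataFrame):
    """Observed mortality rates of two patient groups and the chi-square p."""
    return two_proportion_test(int(gqd["death"].sum()), len(gqd),
                               int(lqd["death"].sum()), len(lqd))
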