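"""CSV round-tripping for registry tables (missing values as empty fields)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .coding import COMORBIDITIES, STAGE_COLUMNS

__all__ = ["read_registry", "write_registry"]

_STR_COLS = ("facility_id", "patient_id", "sex", "procedure", "approach",
             "ptumor", "pnodes", "resection")


def write_registry(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, na_rep="")
    return path


def read_registry(path) -> pd.DataFrame:
    dtype = {c: "object" for c in _STR_COLS}
    table = pd.read_csv(path, dtype=dtype, keep_default_na=True,
                        na_values=[""])
    for c in COMORBIDITIES:
        if c in table.columns:
            table[c] = table[c].astype(int)
    if "death" in table.columns:
        table["death"] = table["death"].astype(int)
    for c in STAGE_COLUMNS:
        if c in table.columns:
            table[c] = table[c].astype(object)
    return table
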