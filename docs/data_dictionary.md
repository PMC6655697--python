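# Registry data dictionary

Both registries are CSV files with one row per patient. Missing values are
encoded as empty fields. `facility_id` is the string key shared across the
two files (and with the hospital profile list).

## Administrative registry (`admin.csv`)

| column        | type   | values / units                                       |
|---------------|--------|------------------------------------------------------|
| `facility_id` | string | facility code, e.g. `H012`                           |
| `patient_id`  | string | unique within the extraction                         |
| `procedure`   | string | `limited`, `lobectomy`, `bilobectomy`, `pneumonectomy` |
| `approach`    | string | `thoracotomy`, `vats`                                |
| `death`       | int    | 0/1 — death ≤30 days of surgery or during the same stay |

The administrative registry is complete by construction (every simulated
patient appears) and carries no further case-mix.

## Clinical registry (`clinical.csv`)

All administrative columns above, plus:

| column               | type   | values / units                              |
|----------------------|--------|---------------------------------------------|
| `sex`                | string | `M`, `F`                                    |
| `age`                | float  | years                                       |
| `asa`                | int    | ASA score 1–3                               |
| `performance_status` | int    | 0, 1, 2 (2 encodes "≥2")                    |
| `dyspnea`            | int    | 0–3 (3 encodes "≥3")                        |
| `fev`                | float  | forced expiratory volume, % predicted; may be blank |
| `bmi`                | float  | kg/m²                                       |
| `ptumor`             | string | `I`, `II`, `III`, `IV`, `Missing`; may be blank |
| `pnodes`             | string | `0`, `1`, `2`, `Missing`; may be blank      |
| `resection`          | string | `R0`, `R1`, `R2`, `Missing`; may be blank   |
| 28 comorbidity flags | int    | 0/1 each — see `smrkit.coding.COMORBIDITIES` |

A blank in `ptumor`/`pnodes`/`resection` is a field blanked by hospital-
level degradation; the literal category `Missing` is baseline registry
missingness present at generation time. `add_missing_categories` folds the
blanks into `Missing` before modelling. The comorbidity flags, in column
order: coronary_disease, tobacco, chronic_bronchitis, arrhythmia,
chronic_heart_failure, peripheral_artery_disease, alcoholism, cirrhosis,
stroke, diabetes, coagulation_disorder, hematologic_disease,
history_of_neoplasm, surgical_history, severe_malnutrition,
pulmonary_embolism, infectious_disease, endocrine_disease, anemia,
steroids, immunosuppression, cardiac_malformation, chronic_renal_disease,
valvulopathy, neurological_disorder, psychiatric_disorder, asthma,
respiratory_failure.

The clinical registry contains only the patients retained by each
hospital's case reporting; its `death` flag is the *recorded* death, which
under death under-recording can be 0 for a true death.
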