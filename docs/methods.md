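# Methods

This note documents the statistical content of `smrkit`: the models and
procedures it implements, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducing its output.

## Outcome and case-mix model

The outcome is a single binary flag meaning death within 30 days of surgery
or later during the same hospital stay. The case-mix model is a logistic
regression on coded terms (`smrkit.coding`):

- age centred at the fitting sample's mean (years); the centring value is
  stored with the model so it travels with any transfer;
- sex (male reference), ASA score entered linearly as its raw 1–3 value
  (the intercept therefore formally corresponds to ASA 0 — an
  extrapolation, kept because it makes transferred linear predictors
  unambiguous), performance status dichotomised 0–1 vs ≥2, dyspnea 0–2 vs
  ≥3, BMI in three classes (<24, 24–28, >28 kg/m²);
- procedure (pneumonectomy vs other), approach (VATS vs thoracotomy);
- pathological tumour stage (I ref / II / III / IV / Missing), nodal stage
  and resection quality (R0 ref / R1 / R2 / Missing), where "Missing" is an
  explicit category — in registries, a blank stage is informative;
- 28 binary comorbidity flags.

Model building follows the conventional registry recipe: univariate
likelihood-ratio screening at p ≤ 0.1; a likelihood-ratio check of ordinal
covariates against the linear gradient (decision level 0.05 — returns
"linear" when linearity is not rejected); backward step-down with AIC as
the stopping rule (a forward variant is available via
`fit_model(select="forward_aic")`); optional admission of pairwise
interaction products of retained terms when they lower AIC. The
likelihood-ratio test (not Wald) is used for screening because it is exact
under the same asymptotics the selection uses.

Diagnostics: the C-statistic is the rank-based AUC (midranks, ties count
½); R² is Nagelkerke's rescaling (the common choice when a single R² is
reported alongside a logistic model); the Hosmer–Lemeshow statistic sums
(O−E)²/(E(1−E/n_g)) over deciles of predicted risk and is referred to
chi-square with groups−2 degrees of freedom (the convention is validated in
the tests by two published statistic/p-value pairs: 4.47→0.81 and
6.4→0.60 with 10 groups). Degenerate cases (constant predictions, merged
deciles) warn and degrade gracefully rather than fail.

## Missing data

Only FEV is imputed. Stage and resection blanks become the "Missing"
category; comorbidity absence is read as "No", as registries do. FEV is
completed by proper multiple imputation (default m = 5): Bayesian linear
regression of observed FEV on all coded covariates plus the outcome
(including the outcome is standard practice — omitting it biases
exposure–outcome associations toward null), drawing the residual variance
from its scaled inverse-chi-square posterior and coefficients from their
normal posterior, with draws truncated to 10–160 % predicted. Per-dataset
estimates are combined with Rubin's rules: pooled coefficient = mean;
pooled variance = within + (1 + 1/m) × between. Because selection and
imputation interact and no single convention exists, the pipeline screens
per completed dataset and keeps variables passing in a majority, runs the
AIC step-down per dataset and keeps variables retained in a majority, then
refits that fixed set per dataset and pools. With no missing FEV the whole
module is the identity.

## Linkage and quality classes

Registries are linked at the facility level only (aggregate counts by
facility code). Completeness ratios are oriented clinical/administrative so
that under-reporting gives values below 1. Conventions: 0/0 death ratio is
1 (no evidence of under-reporting); clinical deaths without administrative
deaths, or ratios above 1 + 0.05, are flagged anomalous and classified LQD;
the GQD rule is closed at the lower boundary (both ratios ≥ 0.7). The
threshold is a parameter; 0.7 is the conventional default.

## SMR profiling

E per hospital is the sum of predicted probabilities; SMR = O/E. The
standard error uses the sum of Bernoulli variances,
Var(O) = Σ p̂ᵢ(1−p̂ᵢ), se(SMR) = √Var(O)/E — the standard form for
indirectly standardized SMRs from a patient-level logistic model. The
outlier test is the normal deviate z = (O−E)/√Var(O) against ±z₁₋α/₂,
two-sided α = 0.05 by default; an exact mid-p Poisson alternative
(`method="midp"`) is available for small expected counts. Hospitals with
O = 0 keep SMR 0 (they are profiled, not excluded); E = 0 with O > 0 is an
error. No multiplicity correction is applied across hospitals by default
(a Bonferroni-style correction can be had by passing a smaller α).

Two estimators: **internal** (model fitted on the profiled group itself,
which enforces Σ E = Σ O at the group level — the intercept's score
equation) and **transferred** (a reference model's coefficients and age
centring applied unchanged; unmappable covariate levels raise with the
offending levels listed). Transferring a model onto its own training group
reproduces the internal expectations exactly; this identity is asserted in
the tests.

## Agreement and group comparison

Unweighted Cohen's kappa on the 3×3 low/non/high cross-classification
(the categories are treated as nominal; unweighted kappa also reproduces
the published worked example the tests pin, which settles the choice
empirically). Bands: >0.8 excellent, 0.6–0.8 satisfactory, 0.41–0.6
moderate, 0.21–0.4 low, otherwise poor. When chance agreement Pe = 1 the
statistic is undefined; perfect observed agreement is reported as 1,
otherwise 0. Group mortality is compared by Pearson chi-square without
continuity correction, with Fisher's exact as automatic fallback when an
expected cell is below 5.

## The synthetic-data generator

The generator emulates a two-year national extraction: an exhaustive
administrative registry and a voluntary clinical registry degraded
per-hospital. Defaults describe the well-documented clinical population:
age N(64, 10) years, 34% female, ASA {15.5, 52, 32.5}%, performance status
{44, 46, 10}%, dyspnea {42.5, 36, 18, 3.5}%, FEV N(83, 21)% predicted with
10% missing, BMI N(25.45, 4.5) kg/m², procedures {limited 14, lobectomy 74,
bilobectomy 3.5, pneumonectomy 8.5}%, 28% VATS, stage and resection
distributions including organic "Missing" levels (10–12%), and the 28
comorbidity prevalences listed in `smrkit.synthetic`. True deaths come from
a reference logistic model (intercept −4.4, age 0.044/yr, female −0.944,
ASA 0.31 linear, and so on — see `default_true_model()`); covariates absent
from that model have true coefficient 0.

Hospitals draw an expected volume LogNormal(ln 140, 0.9) clipped to
[20, 1500] cases and a type (non-teaching 21%, private 46%, teaching 33%).
Degradation mechanisms are separately configurable per hospital: case
omission, death under-recording (recorded alive), comorbidity under-coding,
stage blanking, FEV blanking, and an optional risk-selective omission knob
(off by default — omission is non-selective unless asked for). The
`"clean"` scenario sets all report probabilities to 1 and is exactly the
identity on the registry; `"paper-like"` draws ~25% of hospitals
near-complete (case/death/comorbidity report probabilities ≥ 0.9, stage
blanking 5–15%) and the rest with at least one substantially degraded
mechanism (case 0.20–0.78, death 0.20–0.80, comorbidity 0.40–0.90, stage
blanking 10–35%), so that roughly a quarter of hospitals classify GQD.
Random streams are split per hospital from the master seed, so appending a
hospital never perturbs the others.

What the generator does **not** emulate: between-hospital case-mix
differences (every hospital draws patients from the same marginals — only
the data-quality mechanisms differ), correlation among covariates (a single
optional ASA–comorbidity tilt aside), coding-system artefacts, episodes or
transfers, and temporal drift. Consequently, passing tests demonstrate the
estimators' behaviour under quality degradation with homogeneous case-mix;
they say nothing about confounding by genuinely different patient
populations across hospitals.

One consequence is worth spelling out. With homogeneous case-mix and no
recalibration, the transferred model predicts a near-uniformly higher risk
than the internal model whenever deaths are under-recorded, so every
hospital's transferred SMR is its internal SMR times a factor below 1 and
the between-hospital SMR dispersion *narrows* under transfer even as
Σ E₂ > Σ O. In real registry comparisons the dispersion can widen instead,
because hospitals differ in case-mix and the two coefficient vectors weight
that case-mix differently. Widening under transfer therefore requires
hospital-level case-mix heterogeneity, which this generator deliberately
does not include.

## Numerical choices and problem sizes

Logistic fits use Newton–Raphson (tolerance 1e-10, up to 200 iterations)
with a BFGS fallback polished by a final Newton pass, so the score
equations — and with them the Σ E = Σ O identity — hold to ~1e-8 even near
quasi-separation; a fit that still fails to converge raises rather than
returning silently. Quantiles use linear interpolation. Imputation draws
are truncated, not redrawn. Validation problem sizes were chosen to make
the asserted properties sharp at modest cost: marginal checks at n = 10,000
patients (3-standard-error bands), coefficient recovery at the study scale
of n = 10,597 over 100 replicates, outlier type-I error over 1,000
simulated hospitals, and scenario-level properties over 200 full replicates
of a 100-hospital study.

## Known limitations

- Facility-level linkage only; no probabilistic patient-level record
  linkage.
- No hierarchical/shrinkage SMR estimation and no funnel-plot machinery;
  the z-test treats hospitals independently.
- The interaction search is greedy and pairwise; it will not find
  higher-order structure.
- The transferred estimator is a pure linear-predictor transfer by design;
  recalibration (intercept or slope updating) is deliberately out of scope,
  and conclusions about dispersion under transfer carry the caveat above.
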