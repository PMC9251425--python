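# Methods

## Index construction

**Inputs.** One row per participant × survey year × recall day × food group
with grams consumed, plus the day's total energy intake (kcal). Intakes are
averaged over the (1–3) recall days of a year, then element-wise over the
(1–2) baseline years present; participants assessed in only one baseline
year use that year, and the earliest year present anchors follow-up time.
Profiles with mean energy strictly below 500 or strictly above 5,000
kcal/day are excluded; the boundary values themselves are retained, and the
bounds are configurable.

**Residual energy adjustment.** For each food group, intake y is regressed
on total energy E by ordinary least squares across the analysis sample; the
adjusted intake is the residual plus the prediction at the sample-mean
energy, i.e. y − b·(E − Ē). This is the classic residual-method form: it
removes the between-person energy gradient while keeping the original units
and sample mean. If the sample's energy is constant the regression is
degenerate; raw intakes are returned with a warning rather than failing. The
regression is fit on untransformed intakes (a log-scale variant would change
only ranks near zero; ranks are all the scoring consumes).

**Quintile scoring.** Participants are ranked into quintiles of each
adjusted group intake using midranks for ties: fractional rank
f = (midrank − 0.5)/n, quintile = ⌊5f⌋ + 1 clamped to 5. Midranks matter
because many groups (tea/coffee, nuts, dairy, sugary drinks) are heavily
zero-inflated: naive quantile cut-points would split identical zeros across
quintiles arbitrarily, while the midrank rule keeps equal intakes in one
quintile deterministically and order-independently. Quintile q maps to a
score of q points for a positively scored group and 6 − q for a negatively
scored one; under the PDI all 12 plant groups are positive and the 5 animal
groups negative, under the hPDI only the 7 healthy plant groups are
positive. The 17 group scores sum to a total in [17, 85]. Flipping every
direction maps each score s → 6 − s, so mirrored schemes satisfy
total + total′ = 102 — a structural identity used in the tests.

Exposure quintiles of the total, their median totals, and the z-score
(total minus sample mean over sample SD, ddof = 1) are computed **within
each analysis sample** by default, since each outcome has its own exclusion
flow; whole-cohort scoring is available by scoring first and joining. The
scoring stage is exposed as sklearn-style transformers
(`ResidualEnergyAdjuster`, `PlantDietIndexScorer`): `fit` learns the energy
regression, per-group ranking references and the total's mean/SD from the
analysis sample, `transform` scores any table against those references, so
the scorer composes with sklearn pipelines and model selection.

**Food-group taxonomy.** The default map has exactly 17 groups — 7 healthy
plant, 5 less-healthy plant, 5 animal. Chinese cohorts sometimes separate a
distinct "fermented foods" group; it is available as an optional 18th group
with a configurable category (healthy plant by default), since its health
classification is genuinely contested. Item-code → group lookup is a plain
configurable dictionary; unmapped codes raise rather than being dropped.

## Outcome ascertainment and exclusion flow

Outcomes are evaluated at each attended follow-up wave:

* overweight/obesity: BMI = weight/height² ≥ 24 kg/m² (Chinese Working
  Group combined threshold; no separate ≥ 28 obesity subclass);
* hypertension: SBP ≥ 140 mmHg or DBP ≥ 90 mmHg (means of repeated seated
  readings, taken upstream) or self-reported diagnosis/antihypertensive
  medication;
* type 2 diabetes: at biomarker waves (2009), FPG ≥ 7.0 mmol/L or
  HbA1c ≥ 6.5 % or self-report/medication; at 2015, self-report/medication
  only — biomarkers recorded at such a wave are deliberately ignored so the
  definition matches the wave's instrument.

Medication use counts as disease throughout. A wave where every criterion
is unobservable yields a missing status; a participant with no informative
follow-up wave is excluded as outcome-missing. Events are dated to the
**first wave meeting the definition** (not an interval midpoint): with
wave-based observation this is the earliest observable onset date and keeps
person-years integral. Follow-up runs from the participant's baseline year
to the event wave or the last informative wave; person-years are the sample
sum of follow-up.

The exclusion flow applies, in order: energy filter → prevalent CVD/cancer
→ loss to follow-up → prevalent outcome (per outcome, from baseline
measurements) → missing outcome. The ledger records each step, and
excluded + retained = input is asserted property-style on every synthetic
cohort. Samples with fewer than 5 retained participants cannot be quintile-
scored and are returned unscored with a warning.

## Survival analysis

Cox proportional-hazards models are fit by partial-likelihood maximisation
(delegated to lifelines) on the time scale of years since baseline, with
the **Efron tie correction** — event times are wave years, so ties are
heavy and Breslow would be noticeably biased; no alternative tie method is
exposed. Newton convergence tolerance is tightened to 1e-9 so small-sample
fits agree with a brute-force partial-likelihood grid search to < 1e-4.
Constant covariates are dropped with a warning; fewer than two events is an
error. Adjustment sets are nested: model 1 {urban/rural, age, sex, energy},
model 2 + {education (dummy-coded), MET/day, smoking, alcohol}, model 3
+ {BMI}, with baseline SBP/DBP added for dose–response and ROC runs.

* **Quintile HRs**: indicator terms for Q2–Q5; Q1 is the reference with HR
  identically 1. A quintile level absent from a sample is reported absent,
  never imputed.
* **Trend test**: each participant's exposure is replaced by their
  quintile's median index total, entered continuously in the same model;
  the Wald p of that term is the p-trend. No multiplicity correction is
  applied.
* **Per-SD HR**: the z-scored total entered continuously; by linearity this
  equals the raw-total fit with β rescaled by the sample SD (asserted as a
  cross-check).
* **Restricted cubic splines**: Harrell truncated-power natural-spline
  basis (linear beyond boundary knots), 4 knots at the 5/35/65/95th
  percentiles, normalised by the squared boundary-knot span. The curve is
  anchored at HR = 1 at the reference (sample median by default; the
  reference point is inserted into the evaluation grid so the anchor is
  exact), with pointwise Wald bands from the spline coefficients'
  covariance.
* **PH check**: each term in turn is augmented with a term × log(time)
  interaction in a time-varying Cox model. Episodes are split at distinct
  event times (vectorised; wave data have few distinct times, keeping the
  long format small) and the interaction's Wald p is reported per term.
* **Stratified analyses** (sex; age < 55 / ≥ 55): the model is re-fit
  within each stratum while keeping exposure quintiles fixed from the
  parent sample, so categories remain comparable across strata; strata with
  fewer than two events are skipped with a warning.

## Discrimination and description

AUC is the tie-corrected rank statistic (exhaustive concordant-pair
fraction, ties half), with variance and the paired model comparison via
DeLong's structural components; the degenerate case of identical score
vectors returns ΔAUC = 0, p = 1. Risk scores are the linear predictor of
the fully adjusted Cox model including the index term (a logistic variant
is deliberately not the default), and labels are event vs no event over the
whole follow-up — a static ROC; time-dependent ROC is out of scope.
Censoring before the first event wave counts as non-event, matching the
sample construction. Index concordance uses Spearman midrank correlation.
Descriptive tables report mean ± SD with ANOVA, median [IQR] with
Kruskal–Wallis when flagged (a per-variable flag, not automatic normality
testing — deterministic behaviour), or n (%) with an uncorrected chi-square;
constant categorical variables are skipped with a note.

## Synthetic cohort generator

The generator emulates the *design* of a two-baseline-wave Chinese
nutrition cohort, not its microdata:

* **Covariates** (defaults): sex male 0.48, urban 0.30, age N(46, 13²)
  truncated to 18–80 y, 4-level education (0.45/0.34/0.13/0.08), MET/day
  N(185, 125²) floored at 5, smoking 0.33, alcohol 0.34, habitual energy
  N(2230, 600²) kcal/day — magnitudes typical of published Chinese cohort
  baseline tables. The untruncated energy tails deliberately produce a
  small fraction outside the 500–5,000 kcal window so the energy filter is
  exercised.
* **Intakes**: each group is zero-inflated log-normal (median g/day and
  zero probability per group; e.g. vegetables 350 g/day with no zeros,
  tea/coffee median 5 g/day with 85 % never-consumers), with log-intake
  rising 0.25 per SD of habitual energy. A standard-normal latent
  diet-quality factor shifts each group's log intake by ±1.0 per SD
  (healthy plant groups up, less-healthy plant and animal groups down —
  i.e. aligned with the hPDI directions) and tilts consumer status through
  a Gaussian threshold with correlation 0.6, preserving each group's
  marginal zero probability. The loading magnitudes are chosen so adjacent
  index quintiles differ in fruit intake by roughly an order of magnitude
  between top and bottom, as real plant-based-diet cohorts report.
* **Ground truth**: the *true index* is the diet index computed on the
  participant's habitual (noise-free) intake profile, standardised within
  the cohort (the hPDI by default, configurable). This makes the estimand
  of the recall-based pipeline exactly the quantity the hazard acts on;
  recall noise (multiplicative day-to-day SD 0.30, year-to-year 0.15,
  energy reporting 0.08) is then honest measurement error rather than an
  irreducible latent-variable attenuation.
* **Events**: exponential times with rate h₀·exp(β·z + γᵀ·covariates);
  per-outcome defaults h₀ = 0.042, 0.040, 0.0095 events/person-year and
  true HR per SD 0.89, 0.88, 0.93 for overweight/obesity, hypertension and
  T2D, with age and sex effects, chosen to reproduce cumulative incidences
  of roughly a third, a third and under a tenth over ~10 years of
  follow-up. A Weibull shape is available, and a time-decaying index effect
  (`index_effect_halflife`) provides a genuine PH violation for testing the
  PH check (a Weibull baseline alone cannot violate PH in the covariates).
* **Observation**: baseline prevalence 0.32/0.31/0.035 expressed through
  baseline measurements; 25 % lost to follow-up; attendance 0.90/0.88 at
  the 2009/2015 waves (at least one wave forced for retained participants);
  per-wave measurement-block missingness 0.18/0.15/0.20. Measurements are
  generated consistently with the latent event time: below every diagnostic
  threshold before it, satisfying the wave's definition at and after it.
  T2D biomarkers exist only at the 2009 wave; 2015 carries self-report and
  medication only.
* **Determinism**: one seed in the config; each stage draws from its own
  deterministic substream, so datasets are bit-reproducible and stages can
  be regenerated independently.

What the generator does **not** emulate: item-level (thousands-of-foods)
dictionaries and household inventory weighing (generation is at food-group
level), multi-stage province sampling and clustering, secular dietary
trends between waves, correlated covariate structure beyond the hazard
model, and informative (outcome-dependent) dropout. Passing recovery and
calibration tests therefore demonstrates the *pipeline's* correctness under
a faithful design, not robustness to those real-data complications.

## Numerical choices and degenerate inputs

Quintile assignment requires n ≥ 5; residual adjustment requires n ≥ 3 and
returns raw intakes (with a warning) under zero energy variance; splines
require enough distinct index values for their knots and suggest fewer
knots otherwise; the trend test refuses all-equal quintile medians; AUC
requires both classes; Spearman refuses constant vectors. Wald 95 %
intervals use the normal quantile 1.96 throughout. Problem sizes used by
the stochastic test suites — 20 replicates of n = 5,000 for per-SD
recovery and size, 200 replicates of n = 900 for trend-test calibration —
were chosen as the smallest sizes at which the binomial tolerance bands in
those contracts are meaningful.

## Known limitations

* Only the Efron tie method is implemented.
* The PH check's episode splitting scales with the number of *distinct*
  event times; it is intended for interval-observed (wave) data, not for
  continuous event times on large samples.
* Time-dependent diet exposure, competing risks, frailty and multiple
  imputation of missing outcomes are out of scope; missing outcomes are
  excluded, as the exclusion ledger documents.
* The uPDI (unhealthful plant-based diet index) is not computed, though
  `IndexScheme` makes custom direction sets trivial to define.
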