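# plantdiet

Plant-based diet indices and their longitudinal association with
cardiometabolic disease, as a tested, reusable Python package.

## The problem

Nutritional epidemiology increasingly scores whole diets rather than single
nutrients. Two widely used scores summarise how plant-based a diet is:

* **PDI** (overall plant-based diet index): every plant food group is scored
  positively, every animal food group negatively.
* **hPDI** (healthful plant-based diet index): only *healthy* plant groups
  (whole grains, fruits, vegetables, nuts, legumes, tea/coffee, vegetable
  oils) are scored positively; less-healthy plant groups (refined grains,
  potatoes, sugary drinks, sweets, preserved foods) and animal groups are
  reverse-scored.

Given per-participant 24-h dietary recalls (grams/day for 17 food groups,
plus total energy), each group's intake is energy-adjusted with the
**residual method** — regress intake on total energy by OLS and keep
residual + prediction at the sample-mean energy — then ranked into sample
quintiles. Quintile *q* scores *q* points for a positively scored group and
*6 − q* for a negatively scored one. Summing the 17 group scores gives an
index total in **[17, 85]**; the total is itself divided into exposure
quintiles Q1–Q5.

The association with incident overweight/obesity (BMI ≥ 24 kg/m²),
hypertension (SBP ≥ 140 mmHg, DBP ≥ 90 mmHg, or self-report/medication) and
type 2 diabetes (at biomarker waves FPG ≥ 7.0 mmol/L, HbA1c ≥ 6.5 %, or
self-report; at later waves self-report/medication only) is estimated with
Cox proportional-hazards models

> h(t | X) = h₀(t) · exp(β·exposure + γᵀ·covariates)

under three nested adjustment sets (model 1: urban/rural, age, sex, energy;
model 2: + education, physical activity, smoking, alcohol; model 3: + BMI),
with quintile hazard ratios (Q1 reference), a quintile-median trend test,
per-1-SD hazard ratios, restricted cubic spline dose–response curves,
time-interaction proportional-hazards checks, sex/age stratification, and a
paired DeLong comparison of the ROC AUCs of PDI- vs hPDI-based prediction
models.

Because survey microdata are access-restricted, the package ships a
**synthetic cohort generator** that emulates the study design — 3 recall
days × 2 baseline years, zero-inflated log-normal group intakes coupled to
energy and to a latent diet-quality score, baseline covariates and
prevalence, and outcomes observed only at follow-up waves (2009/2015) —
with known ground truth, so every pipeline stage is testable end to end.

## Worked example

```python
from plantdiet import SimulationConfig, simulate_dataset, analyze_outcome

cfg = SimulationConfig(n_participants=5000, seed=11)
ds = simulate_dataset(cfg)                       # baseline, recalls, waves
res = analyze_outcome(ds, "hypertension", index="hpdi", model=3)

print("n =", res.sample.n, "| events =", res.sample.n_events,
      "| person-years =", round(res.sample.person_years))
print(res.quintile_hr.round(2))
print(f"HR per 1 SD: {res.per_sd['hr']:.2f} "
      f"({res.per_sd['hr_lower']:.2f}, {res.per_sd['hr_upper']:.2f}); "
      f"p-trend = {res.p_trend:.2g}")
```

prints

```
n = 2411 | events = 783 | person-years = 21091
      hr  hr_lower  hr_upper     p
Q1  1.00       NaN       NaN   NaN
Q2  0.93      0.75      1.15  0.50
Q3  0.79      0.64      0.99  0.04
Q4  0.80      0.64      1.00  0.05
Q5  0.63      0.50      0.79  0.00
HR per 1 SD: 0.86 (0.80, 0.92); p-trend = 3.1e-05
```

Reading: of 5,000 simulated participants, 2,411 survive the exclusion flow
(energy filter, prevalent CVD/cancer, loss to follow-up, prevalent
hypertension, missing outcomes). Participants in the top hPDI quintile have
0.63 times the hypertension hazard of the bottom quintile, and each 1-SD
increase of the index multiplies the hazard by 0.86 — close to the
generator's true value of 0.88 for this run. The same entry point serves
user-supplied tables in the documented CSV schemas.

A command-line interface wraps the same functions:

```bash
plantdiet simulate --out cohort/ --n 5000 --seed 11
plantdiet score --dataset cohort/ --index hpdi --out scores.csv
plantdiet build-sample --dataset cohort/ --outcome t2d --out sample_t2d.csv
plantdiet analyze --dataset cohort/ --outcome hypertension --index hpdi \
    --model 3 --out results.json
```

## Layout

| module | contents |
| --- | --- |
| `plantdiet.food_groups` | 17-group taxonomy, item-code classification |
| `plantdiet.intake` | recall aggregation, baseline-year averaging, energy filter |
| `plantdiet.index` | residual adjustment, quintile scoring, PDI/hPDI (sklearn-style transformers) |
| `plantdiet.outcomes` | outcome ascertainment, exclusion flow, person-years |
| `plantdiet.survival` | Cox models, trend test, per-SD HR, splines, PH check, strata |
| `plantdiet.evaluate` | ROC/AUC with DeLong comparison, Spearman, Table-1 summaries |
| `plantdiet.simulate` | synthetic cohort generator and dataset I/O |
| `plantdiet.pipeline` | end-to-end orchestration |

See `docs/methods.md` for the statistical methods, generator design and
known limitations.
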