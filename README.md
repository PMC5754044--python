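# npcohort

Nutrient-profile scoring and cohort survival analysis: a tested,
reproducible pipeline for asking whether eating more "less-healthy" food —
as defined by the UK FSA-Ofcom nutrient profile model — predicts incident
cardiovascular disease (CVD) or mortality in a prospective diet-diary
cohort.

The package is aimed at nutritional epidemiologists and methodologists
who want the full analytic chain of such a study as executable,
verifiable code: item scoring, exposure construction, exclusion rules,
hazard modelling, and a synthetic-data generator that plants a known
truth (including the reverse-causation confounding pattern in which
higher-risk participants eat *less* of the less-healthy food) so that
every stage can be validated quantitatively.

## The model

**Scoring.** Each food/beverage item is scored per 100 g edible weight:

    score = A_energy + A_satfat + A_sugars + A_sodium − C_fvn − C_fibre − [C_protein]

where each A component earns 0–10 points and each C component 0–5 points
from fixed cut-point tables (strictly-greater-than semantics), and
protein points only count when the A total is below 11 or the
fruit/veg/nut component is at its 5-point maximum. A food scoring ≥ 4
(beverage ≥ 1) is classified *less-healthy*; alcoholic beverages are
never scored.

**Exposure.** From a 7-day diet diary, each participant's primary
exposure is

    prop_lh_energy = (E_lh_food + E_lh_beverage) / (E_total − E_alcoholic)

with the analysis sample divided into quintile groups. Alternative
exposures (less-healthy weight share, energy-weighted mean score,
fruit+veg weight) support sensitivity analyses.

**Analysis.** After the exclusion cascade (≥1 diary day; 0.5% trim of
the energy:Schofield-BMR ratio per tail; prevalent CVD for the
incident-CVD analysis; missing covariates), Cox proportional-hazards
models estimate quintile hazard ratios (Q1 reference) under three
covariate sets (unadjusted; Model 1 sociodemographic/behavioural;
Model 2 adding self-reported clinical indicators and family history),
with a linear trend test across quintiles, an isocaloric substitution
model, and Schoenfeld-residual proportional-hazards diagnostics.

See `docs/methods.md` for the full specification of every convention.

## Worked example

Simulate a full study at the default scale (25,000 participants, 7-day
diaries, zero planted exposure effect with planted confounding), score
it, build exposures, apply the incident-CVD exclusion cascade, and fit
the models:

```python
from npcohort import GeneratorConfig, run_study

cfg = GeneratorConfig(seed=1)          # n_participants=25,000
res = run_study(cfg, seed=1, covariate_sets=("unadjusted", "model1", "model2"))
print(res["exclusion_log"].to_frame().to_string(index=False))
r = res["fits"]["model2"]
print(r.quintile_hr.round(3))
print("trend p =", round(r.trend_p, 4))
```

Output (abridged):

```
              step  n_before  n_excluded  n_after
      no_diary_day     25000         369    24631
   energy_bmr_trim     24631         246    24385
     prevalent_cvd     24385        2575    21810
missing_covariates     21810         238    21572

[unadjusted] n = 21572, events = 4200, trend p = 0.0796, slope = +0.0192
[model1]     n = 21572, events = 4200, trend p = 0.2588, slope = -0.0131
[model2]     n = 21572, events = 4200, trend p = 0.4526, slope = -0.0087
```

Reading: the generator planted *no* exposure effect, but confounding
(older, more male, more often smoking participants eat more less-healthy
food) pushes the unadjusted trend slope positive; adjustment removes it.
Across 200 replicates the unadjusted trend test rejects far above the 5%
nominal rate while the adjusted models stay calibrated — the qualitative
signature of a confounded null. Per-quintile hazard ratios with 95% CIs
are in `r.quintile_hr`, covariate effects in `r.hazard_ratios`, and
`r.check_ph()` gives per-covariate and global Schoenfeld tests.

The same chain is scriptable:

```sh
npcohort simulate --seed 1 --out study/
npcohort score --catalogue study/catalogue.csv --out study/scored.csv
npcohort build-exposure --diary study/diary.csv --scored study/scored.csv \
    --catalogue study/catalogue.csv --out study/exposures.csv
npcohort filter --participants study/participants.csv \
    --exposure study/exposures.csv --analysis cvd --out study/cohort.csv
npcohort fit --cohort study/cohort.csv --outcomes study/outcomes.csv \
    --outcome incident_cvd --model model2 --out study/fit.json
```

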