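# Methods

This note documents the models, conventions and design choices behind
`npcohort`: a pipeline that scores food items with the FSA-Ofcom nutrient
profile model, builds person-level "less-healthy food" exposures from
7-day diet diaries, applies a standard epidemiological exclusion cascade,
and fits Cox proportional-hazards models of exposure quintiles on incident
cardiovascular disease (CVD) and mortality. All inputs are produced by a
synthetic study generator with planted truth, so every stage can be
validated quantitatively without access to any real cohort.

## 1. Nutrient profile scoring (`npcohort.scoring`)

Each item is scored from its composition per 100 g edible weight. Four
adverse "A" components — energy (kJ), saturated fat (g), total sugars (g),
sodium (mg) — each earn 0–10 points; three beneficial "C" components — NSP
fibre (g), protein (g), and the fruit/vegetable/nut (FVN) weight
percentage — earn points that are subtracted:

    score = A_energy + A_satfat + A_sugars + A_sodium
            − C_fvn − C_fibre − [C_protein]

A component's points equal the number of its cut-points *strictly
exceeded* by the value. The 2004/05 cut-point tables ship as configuration
(`data/fsa_ofcom_2005.yaml`): energy 335…3350 kJ in steps of 335;
saturated fat 1…10 g; sugars 4.5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45 g;
sodium 90…900 mg in steps of 90; fibre 0.7…3.5 g in steps of 0.7; protein
1.6…8.0 g in steps of 1.6; FVN >40% → 1, >60% → 2, >80% → 5 points.

*Protein gate.* When the A total reaches 11, protein points are only
subtracted if the FVN component is at its 5-point maximum.

*Classification.* A food is "less-healthy" at a score of 4 or more, a
beverage at 1 or more; any alcoholic beverage is exempt from scoring and
carries the class "unscored".

Conventions pinned here because the scoring guidance leaves them implicit
at data scale: strict ">" at every cut-point (exercised by boundary
tests), and no rounding of nutrient values before scoring — diary-derived
compositions are continuous and rounding would create avoidable boundary
artefacts. Category-specific exemptions used by other jurisdictions
(cheese/fat/diet-drink adjustments) are out of scope.

## 2. Exposure construction (`npcohort.exposure`)

Diary rows (participant × day × item × grams) contribute
`grams × energy_kj / 100` kJ each and are routed by the item's
classification. All per-day quantities divide diary totals by the number
of *distinct* diary days, so partial diaries scale correctly. The primary
exposure is the proportion of energy from less-healthy items,

    prop_lh_energy = (E_lh_food + E_lh_beverage) / (E_total − E_alcoholic),

with alcohol excluded from the denominator because alcoholic beverages are
never scored. Three alternative exposures support sensitivity analyses:
the proportion of food *weight* that is less-healthy (beverage weight
included by default, excludable via a switch), the energy-weighted mean
profile score over non-alcoholic items, and fruit+vegetable grams per day
(from the catalogue's disaggregated fruit/veg weight fraction `fv_frac`;
when that column is absent the FVN percentage is used as a fallback).

*Quintiles.* Participants are ranked into fifths with group boundaries at
cumulative ranks ceil(n·j/5) — the nearest-rank empirical quantile
convention — and ties broken by a stable sort on (value, participant id).
For n = 22,992 this yields groups of 4599/4598/4599/4598/4598.
Quintiles are assigned on the analysis sample *after* exclusions,
separately per analysis, since the exclusion cascade differs between the
CVD and mortality analyses.

## 3. Exclusion cascade (`npcohort.filters`)

Fixed order, each step logged as (step, n_before, n_excluded, n_after):

1. **Diary completeness** — at least one diary day.
2. **Energy misreporting** — the ratio of reported energy intake to basal
   metabolic rate predicted by the sex- and age-band-specific Schofield
   weight equations (MJ/day; bands 18–29, 30–59, 60+, coefficients in
   `data/schofield.yaml`). With k = floor(0.005·n), participants whose
   ratio falls strictly outside the order statistics [x(k+1), x(n−k)] are
   removed — exactly k per tail under distinct values, nobody under heavy
   ties. Samples under 200 are not trimmed (warning).
3. **Prevalent CVD** (self-reported angina, heart attack or stroke) —
   removed for the incident-CVD analysis only; the mortality analysis
   retains these participants and adjusts for the flags instead.
4. **Missing covariates** — dropped, not imputed.

Optional sensitivity exclusions reproduce the reverse-causation checks:
dropping baseline clinical comorbidities (hypertension,
hypercholesterolemia, either medication), other comorbidities (diabetes,
cancer), family history of CVD, family history of diabetes, and a
landmark exclusion of events within the first follow-up years. The
cascade is deterministic on re-runs; with the quantile trim disabled it is
also a fixpoint (re-applying it to its own output removes nobody).

## 4. Survival models (`npcohort.survival`)

`CoxExposureModel(cohort, ModelSpec(...)).fit()` returns a
`CoxExposureResults` with hazard ratios, Wald 95% CIs, the quintile trend
test and PH diagnostics. Quintile exposures enter as four indicators
against Q1; covariate sets:

* **Model 1** — age (years, continuous), sex (reference male), education
  (4 levels, reference: no qualifications), smoking (reference: current),
  physical activity (4 levels, reference: inactive), alcohol (units/day),
  total energy (per 2,000 kJ/day);
* **Model 2** — Model 1 + blood-pressure and lipid medication, diabetes,
  hypertension, hypercholesterolemia, past cancer, and family history of
  MI, stroke and diabetes;
* **Model 2′** — Model 1 + past cancer and the family-history flags only
  (drops the potential mediators).

Mortality outcomes additionally adjust for the prevalent-CVD flags in the
adjusted models. Estimation is partial likelihood via lifelines with the
Efron tie approximation; follow-up time is the time scale (age is a
covariate, not the time scale); CIs are Wald on the log-HR scale,
p-values two-sided, and no multiple-testing correction is applied (the
number of fits is the caller's to track). Non-convergence raises with the
fitter's diagnostics; binary covariates whose events all fall in one
level are flagged for separation and the fit is ridge-stabilised
(penalty 0.01) so estimates remain reportable alongside the flag.

*Trend test.* The model is refit with the quintile index (1–5) as one
continuous covariate; the Wald p-value of its coefficient is reported.

*Substitution model.* Energy from less-healthy food, less-healthy
beverages and healthy beverages (each per 1,000 kJ/day) are fitted
alongside total energy (per 1,000 kJ/day, replacing the per-2,000-kJ
term). Holding total energy constant, the less-healthy-food coefficient
estimates the hazard of isocalorically replacing healthy food (the
omitted category) with less-healthy food. A rank-deficient set of energy
terms raises an error rather than silently dropping a column.

*PH diagnostics.* Scaled-Schoenfeld tests per covariate plus the
Grambsch–Therneau global chi-square, implemented from the Schoenfeld
residuals with a rank transform of event time by default (identity, log
and KM transforms available). The per-covariate statistics match
lifelines' `proportional_hazard_test` exactly; the global statistic is
u′Vu·d/Σĝ² with u = Σĝ_k s_k, V the coefficient covariance, d the event
count and ĝ the centred time transform. Fits with fewer than 10 events
skip the diagnostics with a warning. A residual-versus-time plot is
available from the results object.

## 5. Synthetic study generator (`npcohort.simulate`)

The generator emulates the data structure of a UK cohort of adults aged
40–79 recruited in the mid-1990s and followed ~16–20 years.

**Latent affinity.** Each participant carries a latent "less-healthy
affinity" a ~ N(0,1) that tilts both diet and covariates, planting the
confounding pattern seen in such cohorts: per SD of affinity, age +0.55 y,
log-odds of male +0.22, of current smoking +0.16, education latent −0.10,
alcohol consumption ×e^−0.42, daily energy +680 kJ — and, crucially, the
*inverse* clinical gradients that generate reverse causation: log-odds of
diabetes −0.43, lipid-lowering medication −0.70, antihypertensive
medication −0.07, hypertension −0.07, hypercholesterolemia −0.20, family
history of MI −0.055, BMI −0.29 kg/m² per SD, prevalent CVD −0.10.
Clinical flag prevalences also rise with age. Roughly 1.1% of
participants have one covariate set missing; 1.5% return no diary and
9.2% of diary completers record fewer than 7 days.

**Diaries (full path).** A catalogue of archetype items (fruit/veg,
staples, processed foods, sugary/diet/milk beverages, alcoholic drinks)
is drawn with per-100-g nutrient distributions that straddle the
less-healthy thresholds; the generator guarantees at least one
less-healthy food and beverage. Item selection is a per-person softmax
over archetypes tilted by affinity (processed +0.28, sugary beverages
+0.40, fruit/veg −0.35 per SD); portions are lognormal; each person's
grams are rescaled so daily energy matches a target of
N(8217 + 680·a, 1200) kJ. Alcoholic-drink selection follows reported
alcohol units.

**Cohort path.** For Monte Carlo studies where item-level diaries are
irrelevant, `generate_cohort` draws the person-level exposure directly:
logit(prop_lh_energy) ~ N(−0.12 + 0.35·a, 0.33), which reproduces the
same confounding with a realistic exposure range (roughly 0.25–0.9,
median near 0.47). A validation-only mode
(`independent_exposure_components=True`) instead draws the four energy
components from independent gamma distributions, giving the
component-wise variation needed to measure substitution-model recovery
precisely — with affinity-coupled components the estimate's Monte Carlo
error would swamp the planted effect.

**Outcomes.** Event times follow a Weibull proportional-hazards model
(shape 1 = exponential by default; other shapes exist to exercise the PH
diagnostics). The planted covariate log hazard ratios default to values
typical of CVD epidemiology (age 0.080/yr, female −0.654, never-smoker
−0.580, diabetes 0.637, …); the exposure effect defaults to **zero**, so
the generator's flagship configuration embodies a confounded null: the
unadjusted exposure association is spurious and vanishes under
adjustment. Baseline rates are calibrated marginally —
rate = target / mean(exp(linear predictor)) — against targets of 0.0132
incident-CVD events and 0.0175 deaths per person-year (≈36% of deaths
cardiovascular), sized to the event counts a cohort of ~23,000 over
~16 years would accrue. Censoring is administrative (horizon uniform on
18–22 years, emulating staggered entry with a fixed linkage end) plus
exponential dropout at 0.004/year. Incident CVD splits 62/38 into
MI/stroke; a fatal-within-30-days flag is carried as metadata but not
modelled. Survival times are floored at 1e-4 years so CSV rounding can
never produce a non-positive time. Every artefact is a pure function of
(config, seed); regeneration is byte-identical.

**What the generator does not emulate:** real food-composition
correlations beyond the archetype level, seasonal/weekday diary effects,
ICD-coded record linkage (outcomes carry pre-coded flags), informative
censoring, and measurement error in covariates. Passing validation
therefore demonstrates that the *pipeline machinery* is correct and
calibrated, not that any particular real-world association holds.

## 6. Validation studies (`npcohort.validation`)

Problem sizes were chosen to give decisive Monte Carlo evidence at
desk scale:

* **Scoring oracle** — 10,000 random compositions (with planted exact
  boundary values) must agree *exactly*, score and class, with a naively
  coded threshold-count oracle.
* **Cox recovery** — planted log HR 0.2, n = 5,000, 200 replicates:
  mean bias and 95% CI coverage.
* **Confounded-null calibration** — n = 4,000 per replicate, 200
  replicates, zero planted exposure effect with confounding planted
  through the Model-1 covariates: the unadjusted trend test inherits the
  confounded association (rejection well above 5%) while Model 1 and
  Model 2 stay nominal. Planting additional confounding through clinical
  flags outside Model 1's covariate set (as the default generator does)
  leaves Model 1 with genuine residual confounding and above-nominal
  rejection — that behaviour is the reverse-causation phenomenon itself
  and is deliberately excluded from the calibration study's design.
* **Substitution** — 15 replicate cohorts of n = 10,000 in the
  independent-components mode with an elevated baseline rate (0.03/yr,
  for event counts that make the per-1,000-kJ coefficient precise): a
  pure total-energy hazard must leave the substitution coefficient near
  zero, and a planted 0.1 per 1,000 kJ effect must be recovered.
* **PH diagnostics** — 100 replicates at n = 5,000: global-test size
  under exact PH, per-covariate power under a piecewise time-varying
  effect (log HR 0.8 before year 5, −0.3 after).
* **Determinism** — the full pipeline run twice from one (config, seed)
  must produce byte-identical files.

The same functions back `tests/test_acceptance.py` (fixed seeds) and
`scripts/acceptance.py` (caller's seed).

## 7. Known limitations

* The published cohort results themselves are not reproducible here —
  the real data are not public — so all quantitative claims are about
  planted-truth recovery and calibration.
* Weight-based exposure semantics (beverage weight in/out) follow a
  configuration switch because the underlying convention is ambiguous;
  the default includes beverage weight.
* The trim is not a fixpoint under re-application (re-trimming a trimmed
  sample removes new extremes); reproducibility is guaranteed for
  re-runs on the same input, which is the operative property.
* Model 1's residual-confounding behaviour under clinical-flag
  confounding is demonstrated, not "fixed": with such confounding only
  the fully adjusted model is calibrated, which is precisely the
  methodological point the pipeline is built to make executable.
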