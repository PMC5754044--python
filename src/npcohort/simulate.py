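"""Synthetic diet-diary cohort studies.

Generates a complete study bundle — food catalogue, 7-day diet diaries,
participant covariates and time-to-event outcomes — shaped like a
prospective UK cohort of adults aged 40-79 followed for roughly two
decades. The generator plants a known truth (covariate log hazard ratios,
an exposure effect that defaults to zero) and a confounding structure in
which participants who eat *less* of the "less-healthy" food are at
*higher* baseline cardiovascular risk (older medicated participants with
diabetes and higher BMI eating more carefully) — the reverse-causation
pattern that makes the unadjusted exposure-outcome association misleading
while the adjusted one is null.

Two generation paths share the same covariate and outcome machinery:

* the full path (:func:`generate_study`) draws item-level diaries from
  archetype mixtures (fruit/veg, staples, processed foods, sugary and diet
  beverages, milk drinks, alcoholic drinks) so that the scoring and
  aggregation stages run on realistic raw records;
* the cohort path (:func:`generate_cohort`) draws the person-level
  exposure measures directly from the same latent "less-healthy affinity",
  for Monte Carlo studies where diary-level detail is irrelevant.

Every artefact is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .exposure import assign_quintiles

# ---------------------------------------------------------------------------
# configuration


def _default_hazard_betas() -> dict:
    """Planted covariate log hazard ratios (per-unit, on the natural
    covariate scale; continuous covariates are mean-centred internally)."""
    return {
        "age": 0.080, "female": -0.654,
        "smoking_former": -0.462, "smoking_never": -0.580,
        "activity_1": -0.151, "activity_2": -0.139, "activity_3": -0.151,
        "education_1": -0.186, "education_2": -0.128, "education_3": -0.261,
        "alcohol_units": -0.010, "energy_2000": -0.051,
        "bp_medication": 0.300, "lipid_medication": -0.248,
        "past_cancer": 0.174, "diabetes": 0.637, "hypertension": 0.207,
        "hypercholesterolemia": 0.307,
        "fh_mi": 0.174, "fh_stroke": 0.068, "fh_diabetes": 0.086,
    }


@dataclass
class GeneratorConfig:
    """Study-generator parameters.

    Confounding coefficients (``conf_*``) are per standard deviation of the
    latent less-healthy-affinity score; their default signs and magnitudes
    emulate the baseline gradients of a UK cohort in which high consumers
    of less-healthy food are older, more often male, less educated, more
    often current smokers, drink less alcohol, eat more energy, and are
    *less* likely to be on medication or diabetic (the inverse gradient
    driving reverse causation).
    """

    n_participants: int = 25_000
    n_items: int = 60
    diary_days: int = 7
    frac_partial_diary: float = 0.092   # complete fewer than 7 days
    frac_no_diary: float = 0.015        # no diary at all (excluded upstream)

    # covariate marginals
    age_mean: float = 58.6
    age_sd: float = 9.2
    p_male: float = 0.435
    bmi_mean: float = 26.3
    bmi_sd: float = 3.9
    alcohol_mean: float = 1.51
    missing_rate: float = 0.011

    # confounding: covariate response per SD of affinity
    conf_age: float = 0.55
    conf_male: float = 0.22
    conf_education: float = -0.10
    conf_smoking: float = 0.16
    conf_activity: float = 0.0
    conf_alcohol: float = -0.42
    conf_diabetes: float = -0.43
    conf_bp_medication: float = -0.07
    conf_lipid_medication: float = -0.70
    conf_hypertension: float = -0.07
    conf_hypercholesterolemia: float = -0.20
    conf_fh_mi: float = -0.055
    conf_bmi: float = -0.29
    conf_prevalent_cvd: float = -0.10
    conf_energy: float = 680.0          # kJ/day per SD of affinity

    # diary model
    items_per_day_mean: float = 11.0
    energy_target_mean: float = 8217.0  # kJ/day
    energy_target_sd: float = 1200.0

    #: draw the exposure component energies from independent distributions
    #: instead of coupling them through the latent affinity; used to
    #: validate component-wise estimators (e.g. the substitution model)
    #: where collinearity would otherwise dominate the Monte Carlo error
    independent_exposure_components: bool = False

    # planted outcome model
    hazard_betas: dict = field(default_factory=_default_hazard_betas)
    exposure_log_hr_per_quintile: float = 0.0
    prevalent_cvd_log_hr: float = 0.50  # mortality processes only
    baseline_cvd_rate: float = 0.0132   # events / person-year, calibrated
    baseline_death_rate: float = 0.0175
    cvd_death_fraction: float = 0.358
    weibull_shape: float = 1.0
    horizon_min_years: float = 18.0
    horizon_max_years: float = 22.0
    dropout_rate: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_partial_diary", "frac_no_diary", "missing_rate",
                     "cvd_death_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0,1], got {v}")
        if self.horizon_max_years <= 0 or self.horizon_min_years <= 0:
            raise ConfigurationError("follow-up horizon must be positive")
        if self.baseline_cvd_rate < 0 or self.baseline_death_rate < 0:
            raise ValidationError("baseline hazard rates must be non-negative")
        if self.weibull_shape <= 0:
            raise ConfigurationError("weibull_shape must be positive")
        if self.n_items < 7:
            raise ConfigurationError("need at least 7 items (one per archetype)")


@dataclass
class SyntheticStudy:
    """Full generated bundle plus the planted truth."""

    catalogue: pd.DataFrame
    diaries: pd.DataFrame
    participants: pd.DataFrame
    outcomes: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# catalogue

# archetype: (item_class, share, nutrient mean/sd per 100 g, portion grams)
_ARCHETYPES = {
    "fruit_veg":  dict(item_class="food", share=0.20, portion=(90, 0.4),
                       energy=(250, 90), satfat=(0.1, 0.1), sugars=(7, 3),
                       sodium=(15, 10), fibre=(2.2, 0.7), protein=(1.5, 0.6),
                       fvn=(95, 5), fv=True),
    "staple":     dict(item_class="food", share=0.23, portion=(120, 0.4),
                       energy=(1050, 320), satfat=(1.0, 0.7), sugars=(3, 1.5),
                       sodium=(280, 160), fibre=(2.4, 0.9), protein=(6, 2),
                       fvn=(8, 8), fv=False),
    "processed":  dict(item_class="food", share=0.27, portion=(80, 0.45),
                       energy=(1750, 420), satfat=(7, 3), sugars=(16, 9),
                       sodium=(520, 220), fibre=(1.2, 0.6), protein=(7, 3),
                       fvn=(8, 10), fv=False),
    "sugary_bev": dict(item_class="beverage", share=0.08, portion=(250, 0.3),
                       energy=(185, 25), satfat=(0.0, 0.01), sugars=(10, 1.5),
                       sodium=(12, 8), fibre=(0.0, 0.01), protein=(0.1, 0.1),
                       fvn=(2, 4), fv=False),
    "diet_bev":   dict(item_class="beverage", share=0.06, portion=(250, 0.3),
                       energy=(25, 18), satfat=(0.0, 0.01), sugars=(0.7, 0.6),
                       sodium=(10, 6), fibre=(0.0, 0.01), protein=(0.1, 0.1),
                       fvn=(1, 2), fv=False),
    "milk_bev":   dict(item_class="beverage", share=0.06, portion=(200, 0.3),
                       energy=(230, 40), satfat=(1.6, 0.6), sugars=(4.8, 0.5),
                       sodium=(44, 8), fibre=(0.0, 0.01), protein=(3.4, 0.3),
                       fvn=(0, 1), fv=False),
    "alcoholic":  dict(item_class="alcoholic_beverage", share=0.10,
                       portion=(220, 0.35),
                       energy=(210, 80), satfat=(0.0, 0.01), sugars=(2, 2),
                       sodium=(8, 6), fibre=(0.0, 0.01), protein=(0.3, 0.3),
                       fvn=(0, 1), fv=False),
}


def _truncated_normal(rng, mean, sd, size, low=0.0, high=np.inf):
    x = rng.normal(mean, sd, size)
    return np.clip(x, low, high)


def generate_catalogue(config: GeneratorConfig,
                       seed: int | None = None) -> pd.DataFrame:
    """Draw a food-composition catalogue from the archetype mixture.

    Guarantees (for n_items >= 20, by construction of the processed and
    sugary-beverage archetypes) at least one less-healthy food and one
    less-healthy beverage.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    names = list(_ARCHETYPES)
    shares = np.array([_ARCHETYPES[a]["share"] for a in names])
    counts = np.maximum(1, np.round(shares / shares.sum()
                                    * config.n_items).astype(int))
    # adjust the largest archetype so counts sum to n_items
    counts[counts.argmax()] += config.n_items - counts.sum()

    rows = []
    i = 0
    for aname, k in zip(names, counts):
        a = _ARCHETYPES[aname]
        for _ in range(k):
            comp = {
                "energy_kj": _truncated_normal(rng, *a["energy"], None),
                "satfat_g": _truncated_normal(rng, *a["satfat"], None),
                "sugars_g": _truncated_normal(rng, *a["sugars"], None),
                "sodium_mg": _truncated_normal(rng, *a["sodium"], None),
                "fibre_g": _truncated_normal(rng, *a["fibre"], None),
                "protein_g": _truncated_normal(rng, *a["protein"], None),
                "fvn_pct": float(np.clip(rng.normal(*a["fvn"]), 0, 100)),
            }
            rows.append({
                "item_id": f"I{i:04d}", "name": f"{aname}_{i}",
                "item_class": a["item_class"], "archetype": aname,
                **{k2: round(float(v), 3) for k2, v in comp.items()},
                "fv_frac": round(comp["fvn_pct"] / 100.0, 4) if a["fv"] else 0.0,
                "portion_g": a["portion"][0],
                "portion_sigma": a["portion"][1],
            })
            i += 1
    cat = pd.DataFrame(rows)

    # coverage guarantee: nudge one item per side of each threshold if the
    # random draw happened to miss a class entirely
    from .scoring import score_catalogue
    scored = score_catalogue(cat.drop(columns=["archetype", "fv_frac",
                                               "portion_g", "portion_sigma"]))
    merged = cat.assign(classification=scored["classification"].to_numpy())
    lh_food = ((merged["item_class"] == "food")
               & (merged["classification"] == "less_healthy")).any()
    lh_bev = ((merged["item_class"] == "beverage")
              & (merged["classification"] == "less_healthy")).any()
    if not lh_food:
        j = cat.index[cat["archetype"] == "processed"][0]
        cat.loc[j, ["energy_kj", "satfat_g", "sugars_g", "sodium_mg"]] = \
            (2000.0, 9.0, 25.0, 700.0)
    if not lh_bev:
        j = cat.index[cat["archetype"] == "sugary_bev"][0]
        cat.loc[j, "sugars_g"] = 10.5
    return cat


# ---------------------------------------------------------------------------
# participants

_EDU_CUTS = (-0.52, 0.28, 1.11)     # -> levels 0..3, degree ~13%
_SMOKE_BASE = -2.02                 # logit of current smoking ~11.8%


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _draw_participants(config: GeneratorConfig, rng,
                       affinity: np.ndarray) -> pd.DataFrame:
    n = affinity.size
    c = config
    age = np.clip(rng.normal(c.age_mean + c.conf_age * affinity, c.age_sd),
                  40.0, 79.0)
    male = rng.random(n) < _logistic(
        np.log(c.p_male / (1 - c.p_male)) + c.conf_male * affinity)
    sex = np.where(male, "male", "female")

    edu_latent = rng.normal(c.conf_education * affinity, 1.0)
    education = np.digitize(edu_latent, _EDU_CUTS).astype(float)

    current = rng.random(n) < _logistic(_SMOKE_BASE + c.conf_smoking * affinity)
    former = (~current) & (rng.random(n) < 0.45)
    smoking = np.where(current, "current", np.where(former, "former", "never"))

    act_latent = rng.normal(c.conf_activity * affinity, 1.0)
    activity = np.digitize(act_latent, (-0.67, 0.10, 0.88)).astype(float)

    alc_scale = np.exp(c.conf_alcohol * affinity)
    alc_scale /= np.exp(0.5 * c.conf_alcohol ** 2)   # E[exp(bA)] for A~N(0,1)
    alcohol_units = rng.gamma(1.2, c.alcohol_mean / 1.2, n) * alc_scale

    def flag(prevalence, coef, extra=0.0):
        base = np.log(prevalence / (1 - prevalence))
        return (rng.random(n) < _logistic(base + coef * affinity + extra)) \
            .astype(int)

    bmi = np.clip(rng.normal(c.bmi_mean + c.conf_bmi * affinity, c.bmi_sd),
                  16, 50)
    height = np.where(male, rng.normal(1.74, 0.07, n),
                      rng.normal(1.61, 0.06, n))
    weight_kg = np.round(bmi * height ** 2, 1)

    age_dev = (age - c.age_mean) / c.age_sd
    df = pd.DataFrame({
        "participant_id": [f"P{i:06d}" for i in range(n)],
        "affinity": affinity,
        "age": np.round(age, 1), "sex": sex, "weight_kg": weight_kg,
        "bmi": np.round(bmi, 2),
        "education": education, "smoking": smoking, "activity": activity,
        "alcohol_units": np.round(alcohol_units, 2),
        "bp_medication": flag(0.149, c.conf_bp_medication, 0.45 * age_dev),
        "lipid_medication": flag(0.009, c.conf_lipid_medication,
                                 0.30 * age_dev),
        "diabetes": flag(0.019, c.conf_diabetes, 0.25 * age_dev),
        "hypertension": flag(0.20, c.conf_hypertension, 0.45 * age_dev),
        "hypercholesterolemia": flag(0.07, c.conf_hypercholesterolemia,
                                     0.25 * age_dev),
        "past_cancer": flag(0.054, 0.0, 0.30 * age_dev),
        "fh_mi": flag(0.356, c.conf_fh_mi),
        "fh_stroke": flag(0.16, 0.0),
        "fh_diabetes": flag(0.12, 0.0),
        "angina": flag(0.05, c.conf_prevalent_cvd, 0.55 * age_dev),
        "heart_attack": flag(0.031, c.conf_prevalent_cvd, 0.55 * age_dev),
        "stroke": flag(0.015, c.conf_prevalent_cvd, 0.55 * age_dev),
    })

    # sprinkle missing covariates over a small random subset
    if c.missing_rate > 0:
        miss = rng.random(n) < c.missing_rate
        which = rng.integers(0, 3, n)
        df.loc[miss & (which == 0), "education"] = np.nan
        df.loc[miss & (which == 1), "alcohol_units"] = np.nan
        df.loc[miss & (which == 2), "activity"] = np.nan
    return df


# ---------------------------------------------------------------------------
# diaries (full path)

_ARCH_TILT = {"fruit_veg": -0.35, "staple": 0.05, "processed": 0.28,
              "sugary_bev": 0.40, "diet_bev": -0.10, "milk_bev": 0.0,
              "alcoholic": 0.0}
_ARCH_BASE = {"fruit_veg": 1.25, "staple": 1.15, "processed": 1.0,
              "sugary_bev": -0.8, "diet_bev": -1.3, "milk_bev": -0.6,
              "alcoholic": -1.3}


def generate_participants_and_diaries(config: GeneratorConfig,
                                      catalogue: pd.DataFrame,
                                      seed: int | None = None):
    """Draw participants and their item-level 7-day diaries.

    Item selection is a per-person softmax over archetypes tilted by the
    latent affinity (processed food and sugary beverages up, fruit/veg
    down); alcoholic-drink propensity follows reported alcohol units.
    Per-person daily energy is rescaled to a target that increases with
    affinity, so the cohort shows the energy gradient alongside the
    less-healthy-share gradient.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    n = config.n_participants
    affinity = rng.normal(0.0, 1.0, n)
    participants = _draw_participants(config, rng, affinity)

    days = np.full(n, config.diary_days)
    partial = rng.random(n) < config.frac_partial_diary
    days[partial] = rng.integers(1, config.diary_days, partial.sum())
    days[rng.random(n) < config.frac_no_diary] = 0

    arch_names = list(_ARCHETYPES)
    n_arch = len(arch_names)
    arch_of_item = catalogue["archetype"].to_numpy()
    items_by_arch = {a: np.flatnonzero(arch_of_item == a) for a in arch_names}

    alc_units = participants["alcohol_units"].fillna(
        config.alcohol_mean).to_numpy()
    logw = np.empty((n, n_arch))
    for j, a in enumerate(arch_names):
        logw[:, j] = _ARCH_BASE[a] + _ARCH_TILT[a] * affinity
    # alcoholic propensity scales with reported units
    logw[:, arch_names.index("alcoholic")] = np.log1p(alc_units) - 1.3

    n_items_pd = rng.poisson(config.items_per_day_mean, n).clip(min=4)
    rows_per_p = days * n_items_pd
    pidx = np.repeat(np.arange(n), rows_per_p)
    total = pidx.size

    day_idx = np.concatenate(
        [np.repeat(np.arange(1, d + 1), k) for d, k in zip(days, n_items_pd)])

    # Gumbel-max archetype draw per row with per-person weights
    gumbel = -np.log(-np.log(rng.random((total, n_arch))))
    arch_rows = (logw[pidx] + gumbel).argmax(axis=1)

    item_idx = np.empty(total, dtype=int)
    for j, a in enumerate(arch_names):
        m = arch_rows == j
        pool = items_by_arch[a]
        item_idx[m] = pool[rng.integers(0, pool.size, m.sum())]

    portion_mu = catalogue["portion_g"].to_numpy()[item_idx]
    portion_sig = catalogue["portion_sigma"].to_numpy()[item_idx]
    grams = portion_mu * np.exp(rng.normal(0.0, 1.0, total) * portion_sig
                                - portion_sig ** 2 / 2)

    # rescale each participant's grams so daily energy hits the target
    energy_row = grams * catalogue["energy_kj"].to_numpy()[item_idx] / 100.0
    raw_daily = np.divide(np.bincount(pidx, energy_row, minlength=n), days,
                          out=np.zeros(n), where=days > 0)
    target = np.clip(
        rng.normal(config.energy_target_mean
                   + config.conf_energy * affinity,
                   config.energy_target_sd), 3500.0, None)
    factor = target / np.where(raw_daily > 0, raw_daily, 1.0)
    grams *= factor[pidx]

    diaries = pd.DataFrame({
        "participant_id": participants["participant_id"].to_numpy()[pidx],
        "day_index": day_idx,
        "item_id": catalogue["item_id"].to_numpy()[item_idx],
        "grams": np.round(grams, 2),
    })
    diaries = diaries[diaries["grams"] > 0].reset_index(drop=True)
    return participants, diaries


# ---------------------------------------------------------------------------
# outcomes

def _linear_predictor(participants: pd.DataFrame, exposures: pd.DataFrame,
                      betas: dict, include_prevalent: bool,
                      prevalent_beta: float) -> np.ndarray:
    p = participants
    e = exposures.set_index("participant_id").reindex(p["participant_id"])
    x = {
        "age": p["age"].to_numpy(dtype=float),
        "female": (p["sex"] == "female").to_numpy(dtype=float),
        "smoking_former": (p["smoking"] == "former").to_numpy(dtype=float),
        "smoking_never": (p["smoking"] == "never").to_numpy(dtype=float),
        "alcohol_units": p["alcohol_units"].fillna(0).to_numpy(dtype=float),
        "energy_2000": e["energy_total"].to_numpy(dtype=float) / 2000.0,
        # exposure components, for planting substitution-type effects
        "e_lh_food_1000": e["energy_lh_food"].to_numpy(dtype=float) / 1000.0,
        "e_lh_bev_1000": e["energy_lh_bev"].to_numpy(dtype=float) / 1000.0,
        "e_healthy_bev_1000":
            e["energy_healthy_bev"].to_numpy(dtype=float) / 1000.0,
        "e_total_1000": e["energy_total"].to_numpy(dtype=float) / 1000.0,
    }
    for k in (1, 2, 3):
        x[f"education_{k}"] = (p["education"] == k).to_numpy(dtype=float)
        x[f"activity_{k}"] = (p["activity"] == k).to_numpy(dtype=float)
    for c in ("bp_medication", "lipid_medication", "diabetes", "hypertension",
              "hypercholesterolemia", "past_cancer", "fh_mi", "fh_stroke",
              "fh_diabetes"):
        x[c] = p[c].to_numpy(dtype=float)
    lin = np.zeros(len(p))
    for name, b in betas.items():
        if name in x:
            v = x[name]
            lin += b * (v - v.mean())     # centred: baseline = typical person
    if include_prevalent:
        prev = (p[["angina", "heart_attack", "stroke"]].to_numpy(dtype=float)
                .max(axis=1))
        lin += prevalent_beta * (prev - prev.mean())
    return lin


def _event_times(rng, rate0, lin, shape, n):
    """Weibull PH event times: S(t) = exp(-rate0 * exp(lin) * t^shape)."""
    u = rng.exponential(1.0, n)
    return (u / (rate0 * np.exp(lin))) ** (1.0 / shape)


def simulate_outcomes(participants: pd.DataFrame, exposures: pd.DataFrame,
                      config: GeneratorConfig,
                      seed: int | None = None) -> pd.DataFrame:
    """Planted proportional-hazards outcomes with independent censoring.

    Baseline rates are calibrated so that the *marginal* event rates match
    the configured targets: rate0 = target / mean(exp(linear predictor)).
    The exposure effect (default zero) enters per quintile of the
    less-healthy energy share, centred at the median group.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    n = len(participants)
    c = config

    lin_cvd = _linear_predictor(participants, exposures, c.hazard_betas,
                                include_prevalent=False,
                                prevalent_beta=0.0)
    lin_death = _linear_predictor(participants, exposures, c.hazard_betas,
                                  include_prevalent=True,
                                  prevalent_beta=c.prevalent_cvd_log_hr)
    if c.exposure_log_hr_per_quintile != 0.0:
        prop = exposures.set_index("participant_id") \
            .reindex(participants["participant_id"])["prop_lh_energy"] \
            .to_numpy(dtype=float)
        q, _ = assign_quintiles(prop, participants["participant_id"])
        expo = c.exposure_log_hr_per_quintile * (q - 3.0)
        lin_cvd = lin_cvd + expo
        lin_death = lin_death + expo

    rate_cvd = c.baseline_cvd_rate / np.exp(lin_cvd).mean()
    rate_death = c.baseline_death_rate / np.exp(lin_death).mean()

    t_cvd = _event_times(rng, rate_cvd, lin_cvd, c.weibull_shape, n)
    t_death = _event_times(rng, rate_death, lin_death, c.weibull_shape, n)

    horizon = rng.uniform(c.horizon_min_years, c.horizon_max_years, n)
    if c.dropout_rate > 0:
        horizon = np.minimum(horizon, rng.exponential(1.0 / c.dropout_rate, n))
    horizon = np.maximum(horizon, 1e-4)

    cvd_event = (t_cvd <= horizon).astype(int)
    # floor at ~1 hour so rounding can never produce a non-positive time
    cvd_time = np.maximum(np.minimum(t_cvd, horizon), 1e-4)
    death_event = (t_death <= horizon).astype(int)
    death_time = np.maximum(np.minimum(t_death, horizon), 1e-4)

    is_cvd_death = (death_event == 1) & \
        (rng.random(n) < c.cvd_death_fraction)
    is_mi = rng.random(n) < 0.62     # split of incident CVD events

    out = pd.DataFrame({
        "participant_id": participants["participant_id"].to_numpy(),
        "incident_cvd_event": cvd_event,
        "incident_cvd_time": np.round(cvd_time, 4),
        "all_cause_mortality_event": death_event,
        "all_cause_mortality_time": np.round(death_time, 4),
        "cvd_mortality_event": (death_event * is_cvd_death).astype(int),
        "cvd_mortality_time": np.round(death_time, 4),
        "incident_mi_event": (cvd_event * is_mi).astype(int),
        "incident_mi_time": np.round(np.where(cvd_event & is_mi,
                                              cvd_time, horizon), 4),
        "incident_stroke_event": (cvd_event * ~is_mi).astype(int),
        "incident_stroke_time": np.round(np.where(cvd_event & ~is_mi,
                                                  cvd_time, horizon), 4),
        "fatal_30d": (cvd_event
                      & (np.abs(death_time - cvd_time) <= 30 / 365.25)
                      & (death_event == 1)).astype(int),
    })
    return out


# ---------------------------------------------------------------------------
# cohort-level fast path

def generate_cohort(config: GeneratorConfig, seed: int | None = None):
    """Participants + person-level exposures without item-level diaries.

    The less-healthy energy share is drawn on the logit scale from the same
    latent affinity that drives the covariates (plus independent noise), so
    the confounding structure is identical to the full diary path; marginal
    ranges mirror a realistic cohort (share roughly 0.25-0.9, median near
    0.47).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 3)
    n = config.n_participants
    affinity = rng.normal(0.0, 1.0, n)
    participants = _draw_participants(config, rng, affinity)

    alcohol = participants["alcohol_units"].fillna(0).to_numpy()
    if config.independent_exposure_components:
        # independent gammas sized to realistic per-day energies (kJ)
        def gamma(mean, sd):
            shape = (mean / sd) ** 2
            return rng.gamma(shape, mean / shape, n)
        e_lh_food = gamma(3700.0, 1500.0)
        e_lh_bev = gamma(220.0, 300.0)
        e_h_food = gamma(3400.0, 1000.0)
        e_h_bev = gamma(350.0, 250.0)
        energy_alc = alcohol * 290.0
        e_lh = e_lh_food + e_lh_bev
        e_h = e_h_food + e_h_bev
        nonalc = e_lh + e_h
        energy_total = nonalc + energy_alc
        prop = e_lh / nonalc
    else:
        energy_total = np.clip(
            rng.normal(config.energy_target_mean
                       + config.conf_energy * affinity,
                       config.energy_target_sd), 3500.0, None)
        energy_alc = np.minimum(alcohol * 290.0, 0.35 * energy_total)
        prop = _logistic(rng.normal(-0.12 + 0.35 * affinity, 0.33))
        nonalc = energy_total - energy_alc
        e_lh = prop * nonalc
        bev_share = np.clip(rng.normal(0.055 + 0.03 * affinity, 0.03),
                            0.0, 0.4)
        e_lh_bev = e_lh * bev_share
        e_h = nonalc - e_lh
        e_h_bev = e_h * np.clip(rng.normal(0.10, 0.04, n), 0.0, 0.5)
        e_lh_food = e_lh - e_lh_bev
        e_h_food = e_h - e_h_bev

    weight_total = np.clip(rng.normal(2450.0, 450.0, n), 800.0, None)
    prop_w = np.clip(prop * rng.normal(0.52, 0.06, n), 0.0, 1.0)
    fv_weight = np.clip(rng.normal(325.0 - 47.0 * affinity, 120.0), 0.0, None)
    score = np.clip(6.91 + 1.95 * affinity + rng.normal(0, 0.9, n), -5, 25)

    days = np.full(n, config.diary_days)
    partial = rng.random(n) < config.frac_partial_diary
    days[partial] = rng.integers(1, config.diary_days, partial.sum())

    exposures = pd.DataFrame({
        "participant_id": participants["participant_id"],
        "n_diary_days": days,
        "energy_lh_food": e_lh_food,
        "energy_lh_bev": e_lh_bev,
        "energy_healthy_food": e_h_food,
        "energy_healthy_bev": e_h_bev,
        "energy_healthy": e_h,
        "energy_alcoholic": energy_alc,
        "energy_total": energy_total,
        "weight_lh": prop_w * weight_total,
        "weight_total": weight_total,
        "fv_weight": fv_weight,
        "prop_lh_energy": prop,
        "prop_lh_weight": prop_w,
        "mean_weighted_score": score,
    })
    return participants, exposures


# ---------------------------------------------------------------------------
# small planted-truth survival datasets for calibration studies

def simulate_cox_dataset(n: int, betas: dict | float = 0.2,
                         baseline_rate: float = 0.05, shape: float = 1.0,
                         censor_low: float = 5.0, censor_high: float = 20.0,
                         seed: int = 0) -> pd.DataFrame:
    """Exact-PH dataset: standard-normal covariates with known log HRs.

    ``betas`` is either a single coefficient (one covariate ``x1``) or a
    name->log-HR dict. Returns columns [covariates..., time, event].
    """
    rng = np.random.default_rng(seed)
    if not isinstance(betas, dict):
        betas = {"x1": float(betas)}
    X = {name: rng.normal(size=n) for name in betas}
    lin = sum(b * X[name] for name, b in betas.items())
    t = _event_times(rng, baseline_rate, lin, shape, n)
    c = rng.uniform(censor_low, censor_high, n)
    df = pd.DataFrame(X)
    df["time"] = np.minimum(t, c)
    df["event"] = (t <= c).astype(int)
    return df


def simulate_nonph_dataset(n: int, beta_early: float = 0.8,
                           beta_late: float = -0.3,
                           change_time: float = 5.0,
                           baseline_rate: float = 0.05,
                           censor_low: float = 5.0,
                           censor_high: float = 20.0,
                           seed: int = 0) -> pd.DataFrame:
    """Planted time-varying effect: covariate ``x1`` has log HR
    ``beta_early`` before ``change_time`` and ``beta_late`` after
    (piecewise-exponential inverse-CDF simulation)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    r1 = baseline_rate * np.exp(beta_early * x)
    r2 = baseline_rate * np.exp(beta_late * x)
    e = rng.exponential(1.0, n)
    t = np.where(e < r1 * change_time, e / r1,
                 change_time + (e - r1 * change_time) / r2)
    c = rng.uniform(censor_low, censor_high, n)
    return pd.DataFrame({"x1": x, "time": np.minimum(t, c),
                         "event": (t <= c).astype(int)})


# ---------------------------------------------------------------------------
# bundle

def generate_study(config: GeneratorConfig, seed: int | None = None,
                   out_dir=None) -> SyntheticStudy:
    """Compose catalogue, diaries, participants and outcomes (full path).

    When ``out_dir`` is given, writes ``catalogue.csv``, ``diary.csv``,
    ``participants.csv``, ``outcomes.csv``, ``truth.json`` and
    ``config.json`` there.
    """
    from .exposure import build_exposures
    from .scoring import score_catalogue

    base_seed = config.seed if seed is None else seed
    catalogue = generate_catalogue(config, base_seed)
    participants, diaries = generate_participants_and_diaries(
        config, catalogue, base_seed)
    scored = score_catalogue(
        catalogue[[c for c in catalogue.columns
                   if c not in ("archetype", "fv_frac", "portion_g",
                                "portion_sigma")]])
    exposures = build_exposures(diaries, scored, catalogue)
    # participants with no diary rows never reach build_exposures; keep them
    # in the bundle (the exclusion cascade removes them with a logged step)
    outcomes = simulate_outcomes(
        participants,
        exposures.merge(participants[["participant_id"]], how="right",
                        on="participant_id").fillna(
            {"energy_total": config.energy_target_mean,
             "prop_lh_energy": 0.5}),
        config, base_seed)

    truth = {
        "schema_version": 1,
        "seed": int(base_seed),
        "hazard_betas": config.hazard_betas,
        "exposure_log_hr_per_quintile": config.exposure_log_hr_per_quintile,
        "prevalent_cvd_log_hr": config.prevalent_cvd_log_hr,
        "baseline_cvd_rate": config.baseline_cvd_rate,
        "baseline_death_rate": config.baseline_death_rate,
        "weibull_shape": config.weibull_shape,
    }
    study = SyntheticStudy(catalogue=catalogue, diaries=diaries,
                           participants=participants, outcomes=outcomes,
                           truth=truth)
    if out_dir is not None:
        write_study(study, config, out_dir)
    return study


def write_study(study: SyntheticStudy, config: GeneratorConfig,
                out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.catalogue.to_csv(out / "catalogue.csv", index=False)
    study.diaries.to_csv(out / "diary.csv", index=False)
    study.participants.to_csv(out / "participants.csv", index=False)
    study.outcomes.to_csv(out / "outcomes.csv", index=False)
    (out / "truth.json").write_text(json.dumps(study.truth, indent=2,
                                               sort_keys=True))
    cfg = dataclasses.asdict(config)
    (out / "config.json").write_text(json.dumps(cfg, indent=2,
                                                sort_keys=True))
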