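"""Cohort exclusion cascade.

Order of exclusions, fixed and logged:

1. no diary day (fewer than one completed diary day);
2. energy misreporting: trim the top and bottom 0.5% of the ratio of
   reported energy intake to Schofield-predicted basal metabolic rate;
3. prevalent cardiovascular disease (self-reported angina, heart attack or
   stroke) — applied only for the incident-CVD analysis, not for mortality;
4. missing covariates (dropped, not imputed).

Optional sensitivity exclusions drop baseline comorbidities, family history
of CVD, and early events (landmark analysis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputDomainError, ValidationError

logger = logging.getLogger(__name__)

#: Covariates whose missingness excludes a participant (the fully adjusted
#: covariate set; clinical flags and family history included).
COVARIATE_COLUMNS = [
    "age", "sex", "education", "smoking", "activity", "alcohol_units",
    "bp_medication", "lipid_medication", "diabetes", "hypertension",
    "hypercholesterolemia", "past_cancer", "fh_mi", "fh_stroke",
    "fh_diabetes",
]

PREVALENT_CVD_COLUMNS = ["angina", "heart_attack", "stroke"]

COMORBID_CLINICAL = ["hypertension", "hypercholesterolemia",
                     "bp_medication", "lipid_medication"]
COMORBID_OTHER = ["diabetes", "past_cancer"]


@dataclass
class ExclusionLog:
    """Ordered audit of the cascade: (step, n_before, n_excluded, n_after)."""

    steps: list = field(default_factory=list)

    def record(self, step: str, n_before: int, n_after: int) -> None:
        assert 0 <= n_after <= n_before
        self.steps.append((step, n_before, n_before - n_after, n_after))
        logger.info("exclusion %-28s %6d -> %6d (-%d)",
                    step, n_before, n_after, n_before - n_after)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps,
            columns=["step", "n_before", "n_excluded", "n_after"])

    def validate_chain(self) -> bool:
        f = self.to_frame()
        ok = (f["n_after"] == f["n_before"] - f["n_excluded"]).all()
        if len(f) > 1:
            ok &= (f["n_before"].to_numpy()[1:] == f["n_after"].to_numpy()[:-1]).all()
        return bool(ok)


def _load_schofield() -> dict:
    ref = resources.files("npcohort.data") / "schofield.yaml"
    return yaml.safe_load(ref.read_text())


_SCHOFIELD = None


def schofield_bmr(sex, age, weight_kg, coefficients: dict | None = None):
    """Schofield basal metabolic rate in MJ/day.

    Piecewise-linear in weight with sex-specific coefficients over age bands
    18-29, 30-59, 60+. Accepts scalars or aligned arrays.
    """
    global _SCHOFIELD
    if coefficients is None:
        if _SCHOFIELD is None:
            _SCHOFIELD = _load_schofield()
        coefficients = _SCHOFIELD

    sex_a = np.asarray(sex, dtype=object)
    age_a = np.asarray(age, dtype=float)
    w_a = np.asarray(weight_kg, dtype=float)
    scalar = sex_a.ndim == 0
    sex_a, age_a, w_a = np.atleast_1d(sex_a), np.atleast_1d(age_a), np.atleast_1d(w_a)

    if np.any(age_a < 18):
        raise InputDomainError("Schofield equations require age >= 18")
    if np.any(~(w_a > 0)):
        raise InputDomainError("weight_kg must be positive")
    bad_sex = ~np.isin(sex_a, ("male", "female"))
    if np.any(bad_sex):
        raise ConfigurationError(
            f"unknown sex labels: {sorted(set(sex_a[bad_sex]))}")

    bmr = np.full(w_a.shape, np.nan)
    for s in ("male", "female"):
        for band in coefficients[s]:
            # bands are closed integer ranges; continuous ages in the gap
            # (e.g. 59.4) belong to the band containing their floor
            m = (sex_a == s) & (age_a >= band["age_min"]) \
                & (age_a < band["age_max"] + 1)
            bmr[m] = band["slope"] * w_a[m] + band["intercept"]
    if np.isnan(bmr).any():
        raise ConfigurationError("age outside all configured Schofield bands")
    return float(bmr[0]) if scalar else bmr


def energy_bmr_ratio(energy_total_kj, bmr_mj) -> np.ndarray:
    """Reported energy intake (kJ/day) over BMR, both in MJ/day."""
    return np.asarray(energy_total_kj, dtype=float) / 1000.0 / np.asarray(bmr_mj, dtype=float)


def energy_bmr_trim(ratios, trim_fraction: float = 0.005,
                    min_n: int = 200) -> np.ndarray:
    """Boolean keep-mask trimming the extreme tails of the energy:BMR ratio.

    With k = floor(n * trim_fraction), the retained range is
    [x(k+1), x(n-k)] (order statistics); values strictly outside are
    removed. With distinct values this removes exactly k per tail; with
    heavy ties (e.g. all equal) nothing is removed.
    """
    r = np.asarray(ratios, dtype=float)
    n = r.size
    if not np.isfinite(r).all() or np.any(r <= 0):
        raise ValidationError("energy:BMR ratios must be finite and positive")
    if trim_fraction == 0:
        return np.ones(n, dtype=bool)
    if n < min_n:
        warnings.warn(f"n={n} too small for {trim_fraction:.3%} trimming; "
                      "no participants removed")
        return np.ones(n, dtype=bool)
    k = int(np.floor(n * trim_fraction))
    if k == 0:
        return np.ones(n, dtype=bool)
    srt = np.sort(r)
    lo, hi = srt[k], srt[n - k - 1]
    return (r >= lo) & (r <= hi)


def apply_exclusions(participants: pd.DataFrame, exposures: pd.DataFrame,
                     analysis: str = "cvd",
                     outcomes: pd.DataFrame | None = None,
                     outcome: str | None = None,
                     trim_fraction: float = 0.005,
                     landmark_years: float | None = None,
                     drop_comorbid_clinical: bool = False,
                     drop_comorbid_other: bool = False,
                     drop_fh_cvd: bool = False,
                     drop_fh_diabetes: bool = False,
                     covariates: Sequence[str] = COVARIATE_COLUMNS):
    """Run the exclusion cascade; returns (cohort DataFrame, ExclusionLog).

    ``analysis`` is ``"cvd"`` (prevalent CVD excluded) or ``"mortality"``
    (prevalent CVD retained, adjusted for downstream). The landmark option
    needs ``outcomes``/``outcome`` to identify early events.
    """
    if analysis not in ("cvd", "mortality"):
        raise ConfigurationError(f"unknown analysis label {analysis!r}")

    log = ExclusionLog()
    df = participants.merge(exposures, on="participant_id", how="left",
                            validate="one_to_one")

    # 1. at least one diary day
    n0 = len(df)
    has_diary = df["n_diary_days"].fillna(0) >= 1
    df = df[has_diary]
    log.record("no_diary_day", n0, len(df))

    # 2. energy:BMR trim on the full diary-completing sample
    n0 = len(df)
    bmr = schofield_bmr(df["sex"].to_numpy(), df["age"].to_numpy(),
                        df["weight_kg"].to_numpy())
    keep = energy_bmr_trim(energy_bmr_ratio(df["energy_total"], bmr),
                           trim_fraction)
    df = df[keep]
    log.record("energy_bmr_trim", n0, len(df))

    # 3. prevalent CVD (incident-CVD analysis only)
    n0 = len(df)
    if analysis == "cvd":
        prevalent = df[PREVALENT_CVD_COLUMNS].fillna(False).astype(bool).any(axis=1)
        df = df[~prevalent]
    log.record("prevalent_cvd", n0, len(df))

    # 4. missing covariates
    n0 = len(df)
    cov = list(covariates)
    if analysis == "mortality":
        cov = cov + PREVALENT_CVD_COLUMNS
    df = df[df[cov].notna().all(axis=1)]
    log.record("missing_covariates", n0, len(df))

    # optional sensitivity exclusions
    if drop_comorbid_clinical:
        n0 = len(df)
        flag = df[COMORBID_CLINICAL].fillna(False).astype(bool).any(axis=1)
        df = df[~flag]
        log.record("comorbid_clinical", n0, len(df))
    if drop_comorbid_other:
        n0 = len(df)
        flag = df[COMORBID_OTHER].fillna(False).astype(bool).any(axis=1)
        df = df[~flag]
        log.record("comorbid_other", n0, len(df))
    if drop_fh_cvd:
        n0 = len(df)
        flag = df[["fh_mi", "fh_stroke"]].fillna(False).astype(bool).any(axis=1)
        df = df[~flag]
        log.record("fh_cvd", n0, len(df))
    if drop_fh_diabetes:
        n0 = len(df)
        df = df[~df["fh_diabetes"].fillna(False).astype(bool)]
        log.record("fh_diabetes", n0, len(df))
    if landmark_years is not None:
        if outcomes is None or outcome is None:
            raise ConfigurationError(
                "landmark exclusion requires outcomes table and outcome name")
        n0 = len(df)
        oc = outcomes.set_index("participant_id")
        ev = oc[f"{outcome}_event"].reindex(df["participant_id"]).to_numpy()
        tt = oc[f"{outcome}_time"].reindex(df["participant_id"]).to_numpy()
        early = (ev == 1) & (tt < landmark_years)
        df = df[~early]
        log.record(f"landmark_{landmark_years}y", n0, len(df))

    return df.reset_index(drop=True), log
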