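"""Cox proportional-hazards models for diet-exposure cohort analyses.

The central objects follow the Model/Results pattern:

* :class:`CoxExposureModel` is built from a cohort table (covariates +
  exposure quintiles + outcome time/event columns) and a :class:`ModelSpec`
  naming the outcome, the exposure parameterisation and the covariate set.
* :meth:`CoxExposureModel.fit` returns :class:`CoxExposureResults` carrying
  per-quintile hazard ratios (Q1 reference), covariate hazard ratios with
  Wald 95% CIs, the quintile linear-trend p-value, and Schoenfeld-residual
  proportional-hazards diagnostics.

Partial-likelihood estimation is delegated to lifelines (Efron tie
handling); the scaled-Schoenfeld PH test (per covariate and global) is
implemented here following Grambsch & Therneau, since a global test is
needed alongside the per-covariate ones.

Covariate sets mirror the standard two-stage adjustment strategy:

* ``model1`` — sociodemographic/behavioural: age (years), sex, education
  (4 levels, reference: no qualifications), smoking (reference: current),
  physical activity (reference: inactive), alcohol (units/day) and total
  dietary energy (per 2,000 kJ/day);
* ``model2`` — model1 plus self-reported clinical indicators (blood
  pressure- and lipid-lowering medication, diabetes, hypertension,
  hypercholesterolemia, past cancer) and family history (MI, stroke,
  diabetes);
* ``model2prime`` — model1 plus past cancer and family history only
  (drops the potential mediators).

Mortality outcomes additionally adjust for prevalent CVD (angina, heart
attack, stroke) in the adjusted models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError as _LLConvergence
from scipy import stats

from .errors import ConfigurationError, ConvergenceError, ValidationError

OUTCOMES = ("incident_cvd", "cvd_mortality", "all_cause_mortality",
            "incident_mi", "incident_stroke")
MORTALITY_OUTCOMES = frozenset({"cvd_mortality", "all_cause_mortality"})
EXPOSURES = ("quintile_energy", "quintile_weight", "quintile_score",
             "quintile_fv", "substitution")
COVARIATE_SETS = ("unadjusted", "model1", "model2", "model2prime")

_CLINICAL = ["bp_medication", "lipid_medication", "diabetes", "hypertension",
             "hypercholesterolemia", "past_cancer"]
_FAMILY = ["fh_mi", "fh_stroke", "fh_diabetes"]
_PREVALENT = ["angina", "heart_attack", "stroke"]


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit: outcome x exposure x covariate set + flags."""

    outcome: str = "incident_cvd"
    exposure: str = "quintile_energy"
    covariate_set: str = "model1"
    adjust_total_energy: bool = True
    adjust_bmi: bool = False
    #: None = automatic (on for adjusted mortality models)
    adjust_prevalent_cvd: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.exposure not in EXPOSURES:
            raise ConfigurationError(f"unknown exposure {self.exposure!r}")
        if self.covariate_set not in COVARIATE_SETS:
            raise ConfigurationError(
                f"unknown covariate_set {self.covariate_set!r}")

    @property
    def prevalent_cvd_adjusted(self) -> bool:
        if self.adjust_prevalent_cvd is not None:
            return self.adjust_prevalent_cvd
        return (self.outcome in MORTALITY_OUTCOMES
                and self.covariate_set != "unadjusted")


def _covariate_columns(spec: ModelSpec) -> list[str]:
    """Design columns for the spec's covariate set (exposure excluded)."""
    if spec.covariate_set == "unadjusted":
        cols: list[str] = []
    else:
        cols = ["age", "female", "education_1", "education_2", "education_3",
                "smoking_former", "smoking_never",
                "activity_1", "activity_2", "activity_3", "alcohol_units"]
        if spec.adjust_total_energy:
            cols.append("energy_2000")
        if spec.covariate_set == "model2":
            cols += _CLINICAL + _FAMILY
        elif spec.covariate_set == "model2prime":
            cols += ["past_cancer"] + _FAMILY
    if spec.adjust_bmi:
        cols.append("bmi")
    if spec.prevalent_cvd_adjusted:
        cols += _PREVALENT
    return cols


def encode_design(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix + ``time``/``event`` columns for one model spec.

    Quintile exposures enter as four indicators against Q1; the
    substitution exposure as the four energy terms (per 1,000 kJ/day).
    """
    time_col, event_col = f"{spec.outcome}_time", f"{spec.outcome}_event"
    for c in (time_col, event_col):
        if c not in cohort.columns:
            raise ValidationError(f"cohort lacks outcome column {c!r}")

    out = pd.DataFrame(index=cohort.index)

    if spec.exposure == "substitution":
        if not spec.adjust_total_energy:
            raise ConfigurationError(
                "the substitution model requires total-energy adjustment")
        for name, col in (("e_lh_food_1000", "energy_lh_food"),
                          ("e_lh_bev_1000", "energy_lh_bev"),
                          ("e_healthy_bev_1000", "energy_healthy_bev"),
                          ("e_total_1000", "energy_total")):
            out[name] = cohort[col].to_numpy(dtype=float) / 1000.0
        exposure_terms = list(out.columns)
    else:
        q = cohort[spec.exposure]
        if q.isna().any() or (~q.isin([1, 2, 3, 4, 5])).any():
            raise ValidationError(
                f"{spec.exposure} must hold quintile labels 1..5")
        for k in (2, 3, 4, 5):
            out[f"{spec.exposure}_q{k}"] = (q == k).astype(float)
        exposure_terms = list(out.columns)

    need = set(_covariate_columns(spec))
    if need & {"age", "female"}:
        out["age"] = cohort["age"].astype(float)
        out["female"] = (cohort["sex"] == "female").astype(float)
        for k in (1, 2, 3):
            out[f"education_{k}"] = (cohort["education"] == k).astype(float)
            out[f"activity_{k}"] = (cohort["activity"] == k).astype(float)
        out["smoking_former"] = (cohort["smoking"] == "former").astype(float)
        out["smoking_never"] = (cohort["smoking"] == "never").astype(float)
        out["alcohol_units"] = cohort["alcohol_units"].astype(float)
        if "energy_2000" in need:
            out["energy_2000"] = cohort["energy_total"].astype(float) / 2000.0
    for c in sorted(need - set(out.columns)):
        out[c] = cohort[c].astype(float)

    cols = exposure_terms + [c for c in _covariate_columns(spec)
                             if c not in exposure_terms]
    if spec.exposure == "substitution" and "energy_2000" in cols:
        cols.remove("energy_2000")  # e_total_1000 already carries it
    out = out[cols]

    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        first = cohort.loc[out.isna().any(axis=1), "participant_id"].iloc[0] \
            if "participant_id" in cohort.columns else "?"
        raise ValidationError(
            f"missing covariate values in {bad} (first participant {first!r})")

    degenerate = [c for c in exposure_terms if out[c].nunique() <= 1]
    if spec.exposure != "substitution" and len(degenerate) == len(exposure_terms):
        raise ValidationError(
            "degenerate design: exposure shows no contrast variation")
    if spec.exposure == "substitution":
        m = out.to_numpy()
        if np.linalg.matrix_rank(m - m.mean(0)) < m.shape[1]:
            raise ValidationError(
                "rank-deficient substitution design (collinear energy terms)")

    out["time"] = cohort[time_col].astype(float)
    out["event"] = cohort[event_col].astype(int)
    if (out["time"] <= 0).any():
        raise ValidationError("event/censoring times must be positive")
    if (~out["event"].isin([0, 1])).any():
        raise ValidationError("event indicator must be 0/1")
    return out


def detect_separation(design: pd.DataFrame, event: np.ndarray) -> list[str]:
    """Binary covariates whose events all fall in one level (monotone
    likelihood / complete separation risk)."""
    flagged = []
    ev = np.asarray(event).astype(bool)
    if ev.sum() == 0:
        return flagged
    for c in design.columns:
        x = design[c].to_numpy()
        levels = np.unique(x)
        if len(levels) == 2 and len(np.unique(x[ev])) == 1:
            flagged.append(c)
    return flagged


def fit_cox(design: pd.DataFrame, time=None, event=None,
            robust: bool = False) -> tuple[CoxPHFitter, list[str]]:
    """Fit a Cox model (Efron ties, Wald inference) on a design frame.

    ``design`` may already contain ``time``/``event`` columns, or they can
    be passed separately. Returns the fitted lifelines model plus any
    separation flags; a ridge-stabilised refit is attempted on monotone
    likelihoods so the flags can be reported with finite estimates.
    """
    df = design.copy()
    if time is not None:
        df["time"] = np.asarray(time, dtype=float)
    if event is not None:
        df["event"] = np.asarray(event, dtype=int)
    covs = [c for c in df.columns if c not in ("time", "event")]
    flags = detect_separation(df[covs], df["event"].to_numpy())
    penalizer = 0.01 if flags else 0.0
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event", robust=robust)
    except _LLConvergence as exc:
        if not flags:
            # retry once with a small ridge before giving up
            try:
                cph = CoxPHFitter(penalizer=0.01)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="time", event_col="event")
                flags = flags + ["ridge_stabilised"]
            except _LLConvergence:
                raise ConvergenceError(
                    f"Cox partial likelihood failed to converge: {exc}") from exc
        else:
            raise ConvergenceError(
                f"Cox fit failed despite ridge (separation in {flags}): {exc}"
            ) from exc
    return cph, flags


def schoenfeld_ph_test(cph: CoxPHFitter, training_df: pd.DataFrame,
                       transform: str = "rank") -> pd.DataFrame:
    """Scaled-Schoenfeld proportional-hazards test (Grambsch-Therneau).

    Tests, per covariate, the slope of the scaled Schoenfeld residuals on a
    transform of event time (default: rank), plus a global chi-square over
    all covariates. Returns a DataFrame with rows per covariate and a
    ``GLOBAL`` row (columns: chi2, df, p).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        resid = cph.compute_residuals(training_df, kind="schoenfeld")
    # rows are events ordered by time already; make sure
    times = resid.index.get_level_values(0).to_numpy(dtype=float) \
        if isinstance(resid.index, pd.MultiIndex) else None
    if times is None:
        ev = training_df[training_df["event"] == 1]
        times = ev.loc[resid.index, "time"].to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    S = resid.to_numpy()[order]
    t = times[order]
    d, p = S.shape

    if transform == "rank":
        g = stats.rankdata(t, method="average")
    elif transform == "identity":
        g = t.copy()
    elif transform == "log":
        g = np.log(t)
    elif transform == "km":
        # left-continuous KM of the censoring-inclusive sample
        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter().fit(training_df["time"],
                                     training_df["event"])
        g = 1.0 - km.survival_function_at_times(t).to_numpy()
    else:
        raise ConfigurationError(f"unknown time transform {transform!r}")
    g = g - g.mean()
    w = float(np.sum(g ** 2))

    V = cph.variance_matrix_.to_numpy()
    u = S.T @ g                       # p-vector
    vu = V @ u
    chi_cov = d * vu ** 2 / (np.diag(V) * w)
    chi_global = float(d * u @ vu / w)

    rows = [(name, float(c), 1, float(stats.chi2.sf(c, 1)))
            for name, c in zip(resid.columns, chi_cov)]
    rows.append(("GLOBAL", chi_global, p, float(stats.chi2.sf(chi_global, p))))
    return pd.DataFrame(rows, columns=["covariate", "chi2", "df", "p"]) \
        .set_index("covariate")


class CoxExposureModel:
    """Cox PH model of a dietary exposure on a time-to-event outcome.

    Parameters
    ----------
    cohort
        Analysis table after exclusions: one row per participant with
        covariates, quintile labels and ``<outcome>_time``/``_event``.
    spec
        The outcome/exposure/covariate-set specification.
    """

    def __init__(self, cohort: pd.DataFrame, spec: ModelSpec):
        self.cohort = cohort
        self.spec = spec
        self.design = encode_design(cohort, spec)

    @classmethod
    def from_tables(cls, cohort: pd.DataFrame, outcomes: pd.DataFrame,
                    spec: ModelSpec) -> "CoxExposureModel":
        """Build from a filtered cohort plus a separate outcomes table."""
        merged = cohort.merge(outcomes, on="participant_id",
                              validate="one_to_one")
        return cls(merged, spec)

    def fit(self, compute_trend: bool = True,
            robust: bool = False) -> "CoxExposureResults":
        cph, flags = fit_cox(self.design, robust=robust)
        trend_p = trend_slope = None
        if compute_trend and self.spec.exposure != "substitution":
            trend_p, trend_slope = self._trend()
        return CoxExposureResults(self, cph, flags, trend_p, trend_slope)

    def _trend(self) -> tuple[float, float]:
        """Refit with the quintile index as a single continuous covariate."""
        q = self.cohort[self.spec.exposure]
        if q.nunique() <= 1:
            raise ValidationError("quintile labels are constant; "
                                  "trend test undefined")
        dummy_cols = [f"{self.spec.exposure}_q{k}" for k in (2, 3, 4, 5)]
        dd = self.design.drop(columns=dummy_cols)
        dd.insert(0, "quintile_trend", q.to_numpy(dtype=float))
        cph, _ = fit_cox(dd)
        return (float(cph.summary.loc["quintile_trend", "p"]),
                float(cph.params_["quintile_trend"]))


class CoxExposureResults:
    """Fitted hazard ratios, trend test and PH diagnostics."""

    def __init__(self, model: CoxExposureModel, cph: CoxPHFitter,
                 flags: list[str], trend_p, trend_slope):
        self.model = model
        self.spec = model.spec
        self._cph = cph
        self.separation_flags = flags
        self.trend_p = trend_p
        self.trend_slope = trend_slope
        self.n = int(len(model.design))
        self.n_events = int(model.design["event"].sum())
        self._ph = None

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """log hazard ratios."""
        return self._cph.params_

    @property
    def summary_frame(self) -> pd.DataFrame:
        s = self._cph.summary
        return s.rename(columns={
            "exp(coef)": "HR", "exp(coef) lower 95%": "HR_lower",
            "exp(coef) upper 95%": "HR_upper"})[
            ["coef", "se(coef)", "HR", "HR_lower", "HR_upper", "p"]]

    @property
    def hazard_ratios(self) -> pd.DataFrame:
        """All terms: HR with Wald 95% CI and p."""
        return self.summary_frame[["HR", "HR_lower", "HR_upper", "p"]]

    @property
    def quintile_hr(self) -> pd.DataFrame:
        """Per-quintile HRs with the Q1 reference row (HR exactly 1)."""
        if self.spec.exposure == "substitution":
            raise ConfigurationError(
                "substitution model has no quintile contrasts")
        name = self.spec.exposure
        ref = pd.DataFrame(
            {"HR": [1.0], "HR_lower": [np.nan], "HR_upper": [np.nan],
             "p": [np.nan]}, index=[f"{name}_q1"])
        rows = self.hazard_ratios.loc[
            [f"{name}_q{k}" for k in (2, 3, 4, 5)]]
        return pd.concat([ref, rows])

    # -- diagnostics -------------------------------------------------------
    def check_ph(self, transform: str = "rank",
                 min_events: int = 10) -> Optional[pd.DataFrame]:
        """Schoenfeld-residual PH tests (per covariate + GLOBAL row)."""
        if self.n_events < min_events:
            warnings.warn(f"only {self.n_events} events; PH tests skipped")
            return None
        if self._ph is None or transform != getattr(self, "_ph_transform", None):
            self._ph = schoenfeld_ph_test(self._cph, self.model.design,
                                          transform=transform)
            self._ph_transform = transform
        return self._ph

    def plot_schoenfeld(self, covariate: str, ax=None):
        """Scaled Schoenfeld residuals of one covariate against time."""
        import matplotlib.pyplot as plt
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resid = self._cph.compute_residuals(
                self.model.design, kind="scaled_schoenfeld")
        ev = self.model.design[self.model.design["event"] == 1]
        t = ev["time"].to_numpy()
        order = np.argsort(t)
        if ax is None:
            _, ax = plt.subplots()
        y = resid[covariate].to_numpy()[order]
        ax.scatter(np.sort(t), y, s=6, alpha=0.5)
        ax.axhline(float(self.params[covariate]), ls="--", color="k",
                   label="fitted log HR")
        ax.set_xlabel("follow-up time (years)")
        ax.set_ylabel(f"scaled Schoenfeld residual: {covariate}")
        ax.legend()
        return ax

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Cox proportional-hazards model",
            f"  outcome: {self.spec.outcome}   exposure: {self.spec.exposure}"
            f"   covariates: {self.spec.covariate_set}",
            f"  n = {self.n}, events = {self.n_events}",
        ]
        if self.separation_flags:
            lines.append(f"  separation flags: {self.separation_flags}")
        with pd.option_context("display.width", 110,
                               "display.float_format", "{:.3f}".format):
            lines.append(str(self.hazard_ratios))
        if self.trend_p is not None:
            lines.append(f"  linear trend over quintiles: "
                         f"slope = {self.trend_slope:+.4f} (log HR per "
                         f"quintile), p = {self.trend_p:.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        hr = self.hazard_ratios
        out = {
            "spec": {"outcome": self.spec.outcome,
                     "exposure": self.spec.exposure,
                     "covariate_set": self.spec.covariate_set},
            "n": self.n, "n_events": self.n_events,
            "terms": {ix: {k: (None if pd.isna(v) else float(v))
                           for k, v in row.items()}
                      for ix, row in hr.iterrows()},
            "trend_p": self.trend_p,
            "separation_flags": self.separation_flags,
        }
        ph = self.check_ph() if self.n_events >= 10 else None
        if ph is not None:
            out["ph_test"] = {ix: {"chi2": r["chi2"], "df": int(r["df"]),
                                   "p": r["p"]}
                              for ix, r in ph.iterrows()}
        return out


def trend_test(cohort: pd.DataFrame, spec: ModelSpec) -> float:
    """Wald p-value for the quintile index fitted as continuous."""
    model = CoxExposureModel(cohort, spec)
    p, _ = model._trend()
    return p


def fit_substitution(cohort: pd.DataFrame,
                     spec: ModelSpec | None = None) -> CoxExposureResults:
    """Isocaloric substitution model.

    Fits energy from less-healthy food, less-healthy beverages and healthy
    beverages (each per 1,000 kJ/day) alongside total energy; with total
    energy held constant, the less-healthy-food coefficient is the hazard
    of isocalorically replacing healthy food with less-healthy food.
    """
    spec = spec or ModelSpec(exposure="substitution")
    if spec.exposure != "substitution":
        spec = replace(spec, exposure="substitution")
    return CoxExposureModel(cohort, spec).fit(compute_trend=False)
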