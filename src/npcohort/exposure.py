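"""Person-level dietary exposures from 7-day diet diaries.

Each diary row records grams of one catalogue item eaten by one participant
on one day. Energy per row is ``grams * energy_kj / 100``. Rows are routed
by the item's scoring classification into less-healthy food, less-healthy
beverage, healthy food, healthy beverage and alcoholic-beverage groups, and
per-day averages are taken over the participant's distinct diary days.

The primary exposure is the proportion of energy from less-healthy items,

    (E_lh_food + E_lh_beverage) / (E_total - E_alcoholic),

with alcoholic beverages excluded from the denominator because they are
exempt from scoring. Alternative exposures: the proportion of (non-alcoholic)
food weight that is less-healthy, the energy-weighted mean profile score of
non-alcoholic items, and fruit+vegetable weight per day. Participants are
ranked into quintile groups on the analysis sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedExposureError, ValidationError

DIARY_COLUMNS = ["participant_id", "day_index", "item_id", "grams"]

EXPOSURE_COLUMNS = [
    "participant_id", "n_diary_days", "energy_lh_food", "energy_lh_bev",
    "energy_healthy_food", "energy_healthy_bev", "energy_healthy",
    "energy_alcoholic", "energy_total", "weight_lh", "weight_total",
    "fv_weight", "prop_lh_energy", "prop_lh_weight", "mean_weighted_score",
]


def validate_diary(diary: pd.DataFrame, catalogue_ids=None) -> None:
    missing = [c for c in DIARY_COLUMNS if c not in diary.columns]
    if missing:
        raise ValidationError(f"diary missing columns: {missing}")
    if len(diary) == 0:
        return
    if (diary["grams"] <= 0).any() or ~np.isfinite(diary["grams"]).all():
        raise ValidationError("diary grams must be positive and finite")
    if (~diary["day_index"].between(1, 7)).any():
        raise ValidationError("diary day_index must lie in 1..7")
    if catalogue_ids is not None:
        unresolved = set(diary["item_id"]) - set(catalogue_ids)
        if unresolved:
            raise ValidationError(
                f"diary item_id not in catalogue: {sorted(unresolved)[:10]}")


def build_exposures(diary: pd.DataFrame, scored: pd.DataFrame,
                    catalogue: pd.DataFrame,
                    include_beverage_weight: bool = True) -> pd.DataFrame:
    """Aggregate diaries to one exposure row per participant.

    ``scored`` maps item_id to score and classification; ``catalogue`` maps
    item_id to energy density and fruit/veg weight fraction (column
    ``fv_frac``; falls back to ``fvn_pct``/100 when absent).

    ``include_beverage_weight`` controls whether (non-alcoholic) beverage
    weight enters the weight-based exposure's numerator and denominator
    (default: included).
    """
    validate_diary(diary, catalogue["item_id"])

    cat = catalogue.set_index("item_id")
    if "fv_frac" not in cat.columns:
        cat = cat.assign(fv_frac=cat["fvn_pct"] / 100.0)
    sc = scored.set_index("item_id")

    d = diary.copy()
    d["energy"] = d["grams"].to_numpy() * \
        cat["energy_kj"].reindex(d["item_id"]).to_numpy() / 100.0
    d["item_class"] = cat["item_class"].reindex(d["item_id"]).to_numpy()
    d["classification"] = sc["classification"].reindex(d["item_id"]).to_numpy()
    d["score"] = sc["score"].reindex(d["item_id"]).to_numpy()
    d["fv_grams"] = d["grams"].to_numpy() * \
        cat["fv_frac"].reindex(d["item_id"]).to_numpy()

    is_alc = d["classification"].eq("unscored")
    is_lh = d["classification"].eq("less_healthy")
    is_food = d["item_class"].eq("food")
    is_bev = d["item_class"].eq("beverage")

    d["e_lh_food"] = d["energy"].where(is_lh & is_food, 0.0)
    d["e_lh_bev"] = d["energy"].where(is_lh & is_bev, 0.0)
    d["e_h_food"] = d["energy"].where(~is_lh & ~is_alc & is_food, 0.0)
    d["e_h_bev"] = d["energy"].where(~is_lh & ~is_alc & is_bev, 0.0)
    d["e_alc"] = d["energy"].where(is_alc, 0.0)

    weight_eligible = ~is_alc if include_beverage_weight else (is_food & ~is_alc)
    d["w_lh"] = d["grams"].where(is_lh & weight_eligible, 0.0)
    d["w_tot"] = d["grams"].where(weight_eligible, 0.0)
    d["score_energy"] = (d["score"] * d["energy"]).where(~is_alc, 0.0)
    d["e_nonalc"] = d["energy"].where(~is_alc, 0.0)

    g = d.groupby("participant_id", sort=True)
    agg = g.agg(
        n_diary_days=("day_index", "nunique"),
        e_lh_food=("e_lh_food", "sum"), e_lh_bev=("e_lh_bev", "sum"),
        e_h_food=("e_h_food", "sum"), e_h_bev=("e_h_bev", "sum"),
        e_alc=("e_alc", "sum"), energy=("energy", "sum"),
        w_lh=("w_lh", "sum"), w_tot=("w_tot", "sum"),
        fv_grams=("fv_grams", "sum"),
        score_energy=("score_energy", "sum"), e_nonalc=("e_nonalc", "sum"),
    )

    days = agg["n_diary_days"].to_numpy(dtype=float)
    out = pd.DataFrame({
        "participant_id": agg.index,
        "n_diary_days": agg["n_diary_days"].to_numpy(),
        "energy_lh_food": agg["e_lh_food"].to_numpy() / days,
        "energy_lh_bev": agg["e_lh_bev"].to_numpy() / days,
        "energy_healthy_food": agg["e_h_food"].to_numpy() / days,
        "energy_healthy_bev": agg["e_h_bev"].to_numpy() / days,
        "energy_alcoholic": agg["e_alc"].to_numpy() / days,
        "energy_total": agg["energy"].to_numpy() / days,
        "weight_lh": agg["w_lh"].to_numpy() / days,
        "weight_total": agg["w_tot"].to_numpy() / days,
        "fv_weight": agg["fv_grams"].to_numpy() / days,
    }).reset_index(drop=True)
    out["energy_healthy"] = out["energy_healthy_food"] + out["energy_healthy_bev"]

    denom_e = out["energy_total"] - out["energy_alcoholic"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["prop_lh_energy"] = np.where(
            denom_e > 0,
            (out["energy_lh_food"] + out["energy_lh_bev"]) / denom_e, np.nan)
        out["prop_lh_weight"] = np.where(
            out["weight_total"] > 0,
            out["weight_lh"] / out["weight_total"], np.nan)
        e_nonalc = agg["e_nonalc"].to_numpy()
        out["mean_weighted_score"] = np.where(
            e_nonalc > 0, agg["score_energy"].to_numpy() / e_nonalc, np.nan)
    return out[EXPOSURE_COLUMNS]


def aggregate_participant(records: pd.DataFrame, scored: pd.DataFrame,
                          catalogue: pd.DataFrame, **kwargs) -> pd.Series:
    """Exposure row for a single participant's diary records."""
    if len(records) == 0:
        raise ValidationError("no diary records for participant")
    if records["participant_id"].nunique() != 1:
        raise ValidationError("records span more than one participant")
    out = build_exposures(records, scored, catalogue, **kwargs)
    return out.iloc[0]


def mean_energy_weighted_score(records: pd.DataFrame, scored: pd.DataFrame,
                               catalogue: pd.DataFrame) -> float:
    """Energy-weighted mean profile score over non-alcoholic items."""
    row = aggregate_participant(records, scored, catalogue)
    if not np.isfinite(row["mean_weighted_score"]):
        raise UndefinedExposureError(
            "zero non-alcoholic energy: mean energy-weighted score undefined")
    return float(row["mean_weighted_score"])


def assign_quintiles(values, ids=None, n_groups: int = 5):
    """Rank a sample into fifths (or ``n_groups`` generally).

    Group boundaries sit at cumulative ranks ceil(n*j/5) (nearest-rank
    empirical quantiles), with ties broken by stable ascending sort on
    (value, id). For n = 22,992 this yields group sizes
    4599/4598/4599/4598/4598. Returns ``(labels, boundaries)`` where
    ``labels`` are 1..n_groups aligned with the input order and
    ``boundaries`` the n_groups-1 cut values.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < n_groups:
        raise ValidationError(f"need at least {n_groups} values, got {n}")
    if not np.isfinite(v).all():
        raise ValidationError("non-finite exposure values")
    if ids is None:
        ids = np.arange(n)
    order = np.lexsort((np.asarray(ids), v))  # value, then id: stable
    cum = np.ceil(n * np.arange(1, n_groups + 1) / n_groups).astype(int)
    labels_sorted = np.empty(n, dtype=int)
    start = 0
    for q, stop in enumerate(cum, start=1):
        labels_sorted[start:stop] = q
        start = stop
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    boundaries = v[order][cum[:-1] - 1]  # upper value of groups 1..4
    return labels, boundaries
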