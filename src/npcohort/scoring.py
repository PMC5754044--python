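"""FSA-Ofcom nutrient profile scoring.

The model assigns each food or beverage item an integer score from its
composition per 100 g edible weight. Four adverse "A" components (energy,
saturated fat, total sugars, sodium) each earn 0-10 points; three beneficial
"C" components (NSP fibre, protein, fruit/vegetable/nut content) each earn
points that are subtracted. Protein points are gated: when the A total
reaches 11, protein may only offset it if the fruit/veg/nut component is at
its 5-point maximum. A food scoring 4 or more points is classified
"less-healthy"; a beverage, 1 or more. Alcoholic beverages are exempt from
scoring altogether and are classified "unscored".

Cut-point tables are configuration data (see ``data/fsa_ofcom_2005.yaml``)
so they can be corrected against the published guidance without a code
change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputDomainError, ValidationError

logger = logging.getLogger(__name__)

ITEM_CLASSES = ("food", "beverage", "alcoholic_beverage")

#: FoodComposition CSV columns, in canonical order.
CATALOGUE_COLUMNS = [
    "item_id", "name", "item_class", "energy_kj", "satfat_g", "sugars_g",
    "sodium_mg", "fibre_g", "protein_g", "fvn_pct",
]

_NUTRIENT_FIELDS = ("energy_kj", "satfat_g", "sugars_g", "sodium_mg",
                    "fibre_g", "protein_g", "fvn_pct")


@dataclass(frozen=True)
class FoodComposition:
    """One catalogue item: nutrient content per 100 g edible weight."""

    item_id: str
    name: str
    item_class: str
    energy_kj: float
    satfat_g: float
    sugars_g: float
    sodium_mg: float
    fibre_g: float
    protein_g: float
    fvn_pct: float

    def __post_init__(self) -> None:
        if self.item_class not in ITEM_CLASSES:
            raise ConfigurationError(
                f"item {self.item_id!r}: unknown item_class {self.item_class!r}")
        for f in _NUTRIENT_FIELDS:
            v = getattr(self, f)
            if not np.isfinite(v) or v < 0:
                raise InputDomainError(
                    f"item {self.item_id!r}: field {f} must be finite and "
                    f"non-negative, got {v!r}")
        if self.fvn_pct > 100:
            raise InputDomainError(
                f"item {self.item_id!r}: fvn_pct must lie in [0, 100], "
                f"got {self.fvn_pct!r}")


@dataclass(frozen=True)
class ScoredItem:
    """Component points, total score and classification for one item."""

    item_id: str
    a_points_energy: int
    a_points_satfat: int
    a_points_sugars: int
    a_points_sodium: int
    a_total: int
    c_points_fvn: int
    c_points_fibre: int
    c_points_protein: int
    protein_counted: bool
    score: int
    classification: str  # healthy | less_healthy | unscored


@dataclass(frozen=True)
class ScoringTables:
    """Cut-point configuration for the scoring model."""

    energy_kj: tuple
    satfat_g: tuple
    sugars_g: tuple
    sodium_mg: tuple
    fibre_g: tuple
    protein_g: tuple
    fvn_pct: tuple
    fvn_point_map: tuple = (0, 1, 2, 5)
    protein_gate_a_total: int = 11
    protein_gate_fvn_points: int = 5
    food_threshold: int = 4
    beverage_threshold: int = 1

    def __post_init__(self) -> None:
        for name in ("energy_kj", "satfat_g", "sugars_g", "sodium_mg",
                     "fibre_g", "protein_g", "fvn_pct"):
            t = getattr(self, name)
            if len(t) == 0 or any(b <= a for a, b in zip(t, t[1:])):
                raise ConfigurationError(
                    f"cut-point table {name!r} must be non-empty and "
                    f"strictly increasing: {t!r}")
        if len(self.fvn_point_map) != len(self.fvn_pct) + 1:
            raise ConfigurationError(
                "fvn_point_map must have one entry per threshold count")

    @classmethod
    def from_dict(cls, d: dict) -> "ScoringTables":
        a, c = d["a_points"], d["c_points"]
        return cls(
            energy_kj=tuple(a["energy_kj"]), satfat_g=tuple(a["satfat_g"]),
            sugars_g=tuple(a["sugars_g"]), sodium_mg=tuple(a["sodium_mg"]),
            fibre_g=tuple(c["fibre_g"]), protein_g=tuple(c["protein_g"]),
            fvn_pct=tuple(c["fvn_pct"]),
            fvn_point_map=tuple(d.get("fvn_point_map", (0, 1, 2, 5))),
            protein_gate_a_total=d.get("protein_gate_a_total", 11),
            protein_gate_fvn_points=d.get("protein_gate_fvn_points", 5),
            food_threshold=d.get("food_threshold", 4),
            beverage_threshold=d.get("beverage_threshold", 1),
        )

    @classmethod
    def from_yaml(cls, path) -> "ScoringTables":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ScoringTables":
        ref = resources.files("npcohort.data") / "fsa_ofcom_2005.yaml"
        return cls.from_dict(yaml.safe_load(ref.read_text()))


def component_points(value: float, thresholds: Sequence[float],
                     field_name: str = "value") -> int:
    """Points for one component: the number of cut-points strictly exceeded.

    ``value`` is the nutrient quantity per 100 g; no rounding is applied.
    The count is capped at the table length by construction.
    """
    if not np.isfinite(value) or value < 0:
        raise InputDomainError(
            f"{field_name} must be finite and non-negative, got {value!r}")
    t = np.asarray(thresholds, dtype=float)
    if t.size == 0 or np.any(np.diff(t) <= 0):
        raise ConfigurationError(
            f"threshold table for {field_name} must be strictly increasing")
    # strict ">" semantics: searchsorted side='left' counts t < value
    return int(np.searchsorted(t, value, side="left"))


def score_item(item: FoodComposition,
               tables: ScoringTables | None = None) -> ScoredItem:
    """Score one item; classification is attached via :func:`classify_item`."""
    tables = tables or ScoringTables.default()
    a_energy = component_points(item.energy_kj, tables.energy_kj, "energy_kj")
    a_satfat = component_points(item.satfat_g, tables.satfat_g, "satfat_g")
    a_sugars = component_points(item.sugars_g, tables.sugars_g, "sugars_g")
    a_sodium = component_points(item.sodium_mg, tables.sodium_mg, "sodium_mg")
    a_total = a_energy + a_satfat + a_sugars + a_sodium

    c_fvn = tables.fvn_point_map[
        component_points(item.fvn_pct, tables.fvn_pct, "fvn_pct")]
    c_fibre = component_points(item.fibre_g, tables.fibre_g, "fibre_g")
    c_protein = component_points(item.protein_g, tables.protein_g, "protein_g")

    protein_counted = not (a_total >= tables.protein_gate_a_total
                           and c_fvn < tables.protein_gate_fvn_points)
    score = a_total - c_fvn - c_fibre - (c_protein if protein_counted else 0)

    scored = ScoredItem(
        item_id=item.item_id, a_points_energy=a_energy,
        a_points_satfat=a_satfat, a_points_sugars=a_sugars,
        a_points_sodium=a_sodium, a_total=a_total, c_points_fvn=c_fvn,
        c_points_fibre=c_fibre, c_points_protein=c_protein,
        protein_counted=protein_counted, score=score,
        classification=classify_item(score, item.item_class, tables))
    return scored


def classify_item(score: int, item_class: str,
                  tables: ScoringTables | None = None) -> str:
    """Less-healthy classification: food at >=4 points, beverage at >=1;
    alcoholic beverages are never scored."""
    tables = tables or ScoringTables.default()
    if item_class == "alcoholic_beverage":
        return "unscored"
    if item_class == "food":
        return "less_healthy" if score >= tables.food_threshold else "healthy"
    if item_class == "beverage":
        return ("less_healthy" if score >= tables.beverage_threshold
                else "healthy")
    raise ConfigurationError(f"unknown item_class {item_class!r}")


def score_catalogue(catalogue: Iterable[FoodComposition] | pd.DataFrame,
                    tables: ScoringTables | None = None) -> pd.DataFrame:
    """Score every catalogue item, preserving order.

    Accepts a list of :class:`FoodComposition` or a DataFrame with the
    catalogue columns; returns a DataFrame of :class:`ScoredItem` fields.
    """
    tables = tables or ScoringTables.default()
    if isinstance(catalogue, pd.DataFrame):
        items = [FoodComposition(**{k: row[k] for k in CATALOGUE_COLUMNS})
                 for row in catalogue[CATALOGUE_COLUMNS].to_dict("records")]
    else:
        items = list(catalogue)
    ids = [it.item_id for it in items]
    dupes = pd.Series(ids).pipe(lambda s: sorted(s[s.duplicated()].unique()))
    if dupes:
        raise ValidationError(f"duplicate item_id values: {dupes}")
    scored = [score_item(it, tables) for it in items]
    if not scored:
        return pd.DataFrame(columns=list(ScoredItem.__annotations__))
    out = pd.DataFrame([vars(s) for s in scored])
    counts = out["classification"].value_counts().to_dict()
    logger.info("scored %d items: %s", len(out), counts)
    return out


def read_catalogue(path) -> pd.DataFrame:
    """Read a FoodComposition CSV, validating header and domains."""
    df = pd.read_csv(path)
    missing = [c for c in CATALOGUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"catalogue CSV missing columns: {missing}")
    bad = ~df["item_class"].isin(ITEM_CLASSES)
    if bad.any():
        raise ValidationError(
            f"unknown item_class values: {sorted(df.loc[bad, 'item_class'].unique())}")
    return df
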