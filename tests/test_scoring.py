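"""Unit and property tests for the nutrient-profile scoring model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from npcohort import (FoodComposition, ScoringTables, classify_item,
                      component_points, score_catalogue, score_item)
from npcohort.errors import (ConfigurationError, InputDomainError,
                             ValidationError)

# ---------------------------------------------------------------------------
# independent brute-force oracle (kept deliberately naive)


def oracle_points(value, thresholds):
    pts = 0
    for t in thresholds:
        if value > t:
            pts += 1
    return pts


def oracle_score_and_class(comp: dict, item_class: str, t: ScoringTables):
    a = (oracle_points(comp["energy_kj"], t.energy_kj)
         + oracle_points(comp["satfat_g"], t.satfat_g)
         + oracle_points(comp["sugars_g"], t.sugars_g)
         + oracle_points(comp["sodium_mg"], t.sodium_mg))
    fvn = t.fvn_point_map[oracle_points(comp["fvn_pct"], t.fvn_pct)]
    fibre = oracle_points(comp["fibre_g"], t.fibre_g)
    protein = oracle_points(comp["protein_g"], t.protein_g)
    if a >= 11 and fvn < 5:
        score = a - fvn - fibre
    else:
        score = a - fvn - fibre - protein
    if item_class == "alcoholic_beverage":
        cls = "unscored"
    elif item_class == "food":
        cls = "less_healthy" if score >= 4 else "healthy"
    else:
        cls = "less_healthy" if score >= 1 else "healthy"
    return score, cls


def random_compositions(n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "item_id": [f"r{i}" for i in range(n)],
        "name": "x",
        "item_class": rng.choice(["food", "beverage", "alcoholic_beverage"],
                                 n, p=[0.6, 0.3, 0.1]),
        "energy_kj": rng.uniform(0, 4000, n),
        "satfat_g": rng.uniform(0, 25, n),
        "sugars_g": rng.uniform(0, 60, n),
        "sodium_mg": rng.uniform(0, 1200, n),
        "fibre_g": rng.uniform(0, 6, n),
        "protein_g": rng.uniform(0, 15, n),
        "fvn_pct": rng.uniform(0, 100, n),
    })


# ---------------------------------------------------------------------------
# component points

@pytest.mark.parametrize("value,table_name,expected", [
    (0.0, "energy_kj", 0),
    (1800.0, "energy_kj", 5),
    (9.0, "satfat_g", 8),       # strict ">": 9 exceeds 1..8, not 9
    (20.0, "sugars_g", 4),
    (500.0, "sodium_mg", 5),
    (0.5, "fibre_g", 0),
    (5.0, "protein_g", 3),
    (5000.0, "energy_kj", 10),  # capped at table length
])
def test_component_points_examples(tables, value, table_name, expected):
    assert component_points(value, getattr(tables, table_name)) == expected


def test_component_points_rejects_negative_and_bad_tables():
    with pytest.raises(InputDomainError, match="satfat"):
        component_points(-1.0, (1, 2, 3), "satfat_g")
    with pytest.raises(ConfigurationError):
        component_points(1.0, (3, 2, 1), "x")


# ---------------------------------------------------------------------------
# full item scoring

def _comp(**kw):
    base = dict(item_id="i", name="n", item_class="food", energy_kj=0,
                satfat_g=0, sugars_g=0, sodium_mg=0, fibre_g=0, protein_g=0,
                fvn_pct=0)
    base.update(kw)
    return FoodComposition(**base)


def test_all_zero_composition_scores_zero(tables):
    s = score_item(_comp(), tables)
    assert s.a_total == 0 and s.score == 0
    assert s.classification == "healthy"


def test_worked_example_protein_gate(tables):
    item = _comp(energy_kj=1800, satfat_g=9, sugars_g=20, sodium_mg=500,
                 fibre_g=0.5, protein_g=5, fvn_pct=0)
    s = score_item(item, tables)
    assert (s.a_points_energy, s.a_points_satfat, s.a_points_sugars,
            s.a_points_sodium) == (5, 8, 4, 5)
    assert s.a_total == 22
    assert s.c_points_protein == 3 and not s.protein_counted
    assert s.score == 22 and s.classification == "less_healthy"


def test_max_fvn_releases_protein_gate(tables):
    item = _comp(energy_kj=1800, satfat_g=9, sugars_g=20, sodium_mg=500,
                 fibre_g=0.5, protein_g=5, fvn_pct=85)
    s = score_item(item, tables)
    assert s.c_points_fvn == 5 and s.protein_counted
    assert s.score == 22 - 5 - 0 - 3


@pytest.mark.parametrize("item_class,score,expected", [
    ("food", 3, "healthy"), ("food", 4, "less_healthy"),
    ("beverage", 0, "healthy"), ("beverage", 1, "less_healthy"),
    ("food", 1, "healthy"),
    ("alcoholic_beverage", 30, "unscored"),
    ("alcoholic_beverage", -5, "unscored"),
])
def test_classification_thresholds(tables, item_class, score, expected):
    assert classify_item(score, item_class, tables) == expected


def test_classify_unknown_class_errors(tables):
    with pytest.raises(ConfigurationError):
        classify_item(5, "supplement", tables)


# ---------------------------------------------------------------------------
# catalogue scoring

def test_score_catalogue_empty_and_order(tables, toy_catalogue):
    assert len(score_catalogue([], tables)) == 0
    out = score_catalogue(toy_catalogue.drop(columns="fv_frac"), tables)
    assert list(out["item_id"]) == list(toy_catalogue["item_id"])
    assert out.loc[out["item_id"] == "AB", "classification"].item() == "unscored"


def test_score_catalogue_duplicate_ids(tables, toy_catalogue):
    cat = pd.concat([toy_catalogue, toy_catalogue.iloc[[0]]])
    with pytest.raises(ValidationError, match="LF"):
        score_catalogue(cat.drop(columns="fv_frac"), tables)


def test_negative_nutrient_names_item_and_field():
    with pytest.raises(InputDomainError, match=r"bad.*sodium_mg"):
        _comp(item_id="bad", sodium_mg=-2)


def test_oracle_equivalence_sample(tables):
    """score_item agrees exactly with the naive threshold-count oracle."""
    cat = random_compositions(2000, seed=42)
    out = score_catalogue(cat, tables)
    for row, (_, res) in zip(cat.to_dict("records"), out.iterrows()):
        exp_score, exp_cls = oracle_score_and_class(row, row["item_class"],
                                                    tables)
        assert res["score"] == exp_score
        assert res["classification"] == exp_cls


# ---------------------------------------------------------------------------
# properties

a_nutrients = st.sampled_from(["energy_kj", "satfat_g", "sugars_g",
                               "sodium_mg"])
c_nutrients = st.sampled_from(["fibre_g", "protein_g", "fvn_pct"])


@st.composite
def compositions(draw):
    return dict(
        energy_kj=draw(st.floats(0, 4000)), satfat_g=draw(st.floats(0, 30)),
        sugars_g=draw(st.floats(0, 80)), sodium_mg=draw(st.floats(0, 1500)),
        fibre_g=draw(st.floats(0, 8)), protein_g=draw(st.floats(0, 20)),
        fvn_pct=draw(st.floats(0, 100)))


@given(comp=compositions(), nutrient=a_nutrients,
       bump=st.floats(0.1, 500))
def test_increasing_a_nutrient_never_decreases_score(comp, nutrient, bump):
    t = ScoringTables.default()
    lo = score_item(_comp(**comp), t).score
    comp2 = dict(comp)
    comp2[nutrient] = comp2[nutrient] + bump
    hi = score_item(_comp(**comp2), t).score
    assert hi >= lo


@given(comp=compositions(), nutrient=c_nutrients, bump=st.floats(0.1, 40))
def test_increasing_c_nutrient_never_increases_score(comp, nutrient, bump):
    t = ScoringTables.default()
    lo = score_item(_comp(**comp), t).score
    comp2 = dict(comp)
    comp2[nutrient] = min(comp2[nutrient] + bump, 100) \
        if nutrient == "fvn_pct" else comp2[nutrient] + bump
    hi = score_item(_comp(**comp2), t).score
    assert hi <= lo


@given(comp=compositions(), protein=st.floats(0, 30))
def test_gated_score_independent_of_protein(comp, protein):
    t = ScoringTables.default()
    s = score_item(_comp(**comp), t)
    if s.a_total >= 11 and s.c_points_fvn < 5:
        comp2 = dict(comp)
        comp2["protein_g"] = protein
        assert score_item(_comp(**comp2), t).score == s.score
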