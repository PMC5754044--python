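import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from npcohort import ScoringTables

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def tables() -> ScoringTables:
    return ScoringTables.default()


@pytest.fixture()
def toy_catalogue() -> pd.DataFrame:
    """Four items with 100 kJ/100 g so that energy (kJ) equals grams."""
    return pd.DataFrame({
        "item_id": ["LF", "HF", "LB", "AB"],
        "name": ["lh food", "healthy food", "lh beverage", "beer"],
        "item_class": ["food", "food", "beverage", "alcoholic_beverage"],
        "energy_kj": [100.0] * 4,
        "satfat_g": [0.0] * 4, "sugars_g": [0.0] * 4,
        "sodium_mg": [0.0] * 4, "fibre_g": [0.0] * 4,
        "protein_g": [0.0] * 4,
        "fvn_pct": [0.0, 90.0, 0.0, 0.0],
        "fv_frac": [0.0, 0.9, 0.0, 0.0],
    })


@pytest.fixture()
def toy_scored() -> pd.DataFrame:
    """Hand-assigned scores/classes matching the toy catalogue."""
    return pd.DataFrame({
        "item_id": ["LF", "HF", "LB", "AB"],
        "score": [7, -2, 2, 0],
        "classification": ["less_healthy", "healthy", "less_healthy",
                           "unscored"],
    })


def toy_diary(rows):
    return pd.DataFrame(rows, columns=["participant_id", "day_index",
                                       "item_id", "grams"])


@pytest.fixture()
def worked_diary() -> pd.DataFrame:
    """One day: 2000 kJ less-healthy food, 1500 healthy food, 500
    less-healthy beverage, 400 alcoholic."""
    return toy_diary([("p1", 1, "LF", 2000.0), ("p1", 1, "HF", 1500.0),
                      ("p1", 1, "LB", 500.0), ("p1", 1, "AB", 400.0)])


@pytest.fixture()
def participant_frame():
    """A small complete participant table factory."""
    def make(n, seed=0, **overrides):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "participant_id": [f"p{i:04d}" for i in range(n)],
            "age": rng.uniform(40, 79, n).round(1),
            "sex": np.where(rng.random(n) < 0.45, "male", "female"),
            "weight_kg": rng.uniform(50, 100, n).round(1),
            "bmi": rng.uniform(19, 35, n).round(1),
            "education": rng.integers(0, 4, n).astype(float),
            "smoking": rng.choice(["never", "former", "current"], n),
            "activity": rng.integers(0, 4, n).astype(float),
            "alcohol_units": rng.gamma(1.2, 1.3, n).round(2),
            **{c: rng.integers(0, 2, n)
               for c in ("bp_medication", "lipid_medication", "diabetes",
                         "hypertension", "hypercholesterolemia",
                         "past_cancer", "fh_mi", "fh_stroke", "fh_diabetes")},
            "angina": np.zeros(n, dtype=int),
            "heart_attack": np.zeros(n, dtype=int),
            "stroke": np.zeros(n, dtype=int),
        })
        for k, v in overrides.items():
            df[k] = v
        return df
    return make
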