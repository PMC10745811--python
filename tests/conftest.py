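import numpy as np
import pandas as pd
import pytest

from frailmicro.frailty import score_cohort
from frailmicro.io_model import Cohort
from frailmicro.simulate import GeneratorSpec, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (seed 0) shared across read-only tests."""
    cohort, truth = simulate_cohort(GeneratorSpec(rng_seed=0))
    return cohort, truth


@pytest.fixture(scope="session")
def default_scores(default_cohort):
    cohort, _ = default_cohort
    return score_cohort(cohort)


@pytest.fixture
def tiny_cohort():
    """Hand-written four-animal cohort with every table populated."""
    animals = pd.DataFrame({
        "animal_id": ["M1", "M2", "M3", "M4"],
        "genotype": ["wildtype", "wildtype", "5xFAD", "5xFAD"],
        "sex": ["female", "male", "female", "male"],
        "age_months": [4.0, 5.5, 12.0, 14.5],
        "body_weight_g": [24.0, 30.0, 26.0, 32.0],
    })
    items = pd.DataFrame({
        "animal_id": ["M1", "M2", "M3", "M4", "M1", "M2", "M3", "M4"],
        "item_name": ["hearing"] * 4 + ["alopecia"] * 4,
        "score": [1.0, 1.0, 0.5, 0.0, 1.0, 0.5, 1.0, 0.5],
    })
    trials = pd.DataFrame({
        "animal_id": ["M1"] * 3 + ["M2"] * 3 + ["M3"] * 3 + ["M4"] * 3,
        "task": ["cage_top"] * 12,
        "trial_index": [1, 2, 3] * 4,
        "outcome": ["fell", "fell", "held_full"] * 2 + ["fell"] * 6,
        "value": [50.0, 55.0, 60.0, 45.0, 50.0, 60.0,
                  20.0, 25.0, 30.0, 12.0, 15.0, 18.0],
    })
    microbes = pd.DataFrame({
        "animal_id": ["M1", "M2", "M3", "M4"],
        "group_name": ["Bacteroides"] * 4,
        "kind": ["value"] * 4,
        "value": [2e9, 3e9, 1e9, 0.5e9],
        "unit": ["bacteria_per_g"] * 4,
        "below_detection": [False] * 4,
    })
    return Cohort(animals=animals, items=items, trials=trials, microbes=microbes)


def make_scores_frame(rng: np.random.Generator, n_per_genotype: int = 40) -> pd.DataFrame:
    """Bare per-animal score table for association tests (no behaviour model)."""
    rows = []
    for g, prefix in (("wildtype", "WT"), ("5xFAD", "TG")):
        for k in range(n_per_genotype):
            age = rng.uniform(3, 16)
            frailty = 8 + 0.8 * age + rng.normal(0, 1.5)
            rows.append({
                "animal_id": f"{prefix}{k:03d}", "genotype": g,
                "sex": "female" if k % 2 == 0 else "male",
                "age_months": age, "mfs": np.nan, "pcs": np.nan,
                "fitness": np.nan, "frailty": frailty,
            })
    return pd.DataFrame(rows)
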