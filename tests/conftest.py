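"""Shared fixtures: a tiny hand-checkable population (FIXTURE-A) and a
small synthetic country used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mpikit import (
    GeneratorConfig,
    PipelineConfig,
    equal_nested_weights,
    run_pipeline,
)
from mpikit.specs import ASSET_ITEMS, ItemInventory
from mpikit.synthetic import FinitePopulation

#: defaults describe a fully non-deprived adult male in a one-person household
PERSON_DEFAULTS: dict = {
    "hh_id": 1, "person_id": 1, "stratum": 1, "psu": 1, "region": 1,
    "area": "rural", "age_years": 40, "age_months": 480, "sex": "m",
    "usual_member": 1, "weight": 1.0,
    "haz": np.nan, "waz": np.nan, "bmiz": np.nan, "bmi": 22.0,
    "yschool": 8.0, "attending": np.nan,
    "woman_death_any": np.nan, "woman_death_5y_u18": np.nan,
    "male_cm_report": 0.0,
    "fuel": "lpg", "toilet": "flush", "toilet_shared": 0.0,
    "water_source": "piped", "water_time": 5.0, "electricity": 1.0,
    "floor": "finished", "roof": "finished", "walls": "finished",
    "asset_radio": 1.0, "asset_tv": 1.0, "asset_car": 0.0,
    **{f"asset_{i}": 0.0 for i in ASSET_ITEMS if i not in ("radio", "tv")},
}


def make_wave(rows: list[dict]) -> pd.DataFrame:
    """Member-level frame from per-person overrides of the defaults."""
    return pd.DataFrame([{**PERSON_DEFAULTS, **row} for row in rows])


def fixture_a_rows() -> list[dict]:
    """Four single-member households on their own PSUs, unit weights.

    P1 deprived in nutrition + four living standards (c = 7/18, poor),
    P2 in schooling + electricity (c = 2/9, vulnerable),
    P3 in nutrition + child mortality (c = 1/3, exactly at the cutoff),
    P4 in nothing.
    """
    return [
        {"hh_id": 1, "psu": 1, "bmi": 17.0, "fuel": "charcoal",
         "toilet": "pit_open", "water_source": "surface_water", "electricity": 0.0},
        {"hh_id": 2, "psu": 2, "yschool": 4.0, "electricity": 0.0},
        {"hh_id": 3, "psu": 3, "sex": "f", "age_years": 30, "age_months": 360,
         "bmi": 17.0, "woman_death_any": 1.0, "woman_death_5y_u18": 1.0,
         "male_cm_report": np.nan},
        {"hh_id": 4, "psu": 4},
    ]


@pytest.fixture(scope="session")
def fixture_a_wave() -> pd.DataFrame:
    return make_wave(fixture_a_rows())


@pytest.fixture(scope="session")
def fixture_a_population(fixture_a_wave) -> FinitePopulation:
    return FinitePopulation(data=fixture_a_wave.drop(columns="weight"), n_households=4)


@pytest.fixture(scope="session")
def fixture_a_matrix(fixture_a_wave):
    from mpikit.indicators import assemble_matrix
    from mpikit.specs import default_specs

    return assemble_matrix(fixture_a_wave, default_specs(), equal_nested_weights())


@pytest.fixture(scope="session")
def scheme():
    return equal_nested_weights()


# --- a small two-wave synthetic country shared by results/acceptance tests ---

WAVE1_INVENTORY = ItemInventory()
WAVE2_INVENTORY = ItemInventory(
    nutrition_groups=frozenset({"u5"}),
    cm_death_dates=False,
    water_time=False,
    sanitation_shared=False,
    housing_components=frozenset({"floor", "roof"}),
    asset_items=frozenset(set(ASSET_ITEMS) - {"computer"}),
)


def small_generator_config(seed: int = 20260918, **over) -> GeneratorConfig:
    kw = dict(
        seed=seed,
        n_households=1000,
        design={"n_strata": 4, "psus_per_stratum": 3, "households_per_psu": 12,
                "weight_cv": 0.1},
        wave_inventories=(WAVE1_INVENTORY, WAVE2_INVENTORY),
        wave_years=("2010", "2014-2016"),
        n_regions=2,
    )
    kw.update(over)
    return GeneratorConfig(**kw)


@pytest.fixture(scope="session")
def pipeline_result():
    cfg = PipelineConfig(
        generator=small_generator_config(
            missingness_rates={"birth_history": 0.02, "toilet_shared": 0.03}
        )
    )
    return run_pipeline(cfg)


def random_matrix(rng: np.random.Generator, n: int, scheme) -> pd.DataFrame:
    """Random completed deprivation matrix with integer sampling weights."""
    from mpikit.afcore import dcol

    df = pd.DataFrame({dcol(j): rng.integers(0, 2, n).astype(float)
                       for j in scheme.indicators})
    df["weight"] = rng.integers(1, 5, n).astype(float)
    df["hh_id"] = np.arange(n)
    df["psu"] = np.arange(n) % max(2, n // 5)
    df["stratum"] = 1
    df["region"] = rng.integers(1, 4, n)
    return df
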