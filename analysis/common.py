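"""Shared configuration of the worked synthetic country used by the
numbered analysis scripts.

Every script regenerates its inputs deterministically from the seed below,
so the scripts can be run independently and in any order; tables land under
results/analysis/.
"""

from pathlib import Path

from mpikit import PipelineConfig
from mpikit.specs import ASSET_ITEMS, ItemInventory
from mpikit.synthetic import GeneratorConfig

SEED = 20230918
OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"

WAVE1 = ItemInventory()
#: the later wave lost adult anthropometry, death dates, the water round-trip
#: time, the shared-toilet flag, wall materials and the computer item
WAVE2 = ItemInventory(
    nutrition_groups=frozenset({"u5"}),
    cm_death_dates=False,
    water_time=False,
    sanitation_shared=False,
    housing_components=frozenset({"floor", "roof"}),
    asset_items=frozenset(set(ASSET_ITEMS) - {"computer"}),
)


def generator_config(seed: int = SEED) -> GeneratorConfig:
    return GeneratorConfig(
        seed=seed,
        n_households=2000,
        design={"n_strata": 4, "psus_per_stratum": 4, "households_per_psu": 12,
                "weight_cv": 0.1},
        pop_psu_size=25,
        wave_inventories=(WAVE1, WAVE2),
        wave_years=("2010", "2014-2016"),
        missingness_rates={"birth_history": 0.02, "toilet_shared": 0.03,
                           "yschool": 0.01},
        n_regions=2,
    )


def pipeline_config(seed: int = SEED) -> PipelineConfig:
    return PipelineConfig(generator=generator_config(seed), out_dir=str(OUT))
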