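"""Indicator vocabulary shared across the pipeline.

The global MPI comprises ten deprivation indicators in three equally weighted
dimensions: health (nutrition, child mortality), education (years of schooling,
school attendance) and living standards (cooking fuel, sanitation, drinking
water, electricity, housing, assets).  This module holds the indicator names,
dimension membership, the synthetic category code lists for household items,
and the :class:`IndicatorSpec` / :class:`ItemInventory` records that the
indicator builders and the harmonisation logic consume.

Category code lists are the package's own documented dialect; real DHS/MICS
recodes use survey-specific systems that are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

INDICATORS: tuple[str, ...] = (
    "nutr", "cm", "educ", "satt", "ckfl", "sani", "wtr", "elct", "hsg", "asst",
)

#: dimension code -> member indicators (health, education, living standards)
DIMENSIONS: dict[str, tuple[str, ...]] = {
    "hl": ("nutr", "cm"),
    "ed": ("educ", "satt"),
    "ls": ("ckfl", "sani", "wtr", "elct", "hsg", "asst"),
}

INDICATOR_LABELS: dict[str, str] = {
    "nutr": "Nutrition",
    "cm": "Child mortality",
    "educ": "Years of schooling",
    "satt": "School attendance",
    "ckfl": "Cooking fuel",
    "sani": "Sanitation",
    "wtr": "Drinking water",
    "elct": "Electricity",
    "hsg": "Housing",
    "asst": "Assets",
}

DIMENSION_OF: dict[str, str] = {
    ind: dim for dim, members in DIMENSIONS.items() for ind in members
}

DIMENSION_LABELS = {"hl": "Health", "ed": "Education", "ls": "Living standards"}

# ---------------------------------------------------------------------------
# Synthetic category code lists (documented dialect of the generator)
# ---------------------------------------------------------------------------

SOLID_FUELS = frozenset({"dung", "crop", "shrubs", "wood", "charcoal", "coal"})
CLEAN_FUELS = frozenset({"electricity", "lpg", "natural_gas", "biogas", "kerosene"})
FUEL_CODES = SOLID_FUELS | CLEAN_FUELS

IMPROVED_TOILETS = frozenset({"flush", "vip_latrine", "composting", "pit_latrine_slab"})
UNIMPROVED_TOILETS = frozenset({"pit_open", "bucket", "hanging", "open_defecation"})
TOILET_CODES = IMPROVED_TOILETS | UNIMPROVED_TOILETS

SAFE_WATER_SOURCES = frozenset(
    {"piped", "public_tap", "borehole", "protected_well", "protected_spring", "rainwater"}
)
UNSAFE_WATER_SOURCES = frozenset(
    {"unprotected_well", "unprotected_spring", "surface_water", "tanker", "cart_vendor"}
)
WATER_CODES = SAFE_WATER_SOURCES | UNSAFE_WATER_SOURCES

#: housing material quality codes
MATERIAL_CODES = frozenset({"finished", "rudimentary", "natural"})
HOUSING_COMPONENTS: tuple[str, ...] = ("floor", "roof", "walls")

#: the eight small asset items; car/truck is handled separately
ASSET_ITEMS: tuple[str, ...] = (
    "radio", "tv", "phone", "computer", "cart", "bike", "motorbike", "fridge",
)

#: nutrition eligibility groups (anthropometry measured for...)
NUTRITION_GROUPS: tuple[str, ...] = ("u5", "child", "adult_f", "adult_m")

# age bands (months) for anthropometry, per the global MPI definitions
U5_MAX_MONTHS = 60
CHILD_MIN_MONTHS, CHILD_MAX_MONTHS = 61, 228
ADULT_MIN_MONTHS, ADULT_MAX_MONTHS = 229, 840

WOMAN_MIN_AGE, WOMAN_MAX_AGE = 15, 49  # reproductive-age band for birth histories


@dataclass(frozen=True)
class IndicatorSpec:
    """Construction parameters for one deprivation indicator.

    A household is deprived per the global MPI definitions; the optional
    fields encode harmonisation variants (restricted eligible populations or
    restricted item sets).  ``threshold`` fields follow the published cutoffs:
    z-scores strictly below -2, adult BMI strictly below 18.5 kg/m2, fewer
    than six completed years of schooling, a water round trip of 30 minutes
    or longer, at most one small asset and no car.
    """

    name: str
    # nutrition
    nutrition_groups: frozenset[str] = frozenset(NUTRITION_GROUPS)
    zscore_cutoff: float = -2.0
    bmi_cutoff: float = 18.5
    # child mortality
    use_death_dates: bool = True
    # schooling
    years_cutoff: float = 6.0
    schooling_min_age: int = 10
    # attendance
    school_entry_age: int = 6
    # water
    use_water_time: bool = True
    water_time_cutoff: float = 30.0
    # sanitation
    use_shared_flag: bool = True
    # electricity
    universal_coverage: bool = False
    # housing
    housing_components: tuple[str, ...] = HOUSING_COMPONENTS
    # assets
    asset_items: tuple[str, ...] = ASSET_ITEMS
    asset_cutoff: int = 1

    def __post_init__(self) -> None:
        if self.name not in INDICATORS:
            raise ValueError(f"unknown indicator name {self.name!r}")
        if not (-4.0 <= self.zscore_cutoff <= 0.0):
            raise ValueError("z-score cutoff out of range")
        if not (10.0 <= self.bmi_cutoff <= 25.0):
            raise ValueError("BMI cutoff out of range")


def default_specs(school_entry_age: int = 6) -> dict[str, IndicatorSpec]:
    """Full (unharmonised) specs for all ten indicators."""
    return {
        name: IndicatorSpec(name=name, school_entry_age=school_entry_age)
        for name in INDICATORS
    }


@dataclass(frozen=True)
class ItemInventory:
    """What one survey wave collected, per indicator.

    Harmonisation compares inventories across a country's waves and restricts
    each indicator to the common domain (intersection of eligible populations
    and of collected items).
    """

    nutrition_groups: frozenset[str] = frozenset(NUTRITION_GROUPS)
    cm_death_dates: bool = True
    cm_male_report: bool = True
    water_time: bool = True
    sanitation_shared: bool = True
    housing_components: frozenset[str] = frozenset(HOUSING_COMPONENTS)
    asset_items: frozenset[str] = frozenset(ASSET_ITEMS)
    electricity_collected: bool = True

    def __post_init__(self) -> None:
        unknown = self.nutrition_groups - set(NUTRITION_GROUPS)
        if unknown:
            raise ValueError(f"unknown nutrition groups {sorted(unknown)}")
        if not self.nutrition_groups:
            raise ValueError("nutrition must have at least one measured group")
        if not self.housing_components:
            raise ValueError("housing inventory must retain at least one component")
        if not self.asset_items:
            raise ValueError("asset inventory must retain at least one item")


FULL_INVENTORY = ItemInventory()

__all__ = [
    "INDICATORS", "DIMENSIONS", "DIMENSION_OF", "INDICATOR_LABELS",
    "DIMENSION_LABELS", "SOLID_FUELS", "CLEAN_FUELS", "FUEL_CODES",
    "IMPROVED_TOILETS", "UNIMPROVED_TOILETS", "TOILET_CODES",
    "SAFE_WATER_SOURCES", "UNSAFE_WATER_SOURCES", "WATER_CODES",
    "MATERIAL_CODES", "HOUSING_COMPONENTS", "ASSET_ITEMS", "NUTRITION_GROUPS",
    "IndicatorSpec", "ItemInventory", "FULL_INVENTORY", "default_specs",
    "replace", "field",
]
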