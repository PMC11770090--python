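"""Cross-wave harmonisation: restrict indicators to the common domain.

Survey items and eligible populations vary between waves of one country.
For comparable trends each indicator is restricted to the intersection of
the waves' eligible populations and collected items, following the named
variant rules: child-only nutrition when adult anthropometry is not
universal (women-and-children when only male data is missing); any-death
child mortality when death dates are absent in some wave; source-only
drinking water when round-trip time is absent; type-only sanitation when
the shared flag is absent; housing from the materials present everywhere;
assets from the items consistently collected.  Region codes are mapped to a
harmonised frame through a per-wave correspondence table; regions marked
EXCLUDE stay in the sample but are suppressed at the region level only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import specs as sp

EXCLUDE = "EXCLUDE"


@dataclass(frozen=True)
class HarmonisationPlan:
    """Common-domain restriction shared by all waves of one country."""

    specs: dict[str, sp.IndicatorSpec]
    variants: dict[str, str]
    #: per-wave region correspondence: wave index -> {original code -> harmonised code or EXCLUDE}
    region_maps: dict[int, dict[object, object]] | None = None

    def is_identity(self, full_specs: dict[str, sp.IndicatorSpec] | None = None) -> bool:
        full_specs = full_specs or sp.default_specs(
            self.specs["satt"].school_entry_age
        )
        return self.specs == full_specs and self.region_maps is None


def identity_plan(school_entry_age: int = 6) -> HarmonisationPlan:
    return HarmonisationPlan(
        specs=sp.default_specs(school_entry_age),
        variants={j: "full" for j in sp.INDICATORS},
    )


def derive_plan(
    inventories: list[sp.ItemInventory],
    school_entry_age: int = 6,
    region_maps: dict[int, dict[object, object]] | None = None,
) -> HarmonisationPlan:
    """Intersect wave inventories into a single country plan.

    Raises if an included indicator is left with an empty common item set.
    """
    if len(inventories) < 2:
        raise ValueError("harmonisation requires at least two wave inventories")

    specs_out = sp.default_specs(school_entry_age)
    variants: dict[str, str] = {j: "full" for j in sp.INDICATORS}

    groups = frozenset.intersection(*(inv.nutrition_groups for inv in inventories))
    if not groups:
        raise ValueError("empty common domain for indicator: nutr")
    if groups != frozenset(sp.NUTRITION_GROUPS):
        if "u5" in groups and not (groups - {"u5"}):
            variants["nutr"] = "child_only_u5"
        elif "adult_m" not in groups:
            variants["nutr"] = "women_and_children"
        else:
            variants["nutr"] = "restricted"
        specs_out["nutr"] = replace(specs_out["nutr"], nutrition_groups=groups)

    if not all(inv.cm_death_dates for inv in inventories):
        variants["cm"] = "any_death"
        specs_out["cm"] = replace(specs_out["cm"], use_death_dates=False)

    if not all(inv.water_time for inv in inventories):
        variants["wtr"] = "source_only"
        specs_out["wtr"] = replace(specs_out["wtr"], use_water_time=False)

    if not all(inv.sanitation_shared for inv in inventories):
        variants["sani"] = "type_only"
        specs_out["sani"] = replace(specs_out["sani"], use_shared_flag=False)

    components = frozenset.intersection(*(inv.housing_components for inv in inventories))
    if not components:
        raise ValueError("empty common domain for indicator: hsg")
    if components != frozenset(sp.HOUSING_COMPONENTS):
        variants["hsg"] = "reduced_materials"
        specs_out["hsg"] = replace(
            specs_out["hsg"],
            housing_components=tuple(c for c in sp.HOUSING_COMPONENTS if c in components),
        )

    items = frozenset.intersection(*(inv.asset_items for inv in inventories))
    if not items:
        raise ValueError("empty common domain for indicator: asst")
    if items != frozenset(sp.ASSET_ITEMS):
        variants["asst"] = "common_items"
        specs_out["asst"] = replace(
            specs_out["asst"],
            asset_items=tuple(a for a in sp.ASSET_ITEMS if a in items),
        )

    if not all(inv.electricity_collected for inv in inventories):
        # item absent because of universal coverage: all households non-deprived
        variants["elct"] = "universal_coverage"
        specs_out["elct"] = replace(specs_out["elct"], universal_coverage=True)

    return HarmonisationPlan(specs=specs_out, variants=variants, region_maps=region_maps)


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def _mask_nutrition(wave: pd.DataFrame, groups: frozenset[str]) -> None:
    m = wave["age_months"].to_numpy(dtype=float)
    sex = wave["sex"].to_numpy()
    if "u5" not in groups:
        u5 = m <= sp.U5_MAX_MONTHS
        wave.loc[u5, ["haz", "waz"]] = np.nan
    if "child" not in groups:
        child = (m >= sp.CHILD_MIN_MONTHS) & (m <= sp.CHILD_MAX_MONTHS)
        wave.loc[child, "bmiz"] = np.nan
    adult = (m >= sp.ADULT_MIN_MONTHS) & (m <= sp.ADULT_MAX_MONTHS)
    if "adult_f" not in groups:
        wave.loc[adult & (sex == "f"), "bmi"] = np.nan
    if "adult_m" not in groups:
        wave.loc[adult & (sex == "m"), "bmi"] = np.nan


def apply_plan(
    wave: pd.DataFrame,
    plan: HarmonisationPlan,
    wave_index: int | None = None,
) -> tuple[pd.DataFrame, dict[str, sp.IndicatorSpec]]:
    """Mask out-of-domain data and return the wave with the restricted specs.

    Building indicators from the masked wave under the restricted specs is
    exactly equivalent to building from the raw wave under the restricted
    specs: the restricted specs never look at masked values (verified by the
    commutation property tests).  Region codes are mapped to the harmonised
    frame; EXCLUDE regions receive ``region_excluded = True`` and are
    suppressed at the region level of analysis only.
    """
    wave = wave.copy()
    specs_r = plan.specs

    _mask_nutrition(wave, specs_r["nutr"].nutrition_groups)
    if not specs_r["cm"].use_death_dates:
        wave["woman_death_5y_u18"] = np.nan
    if not specs_r["wtr"].use_water_time:
        wave["water_time"] = np.nan
    if not specs_r["sani"].use_shared_flag:
        wave["toilet_shared"] = np.nan
    for comp in sp.HOUSING_COMPONENTS:
        if comp not in specs_r["hsg"].housing_components:
            wave[comp] = np.nan
    for item in sp.ASSET_ITEMS:
        if item not in specs_r["asst"].asset_items:
            wave[f"asset_{item}"] = np.nan

    wave["region_excluded"] = False
    if plan.region_maps is not None:
        if wave_index is None:
            raise ValueError("wave_index required when the plan carries region maps")
        mapping = plan.region_maps.get(wave_index)
        if mapping is None:
            raise ValueError(f"plan has no region correspondence for wave {wave_index}")
        codes = set(wave["region"].unique())
        unmapped = codes - set(mapping)
        if unmapped:
            raise ValueError(f"region codes not in correspondence map: {sorted(map(str, unmapped))}")
        mapped = wave["region"].map(mapping)
        wave["region_excluded"] = (mapped == EXCLUDE).to_numpy()
        wave["region"] = mapped.where(~wave["region_excluded"], wave["region"])

    return wave, specs_r


def read_region_correspondence(path) -> dict[int, dict[object, object]]:
    """Read a 3-column (wave, original, harmonised) correspondence table."""
    tab = pd.read_csv(path)
    expected = {"wave", "original", "harmonised"}
    if set(map(str.lower, tab.columns)) != expected:
        raise ValueError(f"correspondence table needs columns {sorted(expected)}")
    tab.columns = [c.lower() for c in tab.columns]
    out: dict[int, dict[object, object]] = {}
    for w, sub in tab.groupby("wave"):
        out[int(w)] = dict(zip(sub["original"], sub["harmonised"]))
    return out
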