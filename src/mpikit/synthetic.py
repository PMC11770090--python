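"""Synthetic household-survey microdata with known census truth.

Real inputs to the poverty pipeline are restricted DHS/MICS recode files
that cannot be redistributed.  This module generates finite populations and
multi-wave survey samples that emulate the statistical structure the
pipeline assumes: household rosters with age/sex structure and usual-member
flags, household-level deprivation propensities with within-household
correlation across indicators (one Gaussian latent factor per household),
stratified two-stage cluster sampling with unequal weights, wave-to-wave
differences in item availability and eligible populations, and MCAR item
missingness.

Census truth (:func:`compute_truth`) is enumerated household by household
and person by person in plain Python, independently of the vectorised
measurement path, so that it can serve as an oracle for parameter-recovery
and unbiasedness checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.stats import norm

from . import specs as sp
from .afcore import AnalysisParams, WeightScheme, dcol, equal_nested_weights
from .harmonise import _mask_nutrition

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

#: default household-size distribution over 1..12 (mean ~4.6 members)
DEFAULT_HH_SIZE_DIST: dict[int, float] = {
    1: 0.06, 2: 0.11, 3: 0.15, 4: 0.18, 5: 0.16, 6: 0.12,
    7: 0.09, 8: 0.06, 9: 0.03, 10: 0.02, 11: 0.01, 12: 0.01,
}

#: age-band weights (uniform within band); bands cover 0-95 years
DEFAULT_AGE_STRUCTURE: dict[str, float] = {
    "0-4": 0.11, "5-9": 0.11, "10-17": 0.17, "18-59": 0.52, "60-95": 0.09,
}

#: household deprivation propensities typical of a high-poverty setting
DEFAULT_PROPENSITIES: dict[str, float] = {
    "nutr": 0.40, "cm": 0.08, "educ": 0.30, "satt": 0.20, "ckfl": 0.65,
    "sani": 0.50, "wtr": 0.25, "elct": 0.30, "hsg": 0.55, "asst": 0.30,
}


class DesignConfig(BaseModel):
    """Two-stage stratified cluster design of the sample to be drawn."""

    n_strata: int = Field(default=8, ge=1)
    psus_per_stratum: int = Field(default=4, ge=1)
    households_per_psu: int = Field(default=15, ge=1)
    weight_cv: float = Field(default=0.15, ge=0.0)


class GeneratorConfig(BaseModel):
    """Stated world of the generator; ``seed`` is mandatory.

    Defaults describe a single high-poverty country: ~4000 households of
    mean size ~4.6, eight design strata in four reporting regions, 35%
    urban PSUs, and the deprivation propensities above with a latent-factor
    loading of 0.5 inducing within-household correlation of deprivations.
    """

    n_households: int = Field(default=4000, ge=1)
    hh_size_dist: dict[int, float] = Field(default_factory=lambda: dict(DEFAULT_HH_SIZE_DIST))
    age_structure: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_AGE_STRUCTURE))
    indicator_propensities: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_PROPENSITIES)
    )
    household_correlation: float = Field(default=0.5, ge=0.0, lt=1.0)
    design: DesignConfig = Field(default_factory=DesignConfig)
    wave_inventories: tuple[sp.ItemInventory, ...] = ()
    wave_years: tuple[str, ...] = ("2010", "2015")
    missingness_rates: dict[str, float] = Field(default_factory=dict)
    school_entry_age: int = Field(default=6, ge=4, le=8)
    seed: int

    # structural extras of the stated world
    pop_psu_size: int = Field(default=40, ge=2)
    n_regions: int = Field(default=4, ge=1)
    urban_share: float = Field(default=0.35, ge=0.0, le=1.0)
    non_usual_rate: float = Field(default=0.03, ge=0.0, le=1.0)
    male_report_rate: float = Field(default=1.0, ge=0.0, le=1.0)
    old_death_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    wave2_propensity_shift: float = Field(default=-0.05, ge=-0.5, le=0.5)

    model_config = {"arbitrary_types_allowed": True}

    @field_validator("hh_size_dist", "age_structure")
    @classmethod
    def _dist_sums_to_one(cls, v: dict) -> dict:
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"distribution probabilities sum to {total}, expected 1")
        if any(p < 0 for p in v.values()):
            raise ValueError("distribution probabilities must be non-negative")
        return v

    @field_validator("indicator_propensities", "missingness_rates")
    @classmethod
    def _probs_in_unit_interval(cls, v: dict) -> dict:
        for key, p in v.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability for {key!r} is {p}, outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _known_indicators(self) -> "GeneratorConfig":
        unknown = set(self.indicator_propensities) - set(sp.INDICATORS)
        if unknown:
            raise ValueError(f"unknown indicators in propensities: {sorted(unknown)}")
        return self


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FinitePopulation:
    """Member-level census records of one wave's source population."""

    data: pd.DataFrame
    n_households: int

    @property
    def census_size(self) -> int:
        return int(len(self.data))


@dataclass
class MicrodataWave:
    """One sampled country-year: member-level rows with design variables."""

    data: pd.DataFrame
    survey: str = "SYN"
    year: str = "2010"
    t: int = 1
    inventory: sp.ItemInventory = sp.FULL_INVENTORY


@dataclass
class TruthRecord:
    """Census values (population enumeration, no sampling) of all measures."""

    h: float
    a: float | None
    m0: float
    sev: float
    vuln: float
    hd: dict[str, float]
    hdk: dict[str, float]
    n: int
    k: float
    subgroups: dict[str, dict[object, "TruthRecord"]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def _parse_band(band: str) -> tuple[int, int]:
    lo, hi = band.split("-")
    return int(lo), int(hi)


def _draw_ages(rng: np.random.Generator, structure: dict[str, float], n: int) -> np.ndarray:
    bands = list(structure)
    probs = np.array([structure[b] for b in bands])
    idx = rng.choice(len(bands), size=n, p=probs / probs.sum())
    ages = np.empty(n, dtype=int)
    for i, band in enumerate(bands):
        lo, hi = _parse_band(band)
        mask = idx == i
        ages[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    return ages


def _pick_one_per_household(
    rng: np.random.Generator, hh_id: np.ndarray, eligible: np.ndarray
) -> np.ndarray:
    """Boolean mask selecting one random eligible member per household."""
    priority = rng.random(len(hh_id))
    frame = pd.DataFrame({"hh": hh_id, "p": np.where(eligible, priority, -1.0)})
    best = frame.groupby("hh")["p"].transform("max")
    return eligible & (frame["p"].to_numpy() == best.to_numpy()) & (best.to_numpy() >= 0)


def generate_population(
    config: GeneratorConfig,
    seed: int | None = None,
    propensity_shift: float = 0.0,
) -> FinitePopulation:
    """Draw a finite population whose household deprivation probabilities
    equal the configured propensities (before eligibility forcing).

    A household is latently deprived in indicator j iff
    Phi(rho z_h + sqrt(1-rho^2) e_hj) < p_j with z_h a shared household
    factor; raw achievement variables are then filled consistently with the
    latent statuses.  Households lacking eligible members for an indicator
    end up non-deprived regardless of the latent draw, so realised census
    truth comes from :func:`compute_truth`, not from the propensities.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_hh = config.n_households

    sizes_support = np.array(sorted(config.hh_size_dist))
    size_probs = np.array([config.hh_size_dist[s] for s in sizes_support], dtype=float)
    sizes = rng.choice(sizes_support, size=n_hh, p=size_probs / size_probs.sum())

    hh_id = np.repeat(np.arange(1, n_hh + 1), sizes)
    n = len(hh_id)
    person_id = np.concatenate([np.arange(1, s + 1) for s in sizes])

    ages = _draw_ages(rng, config.age_structure, n)
    ages[person_id == 1] = rng.integers(18, 60, size=n_hh)  # head of household is an adult
    months = np.minimum(ages * 12 + rng.integers(0, 12, size=n), 95 * 12)
    sex = np.where(rng.random(n) < 0.5, "f", "m")
    usual = (rng.random(n) >= config.non_usual_rate) | (person_id == 1)

    # design structure: households in strata, chunked into population PSUs
    stratum = (hh_id - 1) * config.design.n_strata // n_hh + 1
    region = (stratum - 1) * config.n_regions // config.design.n_strata + 1
    hh_strat = (np.arange(n_hh) * config.design.n_strata) // n_hh + 1
    psu_of_hh = np.empty(n_hh, dtype=int)
    next_psu = 1
    for s in range(1, config.design.n_strata + 1):
        members = np.flatnonzero(hh_strat == s)
        n_psu = max(1, int(np.ceil(len(members) / config.pop_psu_size)))
        psu_of_hh[members] = next_psu + (np.arange(len(members)) % n_psu)
        next_psu += n_psu
    psu = psu_of_hh[hh_id - 1]
    psu_ids = np.unique(psu_of_hh)
    urban_psu = dict(zip(psu_ids, rng.random(len(psu_ids)) < config.urban_share))
    area = np.where([urban_psu[p] for p in psu], "urban", "rural")

    # latent household deprivation statuses
    rho = config.household_correlation
    z_h = rng.standard_normal(n_hh)
    deprived: dict[str, np.ndarray] = {}
    for j in sp.INDICATORS:
        p = config.indicator_propensities.get(j, 0.0) + propensity_shift
        p = float(np.clip(p, 0.0, 1.0))
        e = rng.standard_normal(n_hh)
        u = rho * z_h + np.sqrt(1.0 - rho**2) * e
        deprived[j] = norm.cdf(u) < p

    df = pd.DataFrame({
        "hh_id": hh_id, "person_id": person_id, "stratum": stratum,
        "psu": psu, "region": region, "area": area,
        "age_years": ages, "age_months": months, "sex": sex,
        "usual_member": usual.astype(int),
    })
    dep_member = {j: deprived[j][hh_id - 1] for j in sp.INDICATORS}

    _fill_health(df, rng, dep_member, config)
    _fill_education(df, rng, dep_member, config)
    _fill_living_standards(df, rng, deprived, config)
    return FinitePopulation(data=df, n_households=n_hh)


def _fill_health(df, rng, dep, config):
    n = len(df)
    m = df["age_months"].to_numpy()
    sex = df["sex"].to_numpy()
    usual = df["usual_member"].to_numpy().astype(bool)
    u5 = m <= sp.U5_MAX_MONTHS
    child = (m >= sp.CHILD_MIN_MONTHS) & (m <= sp.CHILD_MAX_MONTHS)
    adult = (m >= sp.ADULT_MIN_MONTHS) & (m <= sp.ADULT_MAX_MONTHS)

    haz = np.where(u5, rng.uniform(-1.9, 2.0, n), np.nan)
    waz = np.where(u5, rng.uniform(-1.9, 2.0, n), np.nan)
    bmiz = np.where(child, rng.uniform(-1.9, 2.0, n), np.nan)
    bmi = np.where(adult, rng.uniform(18.7, 30.0, n), np.nan)

    elig = (u5 | child | adult) & usual
    chosen = _pick_one_per_household(rng, df["hh_id"].to_numpy(), elig) & dep["nutr"]
    haz[chosen & u5] = rng.uniform(-4.0, -2.05, int((chosen & u5).sum()))
    bmiz[chosen & child] = rng.uniform(-4.0, -2.05, int((chosen & child).sum()))
    bmi[chosen & adult] = rng.uniform(14.0, 18.3, int((chosen & adult).sum()))
    df["haz"], df["waz"], df["bmiz"], df["bmi"] = haz, waz, bmiz, bmi

    # birth histories for women 15-49
    age = df["age_years"].to_numpy()
    woman = (sex == "f") & (age >= sp.WOMAN_MIN_AGE) & (age <= sp.WOMAN_MAX_AGE) & usual
    death_any = np.where(woman, (rng.random(n) < config.old_death_rate).astype(float), np.nan)
    death_recent = np.where(woman, 0.0, np.nan)
    chosen_w = _pick_one_per_household(rng, df["hh_id"].to_numpy(), woman) & dep["cm"]
    death_recent[chosen_w] = 1.0
    death_any[chosen_w] = 1.0
    df["woman_death_any"], df["woman_death_5y_u18"] = death_any, death_recent

    # household-level male report: "no child mortality" unless a woman reported a death
    hh_any = pd.Series(death_any).groupby(df["hh_id"].to_numpy()).max()
    report = hh_any.fillna(0.0).clip(0.0, 1.0)
    present = rng.random(len(report)) < config.male_report_rate
    report = report.where(pd.Series(present, index=report.index), np.nan)
    df["male_cm_report"] = df["hh_id"].map(report).to_numpy()


def _fill_education(df, rng, dep, config):
    n = len(df)
    age = df["age_years"].to_numpy()
    usual = df["usual_member"].to_numpy().astype(bool)
    elig = (age >= 10) & usual
    ys = np.where(elig, rng.integers(0, 6, n).astype(float), np.nan)
    achiever = _pick_one_per_household(rng, df["hh_id"].to_numpy(), elig) & ~dep["educ"]
    ys[achiever] = rng.integers(6, 13, int(achiever.sum()))
    # non-deprived households may have further achievers
    extra = elig & ~dep["educ"] & (rng.random(n) < 0.35) & ~achiever
    ys[extra] = rng.integers(6, 13, int(extra.sum()))
    df["yschool"] = ys

    entry = config.school_entry_age
    school_age = (age >= entry) & (age < entry + 8) & usual
    att = np.where(school_age, 1.0, np.nan)
    out_child = _pick_one_per_household(rng, df["hh_id"].to_numpy(), school_age) & dep["satt"]
    att[out_child] = 0.0
    df["attending"] = att


def _choose(rng, options: tuple, size: int) -> np.ndarray:
    return np.asarray(options, dtype=object)[rng.integers(0, len(options), size)]


def _fill_living_standards(df, rng, deprived, config):
    n_hh = config.n_households
    solid = tuple(sorted(sp.SOLID_FUELS))
    clean = tuple(sorted(sp.CLEAN_FUELS))
    improved = tuple(sorted(sp.IMPROVED_TOILETS))
    unimproved = tuple(sorted(sp.UNIMPROVED_TOILETS))
    safe = tuple(sorted(sp.SAFE_WATER_SOURCES))
    unsafe = tuple(sorted(sp.UNSAFE_WATER_SOURCES))

    fuel = np.where(deprived["ckfl"], _choose(rng, solid, n_hh), _choose(rng, clean, n_hh))

    toilet = _choose(rng, improved, n_hh)
    shared = np.zeros(n_hh)
    dep_sani = deprived["sani"]
    via_unimproved = dep_sani & (rng.random(n_hh) < 0.5)
    toilet[via_unimproved] = _choose(rng, unimproved, int(via_unimproved.sum()))
    shared[via_unimproved] = rng.integers(0, 2, int(via_unimproved.sum()))
    via_shared = dep_sani & ~via_unimproved
    shared[via_shared] = 1.0

    source = _choose(rng, safe, n_hh)
    wtime = rng.uniform(1.0, 29.5, n_hh)
    dep_w = deprived["wtr"]
    via_unsafe = dep_w & (rng.random(n_hh) < 0.6)
    source[via_unsafe] = _choose(rng, unsafe, int(via_unsafe.sum()))
    wtime[via_unsafe] = rng.uniform(5.0, 120.0, int(via_unsafe.sum()))
    via_far = dep_w & ~via_unsafe
    wtime[via_far] = rng.uniform(30.5, 180.0, int(via_far.sum()))

    electricity = (~deprived["elct"]).astype(float)

    floor = np.full(n_hh, "finished", dtype=object)
    roof = np.full(n_hh, "finished", dtype=object)
    walls = np.full(n_hh, "finished", dtype=object)
    comp_pick = rng.integers(0, 3, n_hh)
    dep_h = deprived["hsg"]
    floor[dep_h & (comp_pick == 0)] = "natural"
    roof[dep_h & (comp_pick == 1)] = _choose(
        rng, ("natural", "rudimentary"), int((dep_h & (comp_pick == 1)).sum())
    )
    walls[dep_h & (comp_pick == 2)] = _choose(
        rng, ("natural", "rudimentary"), int((dep_h & (comp_pick == 2)).sum())
    )

    items = {item: np.zeros(n_hh) for item in sp.ASSET_ITEMS}
    car = np.zeros(n_hh)
    dep_a = deprived["asst"]
    one_item = dep_a & (rng.random(n_hh) < 0.5)
    pick = rng.integers(0, len(sp.ASSET_ITEMS), n_hh)
    for idx, item in enumerate(sp.ASSET_ITEMS):
        items[item][one_item & (pick == idx)] = 1.0
    rich = ~dep_a
    has_car = rich & (rng.random(n_hh) < 0.15)
    car[has_car] = 1.0
    counts = rng.integers(2, 7, n_hh)
    for h in np.flatnonzero(rich):
        owned = rng.choice(len(sp.ASSET_ITEMS), size=min(counts[h], 8), replace=False)
        for idx in owned:
            items[sp.ASSET_ITEMS[idx]][h] = 1.0

    hh_idx = df["hh_id"].to_numpy() - 1
    df["fuel"] = fuel[hh_idx]
    df["toilet"] = toilet[hh_idx]
    df["toilet_shared"] = shared[hh_idx]
    df["water_source"] = source[hh_idx]
    df["water_time"] = wtime[hh_idx]
    df["electricity"] = electricity[hh_idx]
    df["floor"] = floor[hh_idx]
    df["roof"] = roof[hh_idx]
    df["walls"] = walls[hh_idx]
    for item in sp.ASSET_ITEMS:
        df[f"asset_{item}"] = items[item][hh_idx]
    df["asset_car"] = car[hh_idx]


# ---------------------------------------------------------------------------
# census truth by person-by-person enumeration
# ---------------------------------------------------------------------------

def _truth_household_status(hh: pd.DataFrame, specs: dict[str, sp.IndicatorSpec]) -> dict[str, int]:
    """Plain-Python Table-1 logic for one complete household (truth oracle)."""
    members = hh.to_dict("records")
    first = members[0]
    out: dict[str, int] = {}

    nspec = specs["nutr"]
    under = False
    for p in members:
        mo = p["age_months"]
        if mo <= sp.U5_MAX_MONTHS and "u5" in nspec.nutrition_groups:
            if (not np.isnan(p["haz"]) and p["haz"] < nspec.zscore_cutoff) or (
                not np.isnan(p["waz"]) and p["waz"] < nspec.zscore_cutoff
            ):
                under = True
        elif sp.CHILD_MIN_MONTHS <= mo <= sp.CHILD_MAX_MONTHS and "child" in nspec.nutrition_groups:
            if not np.isnan(p["bmiz"]) and p["bmiz"] < nspec.zscore_cutoff:
                under = True
        elif sp.ADULT_MIN_MONTHS <= mo <= sp.ADULT_MAX_MONTHS:
            group = "adult_f" if p["sex"] == "f" else "adult_m"
            if group in nspec.nutrition_groups and not np.isnan(p["bmi"]) and p["bmi"] < nspec.bmi_cutoff:
                under = True
    out["nutr"] = int(under)

    cm_col = "woman_death_5y_u18" if specs["cm"].use_death_dates else "woman_death_any"
    death = False
    for p in members:
        if p["sex"] == "f" and sp.WOMAN_MIN_AGE <= p["age_years"] <= sp.WOMAN_MAX_AGE:
            if not np.isnan(p[cm_col]) and p[cm_col] == 1.0:
                death = True
    if not death and not specs["cm"].use_death_dates:
        male = first["male_cm_report"]
        if not np.isnan(male) and male == 1.0:
            death = True
    out["cm"] = int(death)

    espec = specs["educ"]
    achiever = any(
        p["age_years"] >= espec.schooling_min_age
        and not np.isnan(p["yschool"]) and p["yschool"] >= espec.years_cutoff
        for p in members
    )
    eligible = any(p["age_years"] >= espec.schooling_min_age for p in members)
    out["educ"] = int(eligible and not achiever)

    aspec = specs["satt"]
    entry = aspec.school_entry_age
    out_of_school = any(
        entry <= p["age_years"] < entry + 8
        and not np.isnan(p["attending"]) and p["attending"] == 0.0
        for p in members
    )
    out["satt"] = int(out_of_school)

    out["ckfl"] = int(first["fuel"] in sp.SOLID_FUELS)

    sspec = specs["sani"]
    unimp = first["toilet"] in sp.UNIMPROVED_TOILETS
    shared = sspec.use_shared_flag and not np.isnan(first["toilet_shared"]) and first["toilet_shared"] == 1.0
    out["sani"] = int(unimp or shared)

    wspec = specs["wtr"]
    unsafe = first["water_source"] in sp.UNSAFE_WATER_SOURCES
    far = (
        wspec.use_water_time
        and not np.isnan(first["water_time"])
        and first["water_time"] >= wspec.water_time_cutoff
    )
    out["wtr"] = int(unsafe or far)

    out["elct"] = 0 if specs["elct"].universal_coverage else int(first["electricity"] == 0.0)

    bad = False
    for comp in specs["hsg"].housing_components:
        mat = first[comp]
        if comp == "floor":
            bad = bad or mat == "natural"
        else:
            bad = bad or mat in ("natural", "rudimentary")
    out["hsg"] = int(bad)

    aspec2 = specs["asst"]
    owned = sum(
        1 for item in aspec2.asset_items
        if not np.isnan(first[f"asset_{item}"]) and first[f"asset_{item}"] == 1.0
    )
    has_car = not np.isnan(first["asset_car"]) and first["asset_car"] == 1.0
    out["asst"] = int(owned <= aspec2.asset_cutoff and not has_car)
    return out


def _enumerate_truth(
    person_scores: list[tuple[Fraction, dict[str, int]]],
    scheme: WeightScheme,
    k: float,
    params: AnalysisParams,
) -> TruthRecord:
    n = len(person_scores)
    kf = Fraction(k).limit_denominator(10**6)
    sev_cut = Fraction(params.severity_cutoff).limit_denominator(10**6)
    vuln_lo = Fraction(params.vulnerability_lower).limit_denominator(10**6)
    q = 0
    c_sum_poor = Fraction(0)
    n_sev = 0
    n_vuln = 0
    hd = {j: 0 for j in scheme.indicators}
    hdk = {j: 0 for j in scheme.indicators}
    for c, dep in person_scores:
        poor = c >= kf
        if poor:
            q += 1
            c_sum_poor += c
        if c >= sev_cut:
            n_sev += 1
        if vuln_lo <= c < kf:
            n_vuln += 1
        for j in scheme.indicators:
            hd[j] += dep[j]
            if poor:
                hdk[j] += dep[j]
    h = float(Fraction(q, n)) * 100.0
    a = float(c_sum_poor / q) * 100.0 if q else None
    m0 = float(c_sum_poor / n)
    return TruthRecord(
        h=h, a=a, m0=m0,
        sev=float(Fraction(n_sev, n)) * 100.0,
        vuln=float(Fraction(n_vuln, n)) * 100.0,
        hd={j: float(Fraction(hd[j], n)) * 100.0 for j in scheme.indicators},
        hdk={j: float(Fraction(hdk[j], n)) * 100.0 for j in scheme.indicators},
        n=n, k=k,
    )


def compute_truth(
    pop: FinitePopulation,
    k: float = 1.0 / 3.0,
    scheme: WeightScheme | None = None,
    specs: dict[str, sp.IndicatorSpec] | None = None,
    subgroup_cols: tuple[str, ...] = (),
    params: AnalysisParams | None = None,
) -> TruthRecord:
    """Census truth by direct person-by-person enumeration.

    Requires a complete population (no injected missingness); usual members
    only.  Exact rational arithmetic inside, so the truth identities
    (M0 = H x A / 1e4, M0 = sum_j w_j hdk_j / 100) hold to float precision.
    """
    scheme = scheme or equal_nested_weights()
    specs = specs or sp.default_specs()
    params = params or AnalysisParams(k=k)
    data = pop.data[pop.data["usual_member"].astype(bool)]

    wf = {j: Fraction(scheme.weights[j]).limit_denominator(10**6) for j in scheme.indicators}
    person_scores: list[tuple[Fraction, dict[str, int]]] = []
    person_groups: list[dict[str, object]] = []
    for _, hh in data.groupby("hh_id", sort=True):
        dep = _truth_household_status(hh, specs)
        c = sum((wf[j] * dep[j] for j in scheme.indicators), Fraction(0))
        person_scores.extend([(c, dep)] * len(hh))
        if subgroup_cols:
            person_groups.extend(hh[list(subgroup_cols)].to_dict("records"))

    record = _enumerate_truth(person_scores, scheme, k, params)
    for col in subgroup_cols:
        groups: dict[object, TruthRecord] = {}
        values = sorted({g[col] for g in person_groups})
        for val in values:
            subset = [ps for ps, g in zip(person_scores, person_groups) if g[col] == val]
            groups[val] = _enumerate_truth(subset, scheme, k, params)
        record.subgroups[col] = groups
    return record


def brute_force_measures(
    matrix: pd.DataFrame,
    scheme: WeightScheme,
    params: AnalysisParams | None = None,
    weight_col: str = "weight",
) -> dict[str, float | None]:
    """Person-by-person weighted enumeration of all measures on a completed
    deprivation matrix; the independent oracle for the vectorised path."""
    params = params or AnalysisParams()
    W = 0.0
    q_w = 0.0
    c_sum = 0.0
    sev_w = 0.0
    vuln_w = 0.0
    hd = {j: 0.0 for j in scheme.indicators}
    hdk = {j: 0.0 for j in scheme.indicators}
    from .afcore import K_TOL

    for _, row in matrix.iterrows():
        w = float(row[weight_col])
        c = sum(scheme.weights[j] * float(row[dcol(j)]) for j in scheme.indicators)
        W += w
        poor = c >= params.k - K_TOL
        if poor:
            q_w += w
            c_sum += w * c
        if c >= params.severity_cutoff - K_TOL:
            sev_w += w
        if params.vulnerability_lower - K_TOL <= c < params.k - K_TOL:
            vuln_w += w
        for j in scheme.indicators:
            d = float(row[dcol(j)])
            hd[j] += w * d
            if poor:
                hdk[j] += w * d

    out: dict[str, float | None] = {
        "H": q_w / W * 100.0,
        "A": c_sum / q_w * 100.0 if q_w > 0 else None,
        "M0": c_sum / W,
        "sev": sev_w / W * 100.0,
        "vuln": vuln_w / W * 100.0,
    }
    for j in scheme.indicators:
        out[f"hd_{j}"] = hd[j] / W * 100.0
        out[f"hdk_{j}"] = hdk[j] / W * 100.0
        out[f"actb_{j}"] = scheme.weights[j] * hdk[j] / W
        m0 = out["M0"]
        out[f"pctb_{j}"] = (scheme.weights[j] * hdk[j] / W) / m0 * 100.0 if m0 else None
    return out


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def draw_sample(
    pop: FinitePopulation,
    config: GeneratorConfig,
    seed: int | None = None,
    inventory: sp.ItemInventory | None = None,
    survey: str = "SYN",
    year: str = "2010",
    t: int = 1,
) -> MicrodataWave:
    """Two-stage stratified cluster sample with inverse-probability weights.

    PSUs are drawn without replacement within strata, then households within
    PSUs; all members of a sampled household are included.  The household
    weight is the inverse inclusion probability times a mean-one lognormal
    perturbation with coefficient of variation ``weight_cv``.  Items the
    wave inventory does not collect are set to missing.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    design = config.design
    data = pop.data
    hh = data.drop_duplicates("hh_id")[["hh_id", "stratum", "psu"]]

    chosen_hh: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for s, sub in hh.groupby("stratum"):
        psus = np.sort(sub["psu"].unique())
        if len(psus) < design.psus_per_stratum:
            raise ValueError(
                f"stratum {s} has {len(psus)} PSUs, fewer than the "
                f"{design.psus_per_stratum} requested"
            )
        take = rng.choice(psus, size=design.psus_per_stratum, replace=False)
        p_psu = design.psus_per_stratum / len(psus)
        for c in np.sort(take):
            hh_in_psu = sub.loc[sub["psu"] == c, "hh_id"].to_numpy()
            b = min(design.households_per_psu, len(hh_in_psu))
            sampled = rng.choice(hh_in_psu, size=b, replace=False)
            p_hh = b / len(hh_in_psu)
            chosen_hh.append(np.sort(sampled))
            weights.append(np.full(b, 1.0 / (p_psu * p_hh)))

    hh_ids = np.concatenate(chosen_hh)
    base_w = np.concatenate(weights)
    if design.weight_cv > 0:
        sigma2 = np.log1p(design.weight_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=len(base_w))
        base_w = base_w * noise
    w_map = pd.Series(base_w, index=hh_ids)

    wave = data[data["hh_id"].isin(hh_ids)].copy()
    wave["weight"] = wave["hh_id"].map(w_map)
    wave = wave.reset_index(drop=True)

    inventory = inventory or sp.FULL_INVENTORY
    _apply_inventory(wave, inventory)
    return MicrodataWave(data=wave, survey=survey, year=year, t=t, inventory=inventory)


def _apply_inventory(wave: pd.DataFrame, inv: sp.ItemInventory) -> None:
    """Blank out items the wave did not collect (in place)."""
    _mask_nutrition(wave, inv.nutrition_groups)
    if not inv.cm_death_dates:
        wave["woman_death_5y_u18"] = np.nan
    if not inv.cm_male_report:
        wave["male_cm_report"] = np.nan
    if not inv.water_time:
        wave["water_time"] = np.nan
    if not inv.sanitation_shared:
        wave["toilet_shared"] = np.nan
    if not inv.electricity_collected:
        wave["electricity"] = np.nan
    for comp in sp.HOUSING_COMPONENTS:
        if comp not in inv.housing_components:
            wave[comp] = np.nan
    for item in sp.ASSET_ITEMS:
        if item not in inv.asset_items:
            wave[f"asset_{item}"] = np.nan


# ---------------------------------------------------------------------------
# wave pairs and missingness
# ---------------------------------------------------------------------------

def make_wave_pair(
    config: GeneratorConfig,
    seed: int | None = None,
) -> tuple[MicrodataWave, MicrodataWave, TruthRecord, TruthRecord]:
    """Two waves from drifting populations with configured inventory differences.

    Wave 2's deprivation propensities are shifted by
    ``wave2_propensity_shift`` (default: poverty declining).  Census truths
    are computed under the harmonised (common-domain) specs so that they are
    comparable across the pair.  Raises if the two inventories leave an
    empty common domain for any indicator.
    """
    from .harmonise import derive_plan

    if len(config.wave_inventories) < 2:
        raise ValueError("make_wave_pair requires two wave_inventories")
    inv1, inv2 = config.wave_inventories[:2]
    plan = derive_plan([inv1, inv2], school_entry_age=config.school_entry_age)

    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_pop1, s_pop2, s_smp1, s_smp2 = [s.generate_state(1)[0] % 2**31 for s in root.spawn(4)]

    pop1 = generate_population(config, seed=s_pop1)
    pop2 = generate_population(config, seed=s_pop2, propensity_shift=config.wave2_propensity_shift)

    years = config.wave_years
    wave1 = draw_sample(pop1, config, seed=s_smp1, inventory=inv1, year=years[0], t=1)
    wave2 = draw_sample(pop2, config, seed=s_smp2, inventory=inv2, year=years[1], t=2)
    truth1 = compute_truth(pop1, specs=plan.specs)
    truth2 = compute_truth(pop2, specs=plan.specs)
    return wave1, wave2, truth1, truth2


#: alias -> concrete raw columns for missingness injection
MEMBER_ITEMS: dict[str, tuple[str, ...]] = {
    "anthropometry": ("haz", "waz", "bmiz", "bmi"),
    "birth_history": ("woman_death_any", "woman_death_5y_u18"),
    "yschool": ("yschool",),
    "attending": ("attending",),
}
HOUSEHOLD_ITEMS: tuple[str, ...] = (
    "male_cm_report", "fuel", "toilet", "toilet_shared", "water_source",
    "water_time", "electricity", "floor", "roof", "walls", "asset_car",
) + tuple(f"asset_{i}" for i in sp.ASSET_ITEMS)


def inject_missingness(
    wave: MicrodataWave,
    rates: dict[str, float],
    seed: int | None = None,
) -> MicrodataWave:
    """Set raw items missing completely at random at the stated rates.

    Member-level items (anthropometry, birth histories, schooling,
    attendance) are blanked per member; household items per household (all
    members of a hit household share the missing value).
    """
    for item, rate in rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"missingness rate for {item!r} outside [0, 1]")
    rng = np.random.default_rng(seed if seed is not None else 0)
    df = wave.data.copy()
    hh_ids = df["hh_id"].unique()
    for item, rate in rates.items():
        if rate == 0.0:
            continue
        if item in MEMBER_ITEMS:
            hit = rng.random(len(df)) < rate
            for col in MEMBER_ITEMS[item]:
                df.loc[hit, col] = np.nan
        elif item in HOUSEHOLD_ITEMS:
            hit_hh = hh_ids[rng.random(len(hh_ids)) < rate]
            df.loc[df["hh_id"].isin(hit_hh), item] = np.nan
        elif item in df.columns:
            hit = rng.random(len(df)) < rate
            df.loc[hit, item] = np.nan
        else:
            raise ValueError(f"unknown raw item {item!r}")
    return MicrodataWave(
        data=df, survey=wave.survey, year=wave.year, t=wave.t, inventory=wave.inventory
    )


# ---------------------------------------------------------------------------
# microdata on disk
# ---------------------------------------------------------------------------

COLUMN_DICTIONARY: dict[str, str] = {
    "hh_id": "household identifier",
    "person_id": "person number within household",
    "stratum": "design stratum",
    "psu": "primary sampling unit",
    "weight": "household sampling weight (attached to each member)",
    "region": "subnational region code",
    "area": "urban/rural",
    "age_years": "age in completed years",
    "age_months": "age in months",
    "sex": "f/m",
    "usual_member": "1 = usual household member, 0 = visitor",
    "haz": "height-for-age z-score (under-5s)",
    "waz": "weight-for-age z-score (under-5s)",
    "bmiz": "BMI-for-age z-score (5-19 years)",
    "bmi": "body-mass index, kg/m2 (adults 20-70)",
    "yschool": "completed years of schooling (age 10+)",
    "attending": "1 = attending school (school-age children)",
    "woman_death_any": "woman 15-49: any child death reported",
    "woman_death_5y_u18": "woman 15-49: death of child under 18 within 5 years",
    "male_cm_report": "household male report of child mortality (0/1)",
    "fuel": "cooking fuel category",
    "toilet": "sanitation facility category",
    "toilet_shared": "facility shared with other households (0/1)",
    "water_source": "drinking-water source category",
    "water_time": "round-trip minutes to water source",
    "electricity": "household has electricity (0/1)",
    "floor": "floor material quality (finished/rudimentary/natural)",
    "roof": "roof material quality",
    "walls": "wall material quality",
    "asset_car": "owns car or truck (0/1)",
    **{f"asset_{i}": f"owns {i} (0/1)" for i in sp.ASSET_ITEMS},
}


def write_microdata(wave: MicrodataWave, path) -> None:
    """Member-level delimited text plus a machine-readable column dictionary."""
    wave.data.to_csv(path, index=False, float_format="%.6g")
    dict_path = str(path).rsplit(".", 1)[0] + "_columns.json"
    cols = {c: COLUMN_DICTIONARY.get(c, "") for c in wave.data.columns}
    with open(dict_path, "w") as fh:
        json.dump(cols, fh, indent=1)
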