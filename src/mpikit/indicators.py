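"""Household-level deprivation indicators from member-level microdata.

Each builder returns a member-level column in {0, 1, missing} named
``d_<ind>_01``; all members of one household share the household's value.
The builders implement the published eligibility rules (households with no
eligible members are non-deprived), the lower-bound missing-value policies
(e.g. improved water source with missing round-trip time counts as
non-deprived by source) and the two-thirds rules for schooling and
attendance.  Case-wise deletion and missingness accounting live at the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import specs as sp
from .afcore import WeightScheme, dcol

TWO_THIRDS = 2.0 / 3.0 - 1e-12

DESIGN_COLS = ("psu", "stratum", "weight")
DISAGG_COLS = ("region", "area", "agec2", "agec4")


def filter_usual_members(wave: pd.DataFrame) -> pd.DataFrame:
    """Drop non-usual household members before any indicator construction.

    Visitors are excluded throughout so that a household whose only eligible
    member (for some indicator) is a visitor counts as having no eligible
    members for it.
    """
    if "usual_member" not in wave.columns:
        raise ValueError("wave lacks the 'usual_member' flag")
    return wave.loc[wave["usual_member"].astype(bool)].copy()


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _hh_table(wave: pd.DataFrame) -> pd.DataFrame:
    """One row per household (household items are constant within household)."""
    return wave.drop_duplicates("hh_id").set_index("hh_id")


def _broadcast(wave: pd.DataFrame, hh_values: pd.Series, name: str) -> pd.Series:
    out = wave["hh_id"].map(hh_values)
    out.name = name
    return out


def _check_codes(series: pd.Series, valid: frozenset, item: str) -> None:
    observed = set(series.dropna().unique())
    unknown = observed - valid
    if unknown:
        raise ValueError(f"{item}: unknown category code(s) {sorted(map(str, unknown))}")


# ---------------------------------------------------------------------------
# health
# ---------------------------------------------------------------------------

def build_nutrition(wave: pd.DataFrame, spec: sp.IndicatorSpec) -> pd.Series:
    """Deprived if any eligible member with valid anthropometry is undernourished.

    Under-5s (<= 60 months) by height-for-age or weight-for-age z below the
    cutoff; 5-19 year olds (61-228 months) by BMI-for-age z; adults 20-70
    (229-840 months) by BMI below 18.5.  No eligible members => non-deprived;
    eligible members but none measured => missing.
    """
    m = wave["age_months"].to_numpy(dtype=float)
    sex = wave["sex"].to_numpy()
    groups = spec.nutrition_groups

    u5 = (m <= sp.U5_MAX_MONTHS) if "u5" in groups else np.zeros(len(wave), bool)
    child = (
        (m >= sp.CHILD_MIN_MONTHS) & (m <= sp.CHILD_MAX_MONTHS)
        if "child" in groups else np.zeros(len(wave), bool)
    )
    adult_band = (m >= sp.ADULT_MIN_MONTHS) & (m <= sp.ADULT_MAX_MONTHS)
    adult_f = adult_band & (sex == "f") if "adult_f" in groups else np.zeros(len(wave), bool)
    adult_m = adult_band & (sex == "m") if "adult_m" in groups else np.zeros(len(wave), bool)

    haz = wave["haz"].to_numpy(dtype=float)
    waz = wave["waz"].to_numpy(dtype=float)
    bmiz = wave["bmiz"].to_numpy(dtype=float)
    bmi = wave["bmi"].to_numpy(dtype=float)

    eligible = u5 | child | adult_f | adult_m
    measured = np.zeros(len(wave), bool)
    undernourished = np.zeros(len(wave), bool)

    measured |= u5 & (~np.isnan(haz) | ~np.isnan(waz))
    with np.errstate(invalid="ignore"):
        undernourished |= u5 & ((haz < spec.zscore_cutoff) | (waz < spec.zscore_cutoff))
        measured |= child & ~np.isnan(bmiz)
        undernourished |= child & (bmiz < spec.zscore_cutoff)
        adult = adult_f | adult_m
        measured |= adult & ~np.isnan(bmi)
        undernourished |= adult & (bmi < spec.bmi_cutoff)

    agg = pd.DataFrame(
        {"hh_id": wave["hh_id"].to_numpy(), "elig": eligible,
         "meas": measured, "und": undernourished & measured}
    ).groupby("hh_id").sum()
    d = pd.Series(np.nan, index=agg.index)
    d[agg["und"] > 0] = 1.0
    d[(agg["und"] == 0) & (agg["meas"] > 0)] = 0.0
    d[agg["elig"] == 0] = 0.0
    return _broadcast(wave, d, dcol("nutr"))


def build_child_mortality(wave: pd.DataFrame, spec: sp.IndicatorSpec) -> pd.Series:
    """Deprived if a mother (15-49) reports a qualifying child death.

    The dated variant requires the death of a child under 18 within the five
    years preceding the survey; the harmonised any-death variant counts any
    reported child death.  With no usable woman report, a male report of no
    child mortality makes the household non-deprived (lower bound); under the
    any-death variant a male report of a death is itself evidence of
    deprivation.  Otherwise the indicator is missing.
    """
    col = "woman_death_5y_u18" if spec.use_death_dates else "woman_death_any"
    age = wave["age_years"].to_numpy(dtype=float)
    woman = (wave["sex"].to_numpy() == "f") & (age >= sp.WOMAN_MIN_AGE) & (age <= sp.WOMAN_MAX_AGE)
    report = wave[col].to_numpy(dtype=float)

    agg = pd.DataFrame({
        "hh_id": wave["hh_id"].to_numpy(),
        "women": woman,
        "reported": woman & ~np.isnan(report),
        "deaths": woman & (report == 1.0),
    }).groupby("hh_id").sum()
    male = _hh_table(wave)["male_cm_report"].reindex(agg.index)

    d = pd.Series(np.nan, index=agg.index)
    fallback = agg["deaths"] == 0
    # male fallback where no complete woman evidence exists
    d[fallback & (male == 0.0)] = 0.0
    if not spec.use_death_dates:
        d[fallback & (male == 1.0)] = 1.0
    d[(agg["deaths"] == 0) & (agg["women"] > 0) & (agg["reported"] == agg["women"])] = 0.0
    d[agg["deaths"] > 0] = 1.0
    return _broadcast(wave, d, dcol("cm"))


# ---------------------------------------------------------------------------
# education
# ---------------------------------------------------------------------------

def build_schooling(wave: pd.DataFrame, spec: sp.IndicatorSpec) -> pd.Series:
    """Deprived if no member aged 10+ completed six years of schooling.

    Missing if at least two thirds of eligible members are unreported while
    every reported member has fewer than six years (insufficient evidence to
    call the household deprived).
    """
    age = wave["age_years"].to_numpy(dtype=float)
    ys = wave["yschool"].to_numpy(dtype=float)
    elig = age >= spec.schooling_min_age
    with np.errstate(invalid="ignore"):
        achiever = elig & (ys >= spec.years_cutoff)
    agg = pd.DataFrame({
        "hh_id": wave["hh_id"].to_numpy(),
        "elig": elig,
        "reported": elig & ~np.isnan(ys),
        "achv": achiever,
    }).groupby("hh_id").sum()

    d = pd.Series(np.nan, index=agg.index)
    n_elig, n_rep = agg["elig"], agg["reported"]
    low_info = (n_elig - n_rep) >= TWO_THIRDS * n_elig
    d[(agg["achv"] == 0) & ~low_info] = 1.0
    d[agg["achv"] > 0] = 0.0
    d[n_elig == 0] = 0.0
    return _broadcast(wave, d, dcol("educ"))


def build_attendance(wave: pd.DataFrame, spec: sp.IndicatorSpec) -> pd.Series:
    """Deprived if any school-age child is not attending school.

    School age is [entry_age, entry_age + 8) years (through the age at which
    class 8 would be completed).  Missing if at least two thirds of the
    school-age children are unreported while all reported ones attend.
    """
    age = wave["age_years"].to_numpy(dtype=float)
    att = wave["attending"].to_numpy(dtype=float)
    elig = (age >= spec.school_entry_age) & (age < spec.school_entry_age + 8)
    agg = pd.DataFrame({
        "hh_id": wave["hh_id"].to_numpy(),
        "elig": elig,
        "reported": elig & ~np.isnan(att),
        "out": elig & (att == 0.0),
    }).groupby("hh_id").sum()

    d = pd.Series(np.nan, index=agg.index)
    n_elig, n_rep = agg["elig"], agg["reported"]
    low_info = (n_elig - n_rep) >= TWO_THIRDS * n_elig
    d[(agg["out"] == 0) & ~low_info] = 0.0
    d[agg["out"] > 0] = 1.0
    d[n_elig == 0] = 0.0
    return _broadcast(wave, d, dcol("satt"))


# ---------------------------------------------------------------------------
# living standards
# ---------------------------------------------------------------------------

def build_living_standards(
    wave: pd.DataFrame, specs: dict[str, sp.IndicatorSpec]
) -> dict[str, pd.Series]:
    """The six household-item indicators: ckfl, sani, wtr, elct, hsg, asst."""
    hh = _hh_table(wave)
    out: dict[str, pd.Series] = {}

    # cooking fuel: solid fuels deprive
    _check_codes(hh["fuel"], sp.FUEL_CODES, "cooking fuel")
    fuel = hh["fuel"]
    d = pd.Series(np.nan, index=hh.index)
    d[fuel.isin(sp.SOLID_FUELS)] = 1.0
    d[fuel.isin(sp.CLEAN_FUELS)] = 0.0
    out["ckfl"] = _broadcast(wave, d, dcol("ckfl"))

    # sanitation: unimproved, or improved but shared
    _check_codes(hh["toilet"], sp.TOILET_CODES, "sanitation facility")
    toilet, shared = hh["toilet"], hh["toilet_shared"].astype(float)
    improved = toilet.isin(sp.IMPROVED_TOILETS)
    unimproved = toilet.isin(sp.UNIMPROVED_TOILETS)
    spec = specs["sani"]
    d = pd.Series(np.nan, index=hh.index)
    if spec.use_shared_flag:
        d[improved] = 0.0  # lower bound: shared flag missing => non-deprived by type
        d[improved & (shared == 1.0)] = 1.0
        d[shared == 1.0] = 1.0  # shared deprives regardless of (possibly missing) type
        d[improved & shared.isna()] = 0.0
        d[improved & (shared == 0.0)] = 0.0
    else:
        d[improved] = 0.0
    d[unimproved] = 1.0
    out["sani"] = _broadcast(wave, d, dcol("sani"))

    # drinking water: unsafe source, or safe source >= 30 minutes round trip
    _check_codes(hh["water_source"], sp.WATER_CODES, "water source")
    src, wtime = hh["water_source"], hh["water_time"].astype(float)
    safe = src.isin(sp.SAFE_WATER_SOURCES)
    unsafe = src.isin(sp.UNSAFE_WATER_SOURCES)
    spec = specs["wtr"]
    d = pd.Series(np.nan, index=hh.index)
    if spec.use_water_time:
        d[safe] = 0.0  # lower bound: time missing => non-deprived by source
        d[safe & (wtime >= spec.water_time_cutoff)] = 1.0
        d[wtime >= spec.water_time_cutoff] = 1.0  # long fetch deprives even if source unknown
        d[safe & wtime.isna()] = 0.0
        d[safe & (wtime < spec.water_time_cutoff)] = 0.0
    else:
        d[safe] = 0.0
    d[unsafe] = 1.0
    out["wtr"] = _broadcast(wave, d, dcol("wtr"))

    # electricity (with universal-coverage override)
    spec = specs["elct"]
    if spec.universal_coverage:
        d = pd.Series(0.0, index=hh.index)
    else:
        el = hh["electricity"].astype(float)
        d = pd.Series(np.nan, index=hh.index)
        d[el == 1.0] = 0.0
        d[el == 0.0] = 1.0
    out["elct"] = _broadcast(wave, d, dcol("elct"))

    # housing: natural floor, or natural/rudimentary roof or walls
    spec = specs["hsg"]
    bad = pd.Series(False, index=hh.index)
    any_missing = pd.Series(False, index=hh.index)
    for comp in spec.housing_components:
        mat = hh[comp]
        _check_codes(mat, sp.MATERIAL_CODES, f"housing {comp}")
        if comp == "floor":
            bad |= mat == "natural"
        else:
            bad |= mat.isin(("natural", "rudimentary"))
        any_missing |= mat.isna()
    d = pd.Series(np.nan, index=hh.index)
    d[~any_missing] = 0.0
    d[bad] = 1.0
    out["hsg"] = _broadcast(wave, d, dcol("hsg"))

    # assets: at most `asset_cutoff` small assets and no car/truck
    spec = specs["asst"]
    item_cols = [f"asset_{item}" for item in spec.asset_items]
    items = hh[item_cols].astype(float)
    car = hh["asset_car"].astype(float)
    owned = (items == 1.0).sum(axis=1)
    item_missing = items.isna().any(axis=1)
    d = pd.Series(np.nan, index=hh.index)
    complete = ~item_missing & car.notna()
    d[complete & (owned <= spec.asset_cutoff) & (car == 0.0)] = 1.0
    d[owned > spec.asset_cutoff] = 0.0  # enough observed assets regardless of gaps
    d[car == 1.0] = 0.0
    out["asst"] = _broadcast(wave, d, dcol("asst"))

    return out


_BUILDERS = {
    "nutr": build_nutrition,
    "cm": build_child_mortality,
    "educ": build_schooling,
    "satt": build_attendance,
}


def build_indicator(wave: pd.DataFrame, spec: sp.IndicatorSpec) -> pd.Series:
    """Dispatch a single indicator build."""
    if spec.name in _BUILDERS:
        return _BUILDERS[spec.name](wave, spec)
    all_specs = {spec.name: spec}
    # living-standard builders need each other's specs only for their own name
    defaults = sp.default_specs()
    defaults.update(all_specs)
    return build_living_standards(wave, defaults)[spec.name]


# ---------------------------------------------------------------------------
# assembly, missingness accounting, case-wise deletion
# ---------------------------------------------------------------------------

def attach_age_groups(df: pd.DataFrame) -> pd.DataFrame:
    """Two- and four-band age disaggregators (children/adults; 0-9/10-17/18-59/60+)."""
    age = df["age_years"].to_numpy(dtype=float)
    df = df.copy()
    df["agec2"] = np.where(age < 18, 1, 2)
    df["agec4"] = np.select([age < 10, age < 18, age < 60], [1, 2, 3], default=4)
    return df


def assemble_matrix(
    wave: pd.DataFrame,
    specs: dict[str, sp.IndicatorSpec],
    scheme: WeightScheme,
) -> pd.DataFrame:
    """Build all included indicators and deprivation scores for one wave.

    Filters to usual members, builds one ``d_<ind>_01`` column per indicator
    in the weight scheme, and computes c_i as the weighted sum over included
    indicators (missing whenever any included indicator is missing).
    """
    wave = filter_usual_members(wave)
    wave = attach_age_groups(wave)

    id_cols = ["hh_id", "person_id", "age_years", "sex"]
    keep = id_cols + [c for c in DESIGN_COLS + DISAGG_COLS if c in wave.columns]
    matrix = wave[keep].copy()

    ls = None
    for ind in scheme.indicators:
        if ind not in specs:
            raise ValueError(f"no IndicatorSpec supplied for included indicator {ind!r}")
        if ind in _BUILDERS:
            matrix[dcol(ind)] = _BUILDERS[ind](wave, specs[ind]).to_numpy()
        else:
            if ls is None:
                ls = build_living_standards(wave, specs)
            matrix[dcol(ind)] = ls[ind].to_numpy()

    w = np.array([scheme.weights[j] for j in scheme.indicators])
    dmat = matrix[[dcol(j) for j in scheme.indicators]].to_numpy(dtype=float)
    matrix["c"] = dmat @ w  # NaN-propagating: missing indicator => missing score
    return matrix


@dataclass
class MissingReport:
    """Member-level missingness shares (percent) per indicator and retained sample."""

    mv_uw: dict[str, float]
    mv_w: dict[str, float]
    retained_uw: float
    retained_w: float
    region_retained_w: dict[object, float]

    @property
    def national_drop(self) -> float:
        return 100.0 - self.retained_w

    def region_drop(self, region: object) -> float:
        return 100.0 - self.region_retained_w[region]


def _complete_mask(matrix: pd.DataFrame, scheme: WeightScheme) -> pd.Series:
    cols = [dcol(j) for j in scheme.indicators]
    cols += [c for c in DESIGN_COLS + DISAGG_COLS if c in matrix.columns]
    return matrix[cols].notna().all(axis=1)


def missingness_report(matrix: pd.DataFrame, scheme: WeightScheme) -> MissingReport:
    """Weighted and unweighted missing shares, computed before deletion."""
    w = matrix["weight"].to_numpy(dtype=float)
    W = w.sum()
    n = len(matrix)
    mv_uw: dict[str, float] = {}
    mv_w: dict[str, float] = {}
    for j in scheme.indicators:
        miss = matrix[dcol(j)].isna().to_numpy()
        mv_uw[j] = float(miss.sum() / n) * 100.0
        mv_w[j] = float(np.dot(w, miss) / W) * 100.0
    complete = _complete_mask(matrix, scheme).to_numpy()
    retained_uw = float(complete.sum() / n) * 100.0
    retained_w = float(np.dot(w, complete) / W) * 100.0
    region_retained: dict[object, float] = {}
    if "region" in matrix.columns:
        for g, sub in matrix.groupby("region"):
            sw = sub["weight"].to_numpy(dtype=float)
            sc = _complete_mask(sub, scheme).to_numpy()
            region_retained[g] = float(np.dot(sw, sc) / sw.sum()) * 100.0
    return MissingReport(mv_uw, mv_w, retained_uw, retained_w, region_retained)


def casewise_delete(matrix: pd.DataFrame, scheme: WeightScheme) -> pd.DataFrame:
    """Drop members with any missing included indicator, design variable or disaggregator."""
    out = matrix.loc[_complete_mask(matrix, scheme)].copy()
    if out.empty:
        raise ValueError("case-wise deletion removed every observation")
    return out
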