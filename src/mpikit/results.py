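"""Result-file assembly, suppression policy, certification and the
end-to-end pipeline runner.

The database design principle: each row is a single estimate, with a
nucleus (b, se, ll, ul, tval) and metadata identifying its content (country,
survey year, level of analysis, subgroup, measure, indicator, parameters).
Level and change files share the metadata vocabulary; the change file adds
the period bookkeeping (t0, t1, year0, year1, ann).  Human-readable label
companions carry the suffix ``_lab``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import specs as sp
from .afcore import AnalysisParams, WeightScheme, dcol, equal_nested_weights, reweight_for_missing
from .cot import build_change_file
from .harmonise import derive_plan, apply_plan
from .indicators import MissingReport, assemble_matrix, casewise_delete, missingness_report
from .svyest import Estimate, estimate_all
from .synthetic import GeneratorConfig, MicrodataWave, TruthRecord, inject_missingness, make_wave_pair

log = logging.getLogger("mpikit")

#: Table-4 column sets (level file; change file adds the period variables)
LEVEL_COLUMNS = [
    "ccty", "ccnum", "survey", "year", "ctype", "loa", "measure",
    "b", "se", "ll", "ul", "tval", "subg", "k", "wgts", "indicator", "misind",
]
CHANGE_EXTRA = ["t0", "t1", "year0", "year1", "ann"]
LABEL_COLUMNS = [
    "cty_lab", "ind_lab", "measure_lab", "misind_lab", "dim_lab",
    "region_lab", "area_lab", "agec2_lab", "agec4_lab",
]

MEASURE_CODES = {
    "M0", "H", "A", "hd", "hdk", "actb", "pctb", "popsh", "N", "mv_uw", "mv_w",
    "sev", "vuln",
}
#: measures split into (code, indicator) when suffixed with an indicator name
INDICATOR_MEASURES = ("hd", "hdk", "actb", "pctb", "mv_uw", "mv_w")
#: auxiliary rows for which poverty parameters do not apply
PARAMETER_FREE = {"popsh", "N", "mv_uw", "mv_w"}

MEASURE_LABELS = {
    "M0": "MPI (adjusted headcount ratio)",
    "H": "Headcount ratio",
    "A": "Intensity of poverty",
    "hd": "Uncensored headcount ratio",
    "hdk": "Censored headcount ratio",
    "actb": "Absolute contribution to MPI",
    "pctb": "Relative contribution to MPI (%)",
    "popsh": "Population share",
    "N": "Number of observations",
    "mv_uw": "Missing values / retained sample (unweighted)",
    "mv_w": "Missing values / retained sample (weighted)",
    "sev": "Severity of poverty",
    "vuln": "Vulnerability to poverty",
}
AGEC2_LABELS = {1: "0-17", 2: "18+"}
AGEC4_LABELS = {1: "0-9", 2: "10-17", 3: "18-59", 4: "60+"}
AREA_CODES = {"urban": 1, "rural": 2}
AREA_LABELS = {1: "urban", 2: "rural"}

DUPLICATE_KEY = [
    "ccty", "year", "loa", "subg", "measure", "indicator", "k", "wgts",
    "ctype", "ann", "t0", "t1",
]

LOA_ORDER = {"nat": 0, "region": 1, "area": 2, "agec2": 3, "agec4": 4}


class SchemaError(ValueError):
    pass


class CertificationError(ValueError):
    pass


def _split_measure(measure: str) -> tuple[str, str | None]:
    for prefix in INDICATOR_MEASURES:
        if measure.startswith(prefix + "_"):
            suffix = measure[len(prefix) + 1:]
            if suffix in sp.INDICATORS:
                return prefix, suffix
    return measure, None


def assemble(
    estimates: list[Estimate],
    metadata: dict | None = None,
    kind: str = "level",
) -> pd.DataFrame:
    """Turn estimate records into one sorted, labelled result table.

    ``metadata`` supplies defaults (ccty, ccnum, cty_lab, ...) for keys an
    estimate does not carry itself.  Raises on duplicate estimate keys.
    """
    if kind not in ("level", "change"):
        raise SchemaError(f"unknown file kind {kind!r}")
    metadata = metadata or {}
    rows = []
    for est in estimates:
        meta = {**metadata, **est.meta}
        code, indicator = _split_measure(meta.get("measure", ""))
        if code not in MEASURE_CODES:
            raise SchemaError(f"unknown measure code {meta.get('measure')!r}")
        row = {
            "ccty": meta.get("ccty"), "ccnum": meta.get("ccnum"),
            "survey": meta.get("survey"), "year": meta.get("year"),
            "ctype": meta.get("ctype", 0), "loa": meta.get("loa"),
            "measure": code,
            "b": est.b, "se": est.se, "ll": est.ll, "ul": est.ul, "tval": est.tval,
            "subg": meta.get("subg"),
            "k": None if code in PARAMETER_FREE else meta.get("k"),
            "wgts": None if code in PARAMETER_FREE else meta.get("wgts"),
            "indicator": indicator if indicator is not None else meta.get("indicator"),
            "misind": meta.get("misind"),
        }
        if kind == "change":
            for key in CHANGE_EXTRA:
                row[key] = meta.get(key)
        rows.append(row)
    df = pd.DataFrame(rows)

    # labels
    df["cty_lab"] = df["ccty"].map(lambda c: metadata.get("cty_lab", c))
    df["ind_lab"] = df["indicator"].map(sp.INDICATOR_LABELS)
    df["measure_lab"] = df["measure"].map(MEASURE_LABELS)
    df["misind_lab"] = df["misind"].map(
        lambda m: None if m is None or (isinstance(m, float) and np.isnan(m))
        else " & ".join(sp.INDICATOR_LABELS[i] for i in str(m).split("+"))
    )
    df["dim_lab"] = df["indicator"].map(
        lambda i: sp.DIMENSION_LABELS.get(sp.DIMENSION_OF.get(i)) if isinstance(i, str) else None
    )
    df["region_lab"] = np.where(
        df["loa"] == "region", "Region " + df["subg"].astype(str), None
    )
    df["area_lab"] = np.where(
        df["loa"] == "area", df["subg"].map(AREA_LABELS), None
    )
    df["agec2_lab"] = np.where(df["loa"] == "agec2", df["subg"].map(AGEC2_LABELS), None)
    df["agec4_lab"] = np.where(df["loa"] == "agec4", df["subg"].map(AGEC4_LABELS), None)

    columns = LEVEL_COLUMNS + (CHANGE_EXTRA if kind == "change" else []) + LABEL_COLUMNS
    df = df[columns]

    key = df[[c for c in DUPLICATE_KEY if c in df.columns]].astype(str)
    dup = key.duplicated()
    if dup.any():
        raise SchemaError(
            f"duplicate estimate keys:\n{key[dup].drop_duplicates().to_string()}"
        )

    df = df.assign(_loa=df["loa"].map(LOA_ORDER))
    sort_cols = ["ccty", "year", "_loa", "subg", "measure", "indicator"]
    if kind == "change":
        sort_cols = ["ccty", "t0", "t1", "ctype", "ann", "_loa", "subg", "measure", "indicator"]
    df = df.sort_values(sort_cols, na_position="first", kind="mergesort")
    return df.drop(columns="_loa").reset_index(drop=True)


# ---------------------------------------------------------------------------
# suppression
# ---------------------------------------------------------------------------

NATIONAL_DROP_LIMIT = 15.0  # percent; strictly exceeding suppresses region rows
REGIONAL_DROP_LIMIT = 25.0


def apply_suppression(
    file: pd.DataFrame,
    reports: dict[str, MissingReport],
) -> tuple[pd.DataFrame, list[str]]:
    """Remove region-level rows where sample drop breaches the policy.

    All region rows of a survey go if its national drop exceeds 15%;
    individual regions go if their own drop exceeds 25%.  National, area
    and age-group rows always stay.  Thresholds are strict ("exceeds").
    """
    notes: list[str] = []
    keep = pd.Series(True, index=file.index)
    is_region = file["loa"] == "region"
    for year, report in reports.items():
        of_survey = file["year"].astype(str) == str(year)
        if report.national_drop > NATIONAL_DROP_LIMIT:
            keep &= ~(of_survey & is_region)
            notes.append(
                f"survey {year}: national sample drop "
                f"{report.national_drop:.2f}% > {NATIONAL_DROP_LIMIT}%; "
                "all region-level rows suppressed"
            )
            continue
        for region, retained in report.region_retained_w.items():
            drop = 100.0 - retained
            if drop > REGIONAL_DROP_LIMIT:
                cond = of_survey & is_region & (file["subg"] == region)
                keep &= ~cond
                notes.append(
                    f"survey {year}: region {region} sample drop {drop:.2f}% "
                    f"> {REGIONAL_DROP_LIMIT}%; region rows suppressed"
                )
    return file.loc[keep].reset_index(drop=True), notes


# ---------------------------------------------------------------------------
# certification
# ---------------------------------------------------------------------------

IDENTITY_TOL = 1e-9


def certify(
    file: pd.DataFrame,
    kind: str = "level",
    matrix: pd.DataFrame | None = None,
    scheme: WeightScheme | None = None,
) -> list[str]:
    """Quality checks; returns a list of violations (empty = clean).

    Checks schema conformance, measure and ctype coding, interval ordering,
    and — within each level country-year — the Alkire-Foster identities
    M0 = H x A / 1e4 and M0 = sum_j w_j hdk_j / 100.  With the microdata
    matrix supplied, also checks 0/1 coding of the deprivation columns and
    the weight-scheme sums.
    """
    violations: list[str] = []
    expected = LEVEL_COLUMNS + (CHANGE_EXTRA if kind == "change" else []) + LABEL_COLUMNS
    if list(file.columns) != expected:
        violations.append(
            f"schema: columns {list(file.columns)} != expected {expected}"
        )
        return violations

    bad_measures = set(file["measure"].dropna()) - MEASURE_CODES
    if bad_measures:
        violations.append(f"schema: unknown measure codes {sorted(bad_measures)}")
    allowed_ctype = {0} if kind == "level" else {1, 2}
    bad_ctype = set(file["ctype"].dropna()) - allowed_ctype
    if bad_ctype:
        violations.append(f"schema: ctype codes {sorted(bad_ctype)} invalid for {kind} file")

    has_iv = file["se"].notna() & file["ll"].notna() & file["ul"].notna() & file["b"].notna()
    bad_iv = file.loc[has_iv & ~((file["ll"] <= file["b"] + 1e-12) & (file["b"] <= file["ul"] + 1e-12))]
    for idx, row in bad_iv.iterrows():
        violations.append(
            f"row {idx} ({row['measure']}, loa={row['loa']}, subg={row['subg']}): "
            "confidence interval does not bracket the point estimate"
        )

    if kind == "level":
        group_cols = ["ccty", "year", "loa", "subg", "k", "wgts"]
        keyed = file.assign(_subg=file["subg"].astype(str))
        for keys, sub in keyed.groupby(["ccty", "year", "loa", "_subg"], dropna=False):
            pivot = {}
            for _, row in sub.iterrows():
                if row["measure"] in ("M0", "H", "A"):
                    pivot[row["measure"]] = row["b"]
                if row["measure"] == "hdk":
                    pivot.setdefault("hdk", {})[row["indicator"]] = row["b"]
            if {"M0", "H", "A"} <= set(pivot) and pivot["A"] is not None and not np.isnan(pivot["A"]):
                gap = abs(pivot["M0"] - pivot["H"] * pivot["A"] / 1e4)
                if gap > IDENTITY_TOL:
                    violations.append(
                        f"{keys}: M0 != H*A/1e4 (gap {gap:.2e})"
                    )
            if "hdk" in pivot and "M0" in pivot:
                misind = sub["misind"].dropna().unique()
                base = equal_nested_weights()
                try:
                    sch = (
                        reweight_for_missing(base, str(misind[0]).split("+"))
                        if len(misind) else base
                    )
                except ValueError:
                    sch = base
                if set(pivot["hdk"]) == set(sch.indicators):
                    total = sum(sch.weights[j] * pivot["hdk"][j] / 100.0 for j in sch.indicators)
                    if abs(total - pivot["M0"]) > IDENTITY_TOL:
                        violations.append(
                            f"{keys}: M0 != sum_j w_j hdk_j/100 "
                            f"(gap {abs(total - pivot['M0']):.2e})"
                        )

    if matrix is not None and scheme is not None:
        for j in scheme.indicators:
            col = matrix[dcol(j)].dropna()
            if not col.isin([0.0, 1.0]).all():
                violations.append(f"microdata: {dcol(j)} is not 0-1 coded")
        if abs(sum(scheme.weights.values()) - 1.0) > IDENTITY_TOL:
            violations.append("weights do not sum to 1")
        for dim, members in sp.DIMENSIONS.items():
            s = sum(scheme.weights.get(j, 0.0) for j in members)
            if abs(s - 1.0 / 3.0) > IDENTITY_TOL:
                violations.append(f"dimension {dim} weights sum to {s}, expected 1/3")
    return violations


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

COLUMN_DESCRIPTIONS = {
    "ccty": "ISO-like country code",
    "ccnum": "numeric country code",
    "survey": "name of survey (e.g. DHS)",
    "year": "year of survey as stated by the provider",
    "ctype": "0 = level, 1 = absolute change, 2 = relative change",
    "loa": "level of analysis: nat, region, area, agec2, agec4",
    "measure": "measure code (see measure_lab)",
    "b": "point estimate",
    "se": "standard error",
    "ll": "lower confidence bound",
    "ul": "upper confidence bound",
    "tval": "t-value for the null of a zero coefficient",
    "subg": "numeric subgroup identifier within loa",
    "k": "poverty cutoff label (33 = 1/3)",
    "wgts": "weighting scheme label",
    "indicator": "indicator code for indicator-specific measures",
    "misind": "missing indicator(s) for this survey, if any",
    "t0": "first period of change", "t1": "second period of change",
    "year0": "survey year of first period", "year1": "survey year of second period",
    "ann": "1 = annualised change, 0 = raw",
    "cty_lab": "country name", "ind_lab": "indicator name",
    "measure_lab": "measure name", "misind_lab": "missing indicator name(s)",
    "dim_lab": "dimension of the indicator",
    "region_lab": "region name (region rows only)",
    "area_lab": "urban/rural (area rows only)",
    "agec2_lab": "two-band age group", "agec4_lab": "four-band age group",
}


def write(file: pd.DataFrame, path: str | Path, kind: str = "level") -> Path:
    """Byte-stable CSV with fixed column order and numeric formatting, plus
    a machine-readable column dictionary next to it.  Missing values are
    serialised as empty fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = file.copy()
    for col in ("b", "se", "ll", "ul", "tval"):
        out[col] = out[col].map(lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.6f}")
    out.to_csv(path, index=False, na_rep="")
    dict_path = path.with_name(path.stem + "_columns.json")
    with open(dict_path, "w") as fh:
        json.dump({c: COLUMN_DESCRIPTIONS.get(c, "") for c in file.columns}, fh, indent=1)
    return path


def read_result_file(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for files produced by :func:`write`."""
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

class PipelineConfig(BaseModel):
    """Declarative configuration of one country's two-wave production run."""

    ccty: str = "SYL"
    ccnum: int = 998
    cty_lab: str = "Synthetica"
    surveys: tuple[str, ...] = ("DHS", "DHS")
    generator: GeneratorConfig
    k: float = 1.0 / 3.0
    confidence: float = 0.95
    missing_indicators: tuple[str, ...] = ()
    levels: tuple[str, ...] = ("nat", "region", "area", "agec2", "agec4")
    out_dir: str | None = None

    model_config = {"arbitrary_types_allowed": True}


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return PipelineConfig.model_validate(payload)


@dataclass
class PipelineResult:
    level_file: pd.DataFrame
    change_file: pd.DataFrame
    truths: list[TruthRecord]
    reports: dict[str, MissingReport]
    suppression_log: list[str]
    policy_log: list[str]
    paths: dict[str, Path] = field(default_factory=dict)


def _mv_estimates(report: MissingReport, scheme: WeightScheme) -> list[Estimate]:
    """Missingness bookkeeping rows (per indicator + retained sample)."""
    out = []
    for j in scheme.indicators:
        out.append(Estimate(report.mv_uw[j], None, None, None, None, None,
                            {"measure": f"mv_uw_{j}", "loa": "nat", "subg": None}))
        out.append(Estimate(report.mv_w[j], None, None, None, None, None,
                            {"measure": f"mv_w_{j}", "loa": "nat", "subg": None}))
    out.append(Estimate(report.retained_uw, None, None, None, None, None,
                        {"measure": "mv_uw", "loa": "nat", "subg": None}))
    out.append(Estimate(report.retained_w, None, None, None, None, None,
                        {"measure": "mv_w", "loa": "nat", "subg": None}))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """generate -> sample -> harmonise -> indicators -> estimate -> changes
    -> suppress -> certify -> write, with policy decisions logged."""
    policy_log: list[str] = []
    gen = config.generator
    if len(gen.wave_inventories) < 2:
        raise ValueError("pipeline config needs two wave inventories")

    wave1, wave2, truth1, truth2 = make_wave_pair(gen)
    waves = [wave1, wave2]
    if gen.missingness_rates:
        seeds = [s.generate_state(1)[0] % 2**31
                 for s in np.random.SeedSequence(gen.seed + 7).spawn(2)]
        waves = [inject_missingness(w, gen.missingness_rates, seed=s)
                 for w, s in zip(waves, seeds)]
        policy_log.append(f"injected MCAR missingness at rates {gen.missingness_rates}")

    plan = derive_plan(list(gen.wave_inventories[:2]), school_entry_age=gen.school_entry_age)
    for j, variant in plan.variants.items():
        if variant != "full":
            policy_log.append(f"harmonisation: {j} -> variant {variant}")

    scheme = equal_nested_weights()
    misind_label = None
    if config.missing_indicators:
        scheme = reweight_for_missing(scheme, list(config.missing_indicators))
        misind_label = "+".join(config.missing_indicators)
        policy_log.append(
            f"missing indicator(s) {misind_label}: weights redistributed within dimension"
        )

    params = AnalysisParams(k=config.k, confidence=config.confidence)
    years = {w.t: w.year for w in waves}
    level_estimates: list[Estimate] = []
    reports: dict[str, MissingReport] = {}
    matrices = []
    for wave, survey in zip(waves, config.surveys):
        masked, specs_r = apply_plan(wave.data, plan)
        matrix = assemble_matrix(masked, specs_r, scheme)
        report = missingness_report(matrix, scheme)
        reports[wave.year] = report
        matrix = casewise_delete(matrix, scheme)
        matrices.append(matrix)
        ests = estimate_all(matrix, scheme, params, levels=config.levels)
        ests += _mv_estimates(report, scheme)
        meta = {
            "ccty": config.ccty, "ccnum": config.ccnum, "survey": survey,
            "year": wave.year, "t": wave.t, "k": params.k_label,
            "wgts": scheme.name, "misind": misind_label,
        }
        for est in ests:
            est.meta = {**meta, **est.meta}
        level_estimates += ests

    change_estimates = build_change_file(level_estimates, years)
    metadata = {"ccty": config.ccty, "ccnum": config.ccnum, "cty_lab": config.cty_lab}
    level_file = assemble(level_estimates, metadata, kind="level")
    change_file = assemble(change_estimates, metadata, kind="change")

    level_file, supp_notes = apply_suppression(level_file, reports)
    change_file, supp_notes2 = apply_suppression(change_file, reports)
    supp_notes += supp_notes2

    for kind, file, matrix in (("level", level_file, matrices[0]), ("change", change_file, None)):
        problems = certify(file, kind=kind, matrix=matrix, scheme=scheme if matrix is not None else None)
        if problems:
            raise CertificationError(
                f"{kind} file failed certification:\n" + "\n".join(problems)
            )

    result = PipelineResult(
        level_file=level_file, change_file=change_file,
        truths=[truth1, truth2], reports=reports,
        suppression_log=supp_notes, policy_log=policy_log,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        result.paths["level"] = write(level_file, out / "levels.csv", kind="level")
        result.paths["change"] = write(change_file, out / "changes.csv", kind="change")
        with open(out / "policy_log.txt", "w") as fh:
            fh.write("\n".join(policy_log + supp_notes) + "\n")
        result.paths["log"] = out / "policy_log.txt"
    return result
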