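"""Design-based estimation under stratified two-stage cluster sampling.

Point estimates are weighted ratio means; variances use first-order Taylor
linearisation with the stratified between-PSU formula (ultimate-cluster
approximation, no finite-population correction):

    var(T(z)) = sum_h n_h/(n_h - 1) * sum_c (z_hc - zbar_h)^2

where z_hc is the PSU total of the member-level linearised scores w_i u_i.
For the mean R = sum(w y)/sum(w), u_i = (y_i - R)/sum(w); for a ratio of
totals R = X/Y, u_i = (x_i - R y_i)/Y.  Subpopulations (domains) are
handled by zeroing scores outside the domain while keeping the full design,
so all PSUs contribute to the variance.  Degrees of freedom are
(#PSUs - #strata); confidence intervals use Student-t quantiles.

Strata with a single PSU contribute the squared deviation of their PSU
score total from the grand mean of all PSU totals (the behaviour selected
by the ``singleunit(centered)`` option of the production system).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .afcore import AnalysisParams, MeasureSet, WeightScheme, dcol, identify


@dataclass(frozen=True)
class SurveyDesign:
    """psu / stratum / member-level weight triplet."""

    psu: np.ndarray
    stratum: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.psu) == len(self.stratum) == len(self.weight)):
            raise ValueError("design columns must have equal length")
        if (np.asarray(self.weight, dtype=float) <= 0).any():
            raise ValueError("sampling weights must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyDesign":
        return cls(
            psu=df["psu"].to_numpy(),
            stratum=df["stratum"].to_numpy(),
            weight=df["weight"].to_numpy(dtype=float),
        )

    @property
    def n_psus(self) -> int:
        return len(np.unique(_combine(self.stratum, self.psu)))

    @property
    def n_strata(self) -> int:
        return len(np.unique(self.stratum))

    @property
    def df(self) -> int:
        return self.n_psus - self.n_strata


def _combine(stratum: np.ndarray, psu: np.ndarray) -> np.ndarray:
    """PSU identifiers made unique across strata."""
    return np.char.add(
        np.char.add(stratum.astype(str), "||"), psu.astype(str)
    )


@dataclass
class Estimate:
    """One estimated quantity with its survey-design uncertainty."""

    b: float | None
    se: float | None
    ll: float | None
    ul: float | None
    tval: float | None
    df: int | None
    meta: dict = field(default_factory=dict)

    def with_meta(self, **kw) -> "Estimate":
        self.meta.update(kw)
        return self


def _linearised_variance(scores: np.ndarray, design: SurveyDesign) -> float:
    """Stratified between-PSU variance of the total of member scores."""
    frame = pd.DataFrame({
        "stratum": design.stratum,
        "psu": _combine(design.stratum, design.psu),
        "z": scores,
    })
    psu_tot = frame.groupby(["stratum", "psu"], sort=False)["z"].sum()
    grand_mean = psu_tot.mean()
    var = 0.0
    for _, z in psu_tot.groupby(level="stratum", sort=False):
        n_h = len(z)
        if n_h == 1:
            var += float((z.iloc[0] - grand_mean) ** 2)
        else:
            var += n_h / (n_h - 1) * float(((z - z.mean()) ** 2).sum())
    return var


def _finalize(
    b: float, var: float, design: SurveyDesign, confidence: float, scale: float
) -> Estimate:
    df = design.df
    if design.n_psus < 2:
        warnings.warn("single PSU overall: standard error not estimable")
        return Estimate(b=b * scale, se=None, ll=None, ul=None, tval=None, df=df)
    se = float(np.sqrt(max(var, 0.0)))
    b_s, se_s = b * scale, se * scale
    if se == 0.0:
        return Estimate(b=b_s, se=0.0, ll=b_s, ul=b_s, tval=None, df=df)
    tq = float(stats.t.ppf(0.5 + confidence / 2.0, df)) if df > 0 else np.nan
    return Estimate(
        b=b_s, se=se_s, ll=b_s - tq * se_s, ul=b_s + tq * se_s,
        tval=b_s / se_s, df=df,
    )


def estimate_mean(
    y: np.ndarray | pd.Series,
    design: SurveyDesign,
    domain: np.ndarray | None = None,
    confidence: float = 0.95,
    scale: float = 100.0,
) -> Estimate:
    """Weighted mean of member-level y over a domain, with linearised se.

    The domain is handled by zeroing linearised scores outside it while the
    full design is retained.  ``scale`` converts to the reporting scale
    (100 for percent measures, 1 for quantities in units of M).
    """
    y = np.asarray(y, dtype=float)
    w = design.weight
    dom = np.ones(len(y), dtype=float) if domain is None else np.asarray(domain, dtype=float)
    W = float(np.dot(w, dom))
    if W <= 0:
        raise ValueError("domain has zero total weight")
    R = float(np.dot(w, y * dom)) / W
    u = dom * (y - R) / W
    var = _linearised_variance(w * u, design)
    return _finalize(R, var, design, confidence, scale)


def estimate_ratio(
    numerator: np.ndarray | pd.Series,
    denominator: np.ndarray | pd.Series,
    design: SurveyDesign,
    domain: np.ndarray | None = None,
    confidence: float = 0.95,
    scale: float = 100.0,
) -> Estimate:
    """Ratio of weighted totals sum(w x)/sum(w y) with linearised se.

    With a zero denominator total (e.g. intensity A in a domain with no
    poor people) the estimate is reported as missing.
    """
    x = np.asarray(numerator, dtype=float)
    y = np.asarray(denominator, dtype=float)
    w = design.weight
    dom = np.ones(len(x), dtype=float) if domain is None else np.asarray(domain, dtype=float)
    Y = float(np.dot(w, y * dom))
    if Y <= 0:
        return Estimate(b=None, se=None, ll=None, ul=None, tval=None, df=design.df)
    R = float(np.dot(w, x * dom)) / Y
    u = dom * (x - R * y) / Y
    var = _linearised_variance(w * u, design)
    return _finalize(R, var, design, confidence, scale)


# ---------------------------------------------------------------------------
# all measures, all levels of analysis
# ---------------------------------------------------------------------------

LOA_COLUMNS = {"nat": None, "region": "region", "area": "area", "agec2": "agec2", "agec4": "agec4"}


def _measure_estimates(
    matrix: pd.DataFrame,
    scheme: WeightScheme,
    params: AnalysisParams,
    design: SurveyDesign,
    domain: np.ndarray | None,
) -> dict[str, Estimate]:
    """The full measure set for one domain (None = national)."""
    from .afcore import deprivation_scores

    conf = params.confidence
    c = deprivation_scores(matrix, scheme).to_numpy()
    poor = identify(c, params.k)
    out: dict[str, Estimate] = {}
    out["H"] = estimate_mean(poor, design, domain, conf)
    out["A"] = estimate_ratio(c * poor, poor, design, domain, conf)
    out["M0"] = estimate_mean(c * poor, design, domain, conf, scale=1.0)
    out["sev"] = estimate_mean(identify(c, params.severity_cutoff), design, domain, conf)
    vuln = ((c >= params.vulnerability_lower - 1e-10) & (poor == 0.0)).astype(float)
    out["vuln"] = estimate_mean(vuln, design, domain, conf)
    for j in scheme.indicators:
        d = matrix[dcol(j)].to_numpy(dtype=float)
        out[f"hd_{j}"] = estimate_mean(d, design, domain, conf)
        out[f"hdk_{j}"] = estimate_mean(d * poor, design, domain, conf)
        out[f"actb_{j}"] = estimate_mean(scheme.weights[j] * d * poor, design, domain, conf, scale=1.0)
        out[f"pctb_{j}"] = estimate_ratio(scheme.weights[j] * d * poor, c * poor, design, domain, conf)
    n_dom = int(len(matrix)) if domain is None else int(np.asarray(domain, dtype=bool).sum())
    out["N"] = Estimate(b=float(n_dom), se=None, ll=None, ul=None, tval=None, df=None)
    return out


def estimate_all(
    matrix: pd.DataFrame,
    scheme: WeightScheme,
    params: AnalysisParams | None = None,
    levels: tuple[str, ...] = ("nat", "region", "area", "agec2", "agec4"),
    excluded_regions: set | None = None,
) -> list[Estimate]:
    """All measures at the national level and per subgroup of each level.

    Subgroup (domain) estimation retains the full design; ``popsh`` is the
    weighted member share of the subgroup.  Regions flagged as excluded by
    the harmonisation plan get no region-level rows (their members still
    contribute to every other level).
    """
    params = params or AnalysisParams()
    design = SurveyDesign.from_frame(matrix)
    results: list[Estimate] = []
    for loa in levels:
        if loa not in LOA_COLUMNS:
            raise ValueError(f"undefined level of analysis {loa!r}")
        col = LOA_COLUMNS[loa]
        if col is None:
            ests = _measure_estimates(matrix, scheme, params, design, None)
            for measure, est in ests.items():
                results.append(est.with_meta(loa="nat", subg=None, measure=measure))
            continue
        if col not in matrix.columns:
            raise ValueError(f"matrix lacks disaggregator column {col!r}")
        for g in sorted(matrix[col].unique()):
            if loa == "region" and excluded_regions and g in excluded_regions:
                continue
            domain = (matrix[col] == g).to_numpy(dtype=float)
            ests = _measure_estimates(matrix, scheme, params, design, domain)
            ests["popsh"] = estimate_mean(domain, design, None, params.confidence)
            for measure, est in ests.items():
                results.append(est.with_meta(loa=loa, subg=g, measure=measure))
    return results


def psu_bootstrap_se(
    matrix: pd.DataFrame,
    stat: callable,
    n_replicates: int = 1000,
    seed: int = 0,
) -> float:
    """Rao-Wu PSU bootstrap of a statistic (independent variance oracle).

    Within each stratum, n_h - 1 PSUs are drawn with replacement and their
    member weights rescaled by n_h/(n_h - 1); singleton strata enter
    unresampled.  ``stat`` maps a resampled matrix to a scalar.  Test
    oracle only, never a production path.
    """
    rng = np.random.default_rng(seed)
    psus = matrix.groupby(["stratum", "psu"]).indices
    by_stratum: dict[object, list[pd.DataFrame]] = {}
    for (s, _), idx in psus.items():
        by_stratum.setdefault(s, []).append(matrix.iloc[idx])
    vals = np.empty(n_replicates)
    for r in range(n_replicates):
        parts: list[pd.DataFrame] = []
        factors: list[np.ndarray] = []
        for s, groups in by_stratum.items():
            n_h = len(groups)
            if n_h == 1:
                parts.append(groups[0])
                factors.append(np.ones(len(groups[0])))
                continue
            draw = rng.integers(0, n_h, size=n_h - 1)
            rescale = n_h / (n_h - 1)
            for g in draw:
                parts.append(groups[g])
                factors.append(np.full(len(groups[g]), rescale))
        m = pd.concat(parts, ignore_index=True)
        m["weight"] = m["weight"].to_numpy() * np.concatenate(factors)
        vals[r] = stat(m)
    return float(vals.std(ddof=1))
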