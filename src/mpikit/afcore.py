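"""Alkire-Foster measurement on a completed deprivation matrix.

Given member-level 0/1 deprivation columns ``d_<ind>_01``, indicator weights
w_j (summing to 1) and a poverty cutoff k, the deprivation score of person i
is c_i = sum_j w_j d_ij, a person is poor iff c_i >= k, and:

* incidence            H  = weighted share of poor people (percent)
* intensity            A  = weighted mean of c among the poor (percent)
* adjusted headcount   M0 = H x A (on the 0-1 scale), equivalently the
  weighted mean of the censored score c_i * poor_i
* uncensored headcount hd_j  = weighted share deprived in j (percent)
* censored headcount   hdk_j = weighted share poor AND deprived in j (percent)
* absolute / relative contributions actb_j = w_j hdk_j / 100 (units of M0),
  pctb_j = actb_j / M0 x 100
* severity = H at k = 0.5; vulnerability = share with 0.2 <= c < k.

All computations use the member-level sampling weight; point values here are
design-unaware (standard errors live in :mod:`mpikit.svyest`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .specs import DIMENSIONS, DIMENSION_OF, INDICATORS

#: numeric slack for the weak inequality c >= k under float summation
K_TOL = 1e-10


def dcol(ind: str) -> str:
    """Column name convention for harmonised deprivation indicators."""
    return f"d_{ind}_01"


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightScheme:
    """Indicator weights under the equal-nested structure.

    Dimensions carry 1/3 each; indicators share their dimension's weight
    equally.  ``missing`` records indicators dropped for a survey, whose
    weight has been redistributed within the affected dimension.
    """

    weights: dict[str, float]
    missing: tuple[str, ...] = ()
    name: str = "equal"

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"indicator weights sum to {total}, expected 1")
        for dim, members in DIMENSIONS.items():
            dim_sum = sum(self.weights.get(j, 0.0) for j in members)
            if abs(dim_sum - 1.0 / 3.0) > 1e-9:
                raise ValueError(f"dimension {dim!r} weights sum to {dim_sum}, expected 1/3")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(j for j in INDICATORS if j in self.weights)


def equal_nested_weights() -> WeightScheme:
    """The published scheme: 1/6 for health and education, 1/18 for living standards."""
    w: dict[str, float] = {}
    for members in DIMENSIONS.values():
        for j in members:
            w[j] = (1.0 / 3.0) / len(members)
    return WeightScheme(weights=w)


def reweight_for_missing(base: WeightScheme, missing: list[str] | tuple[str, ...]) -> WeightScheme:
    """Redistribute weights when indicators are unavailable for a survey.

    Within each affected dimension the remaining indicators share the
    dimension's 1/3 equally; other dimensions are untouched.  At least one
    health and one education indicator must remain (inclusion policy).
    """
    missing = tuple(dict.fromkeys(missing))
    unknown = set(missing) - set(base.weights)
    if unknown:
        raise ValueError(f"cannot drop indicators not in scheme: {sorted(unknown)}")
    weights: dict[str, float] = {}
    for dim, members in DIMENSIONS.items():
        remaining = [j for j in members if j in base.weights and j not in missing]
        if not remaining:
            raise ValueError(
                f"dropping {missing} leaves dimension {dim!r} empty; "
                "surveys must support at least one indicator per dimension"
            )
        for j in remaining:
            weights[j] = (1.0 / 3.0) / len(remaining)
    return WeightScheme(weights=weights, missing=missing, name=base.name)


# ---------------------------------------------------------------------------
# Parameters and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisParams:
    """Poverty cutoff and reporting bands.

    k defaults to 1/3 (reported under the label "33"); vulnerability is the
    band [0.2, k) and severity the cutoff 0.5; confidence level applies to
    the survey estimation stage.
    """

    k: float = 1.0 / 3.0
    vulnerability_lower: float = 0.2
    severity_cutoff: float = 0.5
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.k <= 1.0):
            raise ValueError("poverty cutoff k must lie in (0, 1]")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence level must lie in (0, 1)")

    @property
    def k_label(self) -> str:
        return str(int(round(self.k * 100)))


@dataclass
class MeasureSet:
    """Point values of all measures for one (sub)population.

    Percent scales for H, A, hd, hdk, sev, vuln, popsh, pctb; 0-1 scale for
    M0 and actb, matching the released database.  ``a`` is None when nobody
    is poor (mean over an empty set).
    """

    h: float
    a: float | None
    m0: float
    sev: float
    vuln: float
    hd: dict[str, float]
    hdk: dict[str, float]
    actb: dict[str, float]
    pctb: dict[str, float | None]
    n: int
    popsh: float = 100.0

    def as_dict(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {
            "H": self.h, "A": self.a, "M0": self.m0,
            "sev": self.sev, "vuln": self.vuln, "N": self.n, "popsh": self.popsh,
        }
        for j, v in self.hd.items():
            out[f"hd_{j}"] = v
        for j, v in self.hdk.items():
            out[f"hdk_{j}"] = v
        for j, v in self.actb.items():
            out[f"actb_{j}"] = v
        for j, v in self.pctb.items():
            out[f"pctb_{j}"] = v
        return out


# ---------------------------------------------------------------------------
# Identification and aggregation
# ---------------------------------------------------------------------------

def deprivation_scores(matrix: pd.DataFrame, scheme: WeightScheme) -> pd.Series:
    """c_i = sum_j w_j d_ij over the scheme's indicators."""
    cols = [dcol(j) for j in scheme.indicators]
    missing_cols = [c for c in cols if c not in matrix.columns]
    if missing_cols:
        raise ValueError(f"matrix lacks indicator columns {missing_cols}")
    w = np.array([scheme.weights[j] for j in scheme.indicators])
    return pd.Series(matrix[cols].to_numpy(dtype=float) @ w, index=matrix.index, name="c")


def identify(scores: pd.Series | np.ndarray, k: float) -> np.ndarray:
    """Poverty identification: poor iff c >= k (weak inequality, float-tolerant)."""
    c = np.asarray(scores, dtype=float)
    if np.isnan(c).any():
        raise ValueError("deprivation scores contain missing values; delete cases first")
    return (c >= k - K_TOL).astype(float)


def compute_measures(
    matrix: pd.DataFrame,
    scheme: WeightScheme,
    params: AnalysisParams | None = None,
    weight_col: str = "weight",
) -> MeasureSet:
    """All Alkire-Foster measures on a completed matrix (vectorised path)."""
    params = params or AnalysisParams()
    if weight_col not in matrix.columns:
        raise ValueError(f"matrix lacks weight column {weight_col!r}")
    w = matrix[weight_col].to_numpy(dtype=float)
    if (w <= 0).any():
        raise ValueError("sampling weights must be positive")
    c = deprivation_scores(matrix, scheme).to_numpy()
    poor = identify(c, params.k)
    W = w.sum()

    h = float(np.dot(w, poor) / W) * 100.0
    wpoor = float(np.dot(w, poor))
    a = float(np.dot(w, c * poor) / wpoor) * 100.0 if wpoor > 0 else None
    m0 = float(np.dot(w, c * poor) / W)
    sev = float(np.dot(w, identify(c, params.severity_cutoff)) / W) * 100.0
    vuln_flag = ((c >= params.vulnerability_lower - K_TOL) & (c < params.k - K_TOL)).astype(float)
    vuln = float(np.dot(w, vuln_flag) / W) * 100.0

    hd: dict[str, float] = {}
    hdk: dict[str, float] = {}
    actb: dict[str, float] = {}
    pctb: dict[str, float | None] = {}
    for j in scheme.indicators:
        d = matrix[dcol(j)].to_numpy(dtype=float)
        hd[j] = float(np.dot(w, d) / W) * 100.0
        hdk[j] = float(np.dot(w, d * poor) / W) * 100.0
        actb[j] = scheme.weights[j] * hdk[j] / 100.0
        pctb[j] = actb[j] / m0 * 100.0 if m0 > 0 else None

    return MeasureSet(
        h=h, a=a, m0=m0, sev=sev, vuln=vuln, hd=hd, hdk=hdk,
        actb=actb, pctb=pctb, n=int(len(matrix)),
    )


def decompose_by_group(
    matrix: pd.DataFrame,
    scheme: WeightScheme,
    params: AnalysisParams | None = None,
    grouping: str = "region",
    weight_col: str = "weight",
) -> dict[object, MeasureSet]:
    """Per-subgroup measures plus weighted population shares.

    The grouping column must partition the sample (no missing codes); the
    population-weighted average of subgroup H (or M0) recovers the national
    value by construction.
    """
    if grouping not in matrix.columns:
        raise ValueError(f"grouping column {grouping!r} not present")
    if matrix[grouping].isna().any():
        raise ValueError(f"grouping column {grouping!r} does not partition the sample")
    W = matrix[weight_col].sum()
    out: dict[object, MeasureSet] = {}
    for g, sub in matrix.groupby(grouping, sort=True):
        ms = compute_measures(sub, scheme, params, weight_col=weight_col)
        ms.popsh = float(sub[weight_col].sum() / W) * 100.0
        out[g] = ms
    return out
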