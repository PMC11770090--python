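"""Changes over time between survey pairs: raw and annualised, absolute and
relative, with delta-method uncertainty.

For a measure with level b_0 at reference year y_0 and b_1 at y_1
(dt = y_1 - y_0 > 0):

* raw absolute        b_1 - b_0
* raw relative        (b_1 - b_0)/b_0 x 100
* annualised absolute (b_1 - b_0)/dt
* annualised relative ((b_1/b_0)^(1/dt) - 1) x 100

Surveys are treated as independent cross-sections, so the variance of the
absolute change is se_0^2 + se_1^2; the relative and annualised forms use
the first-order delta method on (b_0, b_1).  For surveys fielded across
several calendar years the reference year is the mean of the span's
endpoints (e.g. "2005-2006" -> 2005.5).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .svyest import Estimate

#: measure codes that are levels-only bookkeeping, never differenced
NON_CHANGE_MEASURES = {"N", "mv_uw", "mv_w"}

_YEAR_RE = re.compile(r"^\s*(\d{4})(?:\s*[-/]\s*(\d{4}))?\s*$")


@dataclass(frozen=True)
class ChangeSpec:
    """One change computation: type (1 absolute, 2 relative), annualised flag,
    and the period bookkeeping carried into the change file."""

    ctype: int
    ann: int
    t0: int
    t1: int
    year0: str
    year1: str

    def __post_init__(self) -> None:
        if self.ctype not in (1, 2):
            raise ValueError("ctype must be 1 (absolute) or 2 (relative)")
        if self.ann not in (0, 1):
            raise ValueError("ann must be 0 or 1")
        if self.t0 >= self.t1:
            raise ValueError("change requires t0 < t1")


def reference_year(year_field: str | float | int) -> float:
    """Numeric reference year: single year as itself, a span as the mean of
    its endpoints."""
    if isinstance(year_field, (int, float)):
        return float(year_field)
    m = _YEAR_RE.match(str(year_field))
    if not m:
        raise ValueError(f"unparseable survey year field {year_field!r}")
    y0 = float(m.group(1))
    if m.group(2) is None:
        return y0
    return (y0 + float(m.group(2))) / 2.0


_MATCH_KEYS = ("measure", "loa", "subg", "indicator", "k", "wgts")


def change(est0: Estimate, est1: Estimate, spec: ChangeSpec) -> Estimate:
    """Change estimate between two level estimates of the same quantity."""
    for key in _MATCH_KEYS:
        if est0.meta.get(key) != est1.meta.get(key):
            raise ValueError(
                f"level estimates disagree on {key!r}: "
                f"{est0.meta.get(key)!r} vs {est1.meta.get(key)!r}"
            )
    meta = dict(est1.meta)
    meta.update(
        ctype=spec.ctype, ann=spec.ann, t0=spec.t0, t1=spec.t1,
        year0=spec.year0, year1=spec.year1,
    )
    b0, b1 = est0.b, est1.b
    if b0 is None or b1 is None:
        return Estimate(None, None, None, None, None, None, meta)
    se0 = est0.se if est0.se is not None else float("nan")
    se1 = est1.se if est1.se is not None else float("nan")
    dt = reference_year(spec.year1) - reference_year(spec.year0)
    if spec.ann and dt <= 0:
        raise ValueError("annualised change requires year1 > year0")

    if spec.ctype == 1 and not spec.ann:
        b = b1 - b0
        g0, g1 = -1.0, 1.0
    elif spec.ctype == 1:
        b = (b1 - b0) / dt
        g0, g1 = -1.0 / dt, 1.0 / dt
    elif spec.ctype == 2 and not spec.ann:
        if b0 == 0:
            return Estimate(None, None, None, None, None, None, meta)
        b = (b1 - b0) / b0 * 100.0
        g0, g1 = -100.0 * b1 / b0**2, 100.0 / b0
    else:
        if b0 == 0 or (b1 / b0) <= 0:
            return Estimate(None, None, None, None, None, None, meta)
        r = b1 / b0
        b = (r ** (1.0 / dt) - 1.0) * 100.0
        gr = 100.0 / dt * r ** (1.0 / dt - 1.0)  # d b / d r
        g0, g1 = gr * (-b1 / b0**2), gr / b0

    var = g0**2 * se0**2 + g1**2 * se1**2
    se = math.sqrt(var) if not math.isnan(var) else None
    df = est1.df
    if se is None or math.isnan(se):
        return Estimate(b, None, None, None, None, df, meta)
    if se == 0.0:
        return Estimate(b, 0.0, b, b, 0.0 if b == 0 else None, df, meta)
    from scipy import stats

    conf = meta.get("confidence", 0.95)
    tq = float(stats.t.ppf(0.5 + conf / 2.0, df)) if df and df > 0 else float("nan")
    return Estimate(b, se, b - tq * se, b + tq * se, b / se, df, meta)


def build_change_file(
    level_estimates: list[Estimate],
    years: dict[int, str],
    pairs: list[tuple[int, int]] | None = None,
) -> list[Estimate]:
    """All change rows for a country's sequence of level estimates.

    ``years`` maps period index t (1, 2, ...) to the survey year label.
    By default consecutive pairs (t, t+1) are formed; ``pairs`` overrides
    (e.g. first-to-last).  For every pair and every measure/subgroup both
    raw and annualised, absolute and relative changes are produced;
    sample-size and missingness bookkeeping rows are excluded.
    """
    periods = sorted(years)
    if len(periods) < 2:
        raise ValueError("changes require at least two survey periods")
    if pairs is None:
        pairs = list(zip(periods[:-1], periods[1:]))

    by_key: dict[tuple, dict[int, Estimate]] = {}
    for est in level_estimates:
        t = est.meta.get("t")
        if t is None:
            raise ValueError("level estimates must carry a period index 't'")
        measure = est.meta.get("measure", "")
        if measure in NON_CHANGE_MEASURES or measure.startswith("mv_"):
            continue
        key = tuple(est.meta.get(k) for k in _MATCH_KEYS)
        by_key.setdefault(key, {})[t] = est

    out: list[Estimate] = []
    for key in sorted(by_key, key=lambda k: tuple(str(x) for x in k)):
        series = by_key[key]
        for t0, t1 in pairs:
            if t0 not in series or t1 not in series:
                continue
            for ctype in (1, 2):
                for ann in (0, 1):
                    spec = ChangeSpec(
                        ctype=ctype, ann=ann, t0=t0, t1=t1,
                        year0=years[t0], year1=years[t1],
                    )
                    out.append(change(series[t0], series[t1], spec))
    return out
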