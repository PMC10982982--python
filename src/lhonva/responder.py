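"""Responder-endpoint classification for (baseline, endpoint) acuity pairs.

Four outcomes, evaluated from baseline to an analysis timepoint:

* CRR (clinically relevant recovery): from off-chart to reading at
  least 5 letters on-chart (<= 1.6 logMAR), or an on-chart improvement
  of at least 10 letters (-0.2 logMAR);
* CRS (clinically relevant stabilization): maintenance of VA < 1.0
  logMAR; only eyes with baseline < 1.0 logMAR are eligible;
* CRW (clinically relevant worsening): from on-chart to off-chart, or
  an on-chart loss of at least 10 letters (+0.2 logMAR); only eyes with
  an on-chart baseline (<= 1.68 logMAR) are eligible;
* CRB (clinically relevant benefit): CRR and/or CRS, evaluated on all
  eyes (an eye ineligible for CRS can still achieve CRB through CRR).

Threshold comparisons absorb decimal-representation error from Snellen
conversion with a 1e-9 tolerance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .va import ON_CHART_BOUND, VAMeasure

__all__ = [
    "TriState",
    "ResponderFlags",
    "classify_crr",
    "classify_crs",
    "classify_crw",
    "classify_crb",
    "classify_eye",
    "classify_dataset",
    "responder_rates",
]

#: Comparison tolerance for the +/-0.2 logMAR (10 letter) thresholds.
TOL = 1e-9

CRR_ONCHART_TARGET = 1.6  # "at least 5 letters on-chart"
CRS_BOUND = 1.0
CHANGE_THRESHOLD = 0.2


class TriState(str, enum.Enum):
    TRUE = "true"
    FALSE = "false"
    NOT_ELIGIBLE = "not_eligible"

    def __bool__(self) -> bool:
        return self is TriState.TRUE


@dataclass(frozen=True)
class ResponderFlags:
    """CRR/CRS/CRW/CRB verdicts for one eye at one timepoint."""

    crr: bool
    crs: TriState
    crw: TriState
    crb: bool
    baseline: VAMeasure
    endpoint: VAMeasure
    timepoint: Optional[float] = None


def classify_crr(baseline: VAMeasure, endpoint: VAMeasure) -> bool:
    """Recovery: off-chart baseline needs an on-chart endpoint <= 1.6
    logMAR; on-chart baseline needs improvement >= 0.2 logMAR."""
    if baseline.off_chart:
        return (not endpoint.off_chart) and endpoint.logmar <= CRR_ONCHART_TARGET + TOL
    return baseline.logmar - endpoint.logmar >= CHANGE_THRESHOLD - TOL


def classify_crs(baseline: VAMeasure, endpoint: VAMeasure) -> TriState:
    """Stabilization: maintenance of VA < 1.0 logMAR; eyes at or above
    1.0 at baseline (including all off-chart baselines) are ineligible."""
    if baseline.off_chart or baseline.logmar >= CRS_BOUND:
        return TriState.NOT_ELIGIBLE
    return TriState.TRUE if endpoint.logmar < CRS_BOUND else TriState.FALSE


def classify_crw(baseline: VAMeasure, endpoint: VAMeasure) -> TriState:
    """Worsening: on-chart to off-chart, or an on-chart loss >= 0.2
    logMAR; only on-chart baselines (<= 1.68) are eligible."""
    if baseline.off_chart or baseline.logmar > ON_CHART_BOUND + TOL:
        return TriState.NOT_ELIGIBLE
    if endpoint.off_chart:
        return TriState.TRUE
    return (
        TriState.TRUE
        if endpoint.logmar - baseline.logmar >= CHANGE_THRESHOLD - TOL
        else TriState.FALSE
    )


def classify_crb(crr: bool, crs: TriState) -> bool:
    """Benefit: the composite CRR and/or CRS; an ineligible CRS
    contributes false."""
    return bool(crr) or crs is TriState.TRUE


def classify_eye(
    baseline: VAMeasure, endpoint: VAMeasure, timepoint: Optional[float] = None
) -> ResponderFlags:
    crr = classify_crr(baseline, endpoint)
    crs = classify_crs(baseline, endpoint)
    crw = classify_crw(baseline, endpoint)
    return ResponderFlags(
        crr=crr,
        crs=crs,
        crw=crw,
        crb=classify_crb(crr, crs),
        baseline=baseline,
        endpoint=endpoint,
        timepoint=timepoint,
    )


def _measure(logmar: float, off_chart: bool) -> VAMeasure:
    return VAMeasure(logmar=1.8 if off_chart else logmar, off_chart=bool(off_chart))


def classify_dataset(matched: pd.DataFrame) -> pd.DataFrame:
    """Append per-eye outcome columns to a matched analysis table.

    CRS/CRW are tri-state strings; the paired ``*_eligible`` booleans
    give the analysis denominators.
    """
    out = matched.copy()
    crr, crs, crw, crb = [], [], [], []
    for row in matched.itertuples():
        flags = classify_eye(
            _measure(row.baseline_logmar, row.baseline_off_chart),
            _measure(row.endpoint_logmar, row.endpoint_off_chart),
        )
        crr.append(flags.crr)
        crs.append(flags.crs.value)
        crw.append(flags.crw.value)
        crb.append(flags.crb)
    out["crr"] = crr
    out["crs"] = crs
    out["crw"] = crw
    out["crb"] = crb
    # audit: CRS and CRW can both be true for one eye (e.g. 0.5 -> 0.9,
    # a maintained-under-1.0 eye that still lost >= 0.2); surface it.
    both = (out["crs"] == "true") & (out["crw"] == "true")
    out.attrs["crs_and_crw_count"] = int(both.sum())
    return out


def responder_rates(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-group numerators, denominators and percentage rates.

    Rates are percentages rounded to one decimal; a zero denominator is
    reported as not-estimable (NaN rate).
    """
    rows = []
    for group, grp in classified.groupby("group", sort=True):
        for outcome in ("crb", "crr", "crs", "crw"):
            col = grp[outcome]
            if outcome in ("crs", "crw"):
                eligible = col != TriState.NOT_ELIGIBLE.value
                num = int((col == TriState.TRUE.value).sum())
            else:
                eligible = pd.Series(True, index=grp.index)
                num = int(col.astype(bool).sum())
            den = int(eligible.sum())
            rows.append(
                {
                    "group": group,
                    "outcome": outcome,
                    "responders": num,
                    "eligible": den,
                    "rate_percent": round(100.0 * num / den, 1) if den else float("nan"),
                    "estimable": den > 0,
                }
            )
    return pd.DataFrame(rows)


def rates_report(rates: pd.DataFrame) -> str:
    """Plain-text outcome x group rate table (N.E. = not estimable)."""
    lines = ["outcome  group             rate      n/N"]
    for row in rates.itertuples():
        rate = f"{row.rate_percent:5.1f}%" if row.estimable else "  N.E."
        lines.append(
            f"{row.outcome.upper():<7}  {row.group:<16}  {rate}  {row.responders}/{row.eligible}"
        )
    return "\n".join(lines)
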