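"""Baseline matching against the untreated natural-history cohort.

Time since symptom onset is the dominant prognostic factor for visual
acuity in LHON, so NH control baselines are chosen to match the treated
cohort on that axis. Any NH visit can in principle serve as a baseline
(there was no treatment), which leaves a free choice the two algorithms
pin down:

* subacute/dynamic branch: from all (baseline, follow-up) visit pairs
  whose separation falls within +/- ``window`` of the analysis timepoint
  and whose baseline lies within 1 year of symptom onset, pick the pair
  whose baseline time-since-onset is closest to ``onset_L`` (the treated
  cohort's mean time from second-eye onset to its baseline visit);

* chronic branch: pairs are binned by baseline time-since-onset into
  >1-2, >2-3, >3-4 and >4-5 years; within each bin the pair whose
  baseline is closest to the bin midpoint (18, 30, 42, 54 months) wins,
  and one eye may contribute a pair to every bin.

Ties (equal distance) go to the earlier baseline date; several pairs
sharing one baseline are first reduced to the follow-up closest to
baseline + timepoint. Both conventions are deterministic and invariant
to input row order.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .cohort import Cohort, EyeHistory
from .eligibility import (
    ExclusionLedger,
    Phase,
    months_since_onset,
    phase_matches,
    phase_of,
    pooled_phase,
)
from .va import VAMeasure

__all__ = [
    "VisitPair",
    "MatchingConfig",
    "MatchedBaseline",
    "CHRONIC_BINS",
    "compute_onset_L",
    "enumerate_visit_pairs",
    "match_subacute",
    "match_chronic",
    "build_matched_dataset",
]

#: Chronic bins in months since onset, half-open (low, high], with midpoints.
CHRONIC_BINS: List[Tuple[float, float, float]] = [
    (12.0, 24.0, 18.0),
    (24.0, 36.0, 30.0),
    (36.0, 48.0, 42.0),
    (48.0, 60.0, 54.0),
]


@dataclass(frozen=True)
class VisitPair:
    """A candidate (baseline, follow-up) pair of visits from one eye."""

    baseline_date: dt.date
    baseline_measure: VAMeasure
    followup_date: dt.date
    followup_measure: VAMeasure
    baseline_months_since_onset: float
    separation_months: float


@dataclass
class MatchingConfig:
    """Parameters of the matching algorithms.

    ``onset_L`` is in months and must be computed from the treated
    cohort (or overridden explicitly); ``window_halfwidth`` is the
    +/- window, in months, around each analysis timepoint.
    """

    onset_L: Optional[float] = None
    window_halfwidth: float = 3.0
    chronic_bins: List[Tuple[float, float, float]] = field(
        default_factory=lambda: list(CHRONIC_BINS)
    )

    def __post_init__(self):
        if self.onset_L is not None and self.onset_L < 0:
            raise ValueError("onset_L must be nonnegative")
        if self.window_halfwidth <= 0:
            raise ValueError("window_halfwidth must be positive")


@dataclass(frozen=True)
class MatchedBaseline:
    """The NH visit pair selected for one eye, phase and timepoint."""

    eye_key: str
    phase: Phase
    analysis_timepoint: float
    pair: VisitPair
    bin_label: Optional[str] = None
    selection_distance: float = 0.0


def compute_onset_L(treated: Sequence[EyeHistory]) -> float:
    """Mean months from second-eye symptom onset to the baseline visit,
    over treated patients.

    The second eye is the later-onset eye of each patient; patients with
    a single recorded eye contribute that eye's onset. The baseline
    visit is the patient's earliest visit date.
    """
    if not treated:
        raise ValueError("cannot compute onset_L from an empty treated cohort")
    by_patient: Dict[str, List[EyeHistory]] = {}
    for eye in treated:
        by_patient.setdefault(eye.patient_id, []).append(eye)
    gaps = []
    for pid, eyes in sorted(by_patient.items()):
        onsets = [e.onset_date for e in eyes if e.onset_date is not None]
        if not onsets:
            raise ValueError(f"patient {pid}: no onset date for any eye")
        second_onset = max(onsets)
        baseline_date = min(e.baseline[0] for e in eyes)
        if baseline_date < second_onset:
            raise ValueError(
                f"patient {pid}: baseline {baseline_date} precedes second-eye onset"
            )
        gaps.append(months_since_onset(second_onset, baseline_date))
    return sum(gaps) / len(gaps)


def enumerate_visit_pairs(
    eye: EyeHistory, timepoint: float, window: float
) -> List[VisitPair]:
    """All ordered visit pairs separated by ``timepoint`` +/- ``window``
    months, sorted by baseline date (then follow-up date)."""
    if eye.onset_date is None:
        return []
    pairs = []
    visits = eye.visits
    for i in range(len(visits)):
        b_date, b_meas = visits[i]
        if b_date < eye.onset_date:
            continue
        for j in range(i + 1, len(visits)):
            f_date, f_meas = visits[j]
            sep = (f_date - b_date).days / 30.4375
            if timepoint - window <= sep <= timepoint + window:
                pairs.append(
                    VisitPair(
                        baseline_date=b_date,
                        baseline_measure=b_meas,
                        followup_date=f_date,
                        followup_measure=f_meas,
                        baseline_months_since_onset=months_since_onset(
                            eye.onset_date, b_date
                        ),
                        separation_months=sep,
                    )
                )
    pairs.sort(key=lambda p: (p.baseline_date, p.followup_date))
    return pairs


def _best_followup_per_baseline(
    pairs: Sequence[VisitPair], timepoint: float
) -> List[VisitPair]:
    """Reduce pairs sharing a baseline to the follow-up closest to
    baseline + timepoint (earlier follow-up on ties)."""
    best: Dict[dt.date, VisitPair] = {}
    for p in sorted(pairs, key=lambda p: (p.baseline_date, p.followup_date)):
        cur = best.get(p.baseline_date)
        if cur is None or abs(p.separation_months - timepoint) < abs(
            cur.separation_months - timepoint
        ) - 1e-12:
            best[p.baseline_date] = p
    return sorted(best.values(), key=lambda p: p.baseline_date)


def _argmin_by_distance(
    candidates: Sequence[VisitPair], target: float
) -> Optional[Tuple[VisitPair, float]]:
    """Pair whose baseline time-since-onset is closest to ``target``;
    ties broken by earlier baseline date."""
    best = None
    best_dist = None
    for p in sorted(candidates, key=lambda p: p.baseline_date):
        dist = abs(p.baseline_months_since_onset - target)
        if best is None or dist < best_dist - 1e-12:
            best, best_dist = p, dist
    if best is None:
        return None
    return best, best_dist


def match_subacute(
    eye: EyeHistory, config: MatchingConfig, timepoint: float
) -> Optional[MatchedBaseline]:
    """Subacute/dynamic branch: qualifying baselines lie within 1 year of
    onset; the one closest to ``onset_L`` wins."""
    if config.onset_L is None:
        raise ValueError("config.onset_L must be computed from the treated cohort")
    pairs = enumerate_visit_pairs(eye, timepoint, config.window_halfwidth)
    pairs = [p for p in pairs if p.baseline_months_since_onset <= 12.0]
    pairs = _best_followup_per_baseline(pairs, timepoint)
    chosen = _argmin_by_distance(pairs, config.onset_L)
    if chosen is None:
        return None
    pair, dist = chosen
    return MatchedBaseline(
        eye_key=eye.key,
        phase=Phase.SUBACUTE_DYNAMIC,
        analysis_timepoint=timepoint,
        pair=pair,
        selection_distance=dist,
    )


def match_chronic(
    eye: EyeHistory, config: MatchingConfig, timepoint: float
) -> List[MatchedBaseline]:
    """Chronic branch: one winner per bin, closest baseline to the bin
    midpoint; an eye may contribute to several bins."""
    pairs = enumerate_visit_pairs(eye, timepoint, config.window_halfwidth)
    pairs = _best_followup_per_baseline(pairs, timepoint)
    matches = []
    for low, high, mid in config.chronic_bins:
        in_bin = [
            p for p in pairs if low < p.baseline_months_since_onset <= high
        ]
        chosen = _argmin_by_distance(in_bin, mid)
        if chosen is None:
            continue
        pair, dist = chosen
        matches.append(
            MatchedBaseline(
                eye_key=eye.key,
                phase=Phase.CHRONIC,
                analysis_timepoint=timepoint,
                pair=pair,
                bin_label=f">{low / 12:.0f}-{high / 12:.0f}y",
                selection_distance=dist,
            )
        )
    return matches


def _bin_label_for(months: float, bins) -> Optional[str]:
    for low, high, _ in bins:
        if low < months <= high:
            return f">{low / 12:.0f}-{high / 12:.0f}y"
    return None


def _treated_row(eye: EyeHistory, timepoint: float, window: float):
    """Treated eye's (baseline, endpoint) at the scheduled timepoint, or
    None when no follow-up falls inside the window."""
    b_date, b_meas = eye.baseline
    best = None
    best_dist = None
    for f_date, f_meas in eye.visits[1:]:
        sep = (f_date - b_date).days / 30.4375
        if timepoint - window <= sep <= timepoint + window:
            dist = abs(sep - timepoint)
            if best is None or dist < best_dist - 1e-12:
                best, best_dist = (f_date, f_meas, sep), dist
    return best


def build_matched_dataset(
    treated: Sequence[EyeHistory],
    nh: Sequence[EyeHistory],
    phase: Phase,
    timepoint: float,
    config: MatchingConfig,
) -> Tuple[pd.DataFrame, ExclusionLedger]:
    """Assemble the per-eye analysis table for one phase and timepoint.

    Treated eyes enter at their actual baseline (first visit) with the
    endpoint taken from the scheduled visit closest to the timepoint
    within the +/- window; NH eyes enter through the phase's matching
    algorithm. Returns one row per eye per group (an NH eye may appear
    once per chronic bin) plus a ledger of treated eyes dropped for a
    missing endpoint visit.
    """
    phase = pooled_phase(phase)
    ledger = ExclusionLedger(eyes_in=len(treated))
    ledger.add_rule("no_endpoint_visit", "no follow-up visit within the timepoint window")
    ledger.add_rule("phase_mismatch", "baseline outside the requested phase")
    rows = []
    for eye in treated:
        try:
            eye_phase = phase_of(eye, eye.baseline[0])
        except ValueError:
            ledger.exclude("phase_mismatch", eye)
            continue
        if not phase_matches(eye_phase, phase):
            ledger.exclude("phase_mismatch", eye)
            continue
        endpoint = _treated_row(eye, timepoint, config.window_halfwidth)
        if endpoint is None:
            ledger.exclude("no_endpoint_visit", eye)
            continue
        b_date, b_meas = eye.baseline
        f_date, f_meas, sep = endpoint
        months = months_since_onset(eye.onset_date, b_date)
        rows.append(
            {
                "group": Cohort.TREATED.value,
                "eye_key": eye.key,
                "gender": eye.gender.value,
                "mutation": eye.mutation.value,
                "age_at_onset": eye.age_at_onset,
                "baseline_logmar": b_meas.logmar,
                "baseline_off_chart": b_meas.off_chart,
                "endpoint_logmar": f_meas.logmar,
                "endpoint_off_chart": f_meas.off_chart,
                "months_since_onset": months,
                "separation_months": sep,
                "bin": _bin_label_for(months, config.chronic_bins)
                if phase == Phase.CHRONIC
                else None,
            }
        )
    ledger.eyes_retained = len(rows)

    for eye in nh:
        if phase == Phase.SUBACUTE_DYNAMIC:
            m = match_subacute(eye, config, timepoint)
            matches = [m] if m is not None else []
        else:
            matches = match_chronic(eye, config, timepoint)
        for m in matches:
            rows.append(
                {
                    "group": Cohort.NATURAL_HISTORY.value,
                    "eye_key": eye.key,
                    "gender": eye.gender.value,
                    "mutation": eye.mutation.value,
                    "age_at_onset": eye.age_at_onset,
                    "baseline_logmar": m.pair.baseline_measure.logmar,
                    "baseline_off_chart": m.pair.baseline_measure.off_chart,
                    "endpoint_logmar": m.pair.followup_measure.logmar,
                    "endpoint_off_chart": m.pair.followup_measure.off_chart,
                    "months_since_onset": m.pair.baseline_months_since_onset,
                    "separation_months": m.pair.separation_months,
                    "bin": m.bin_label,
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["change_logmar"] = df["endpoint_logmar"] - df["baseline_logmar"]
        df["phase"] = phase.value
        df["timepoint"] = timepoint
        if (df["group"] == Cohort.NATURAL_HISTORY.value).sum() == 0:
            ledger.notes.append("no NH eyes matched; table has treated rows only")
    return df, ledger
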