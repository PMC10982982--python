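"""Cohort eligibility rules, disease-phase stratification, exclusion ledger.

Phases by time since symptom onset at baseline: subacute < 6 months,
dynamic 6-12 months (pooled as subacute/dynamic, <= 1 year), chronic
> 1 to <= 5 years. Beyond 5 years an eye is not classifiable and is
ineligible.

Each eye is excluded under exactly the first failing rule, in declared
order, so ledger counts are conservative and reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .cohort import COMMON_MUTATIONS, EyeHistory

__all__ = [
    "DAYS_PER_MONTH",
    "Phase",
    "ExclusionLedger",
    "months_since_onset",
    "phase_of",
    "pooled_phase",
    "apply_treated_eligibility",
    "apply_nh_eligibility",
    "restrict_to_common_mutations",
]

#: Fixed month length (365.25 / 12 days) for all time arithmetic.
DAYS_PER_MONTH = 30.4375

MAX_MONTHS = 60.0  # 5-year eligibility horizon


class Phase(str, Enum):
    SUBACUTE = "subacute"
    DYNAMIC = "dynamic"
    SUBACUTE_DYNAMIC = "subacute_dynamic"
    CHRONIC = "chronic"


@dataclass
class ExclusionLedger:
    """Auditable per-rule exclusion counts.

    Conservation invariant: ``eyes_in == eyes_retained + sum(excluded)``.
    """

    rules: List[str] = field(default_factory=list)
    eyes_excluded: Dict[str, int] = field(default_factory=dict)
    patients_excluded: Dict[str, set] = field(default_factory=dict)
    reasons: Dict[str, str] = field(default_factory=dict)
    eyes_in: int = 0
    eyes_retained: int = 0
    notes: List[str] = field(default_factory=list)

    def add_rule(self, rule: str, reason: str = "") -> None:
        if rule not in self.rules:
            self.rules.append(rule)
            self.eyes_excluded[rule] = 0
            self.patients_excluded[rule] = set()
            self.reasons[rule] = reason

    def exclude(self, rule: str, eye: EyeHistory) -> None:
        self.eyes_excluded[rule] += 1
        self.patients_excluded[rule].add(eye.patient_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": self.rules,
                "patients_excluded": [len(self.patients_excluded[r]) for r in self.rules],
                "eyes_excluded": [self.eyes_excluded[r] for r in self.rules],
                "reason": [self.reasons[r] for r in self.rules],
            }
        )

    @property
    def total_excluded(self) -> int:
        return sum(self.eyes_excluded.values())


def months_since_onset(onset_date: dt.date, reference_date: dt.date) -> float:
    """Elapsed time in months of 30.4375 days."""
    if reference_date < onset_date:
        raise ValueError(
            f"reference date {reference_date} precedes onset {onset_date}"
        )
    return (reference_date - onset_date).days / DAYS_PER_MONTH


def phase_of(eye: EyeHistory, baseline_date: dt.date) -> Phase:
    """Disease phase at a baseline visit.

    Returns the fine-grained label; exactly 12 months counts as dynamic
    (the one-year boundary is inclusive on the subacute/dynamic side).
    """
    if eye.onset_date is None:
        raise ValueError(f"{eye.key}: unknown onset date")
    m = months_since_onset(eye.onset_date, baseline_date)
    if m > MAX_MONTHS:
        raise ValueError(f"{eye.key}: {m:.1f} months since onset exceeds 5 years")
    if m < 6.0:
        return Phase.SUBACUTE
    if m <= 12.0:
        return Phase.DYNAMIC
    return Phase.CHRONIC


def pooled_phase(phase: Phase) -> Phase:
    """Collapse subacute and dynamic into the pooled <=1-year stratum."""
    if phase in (Phase.SUBACUTE, Phase.DYNAMIC, Phase.SUBACUTE_DYNAMIC):
        return Phase.SUBACUTE_DYNAMIC
    return Phase.CHRONIC


def phase_matches(phase: Phase, selection: Phase) -> bool:
    if selection == Phase.SUBACUTE_DYNAMIC:
        return phase in (Phase.SUBACUTE, Phase.DYNAMIC, Phase.SUBACUTE_DYNAMIC)
    return phase == selection


def _age_at(eye: EyeHistory, date: dt.date) -> float:
    """Age in years at a date, from age at onset plus elapsed time."""
    if eye.onset_date is None or eye.age_at_onset != eye.age_at_onset:
        return float("nan")
    return eye.age_at_onset + months_since_onset(eye.onset_date, date) / 12.0


def apply_treated_eligibility(
    histories: Sequence[EyeHistory],
) -> Tuple[List[EyeHistory], ExclusionLedger]:
    """Treated-arm rules: known onset; age >= 12 at baseline; onset <= 5
    years before baseline; treatment-naive."""
    ledger = ExclusionLedger(eyes_in=len(histories))
    ledger.add_rule("unknown_onset", "unknown date of symptom onset")
    ledger.add_rule("age_lt_12", "younger than 12 years at baseline")
    ledger.add_rule("onset_gt_5y", "symptom onset more than 5 years before baseline")
    ledger.add_rule("prior_idebenone", "previous idebenone use")
    retained = []
    for eye in histories:
        baseline_date = eye.baseline[0]
        if eye.onset_date is None:
            ledger.exclude("unknown_onset", eye)
        elif _age_at(eye, baseline_date) < 12.0:
            ledger.exclude("age_lt_12", eye)
        elif months_since_onset(eye.onset_date, baseline_date) > MAX_MONTHS:
            ledger.exclude("onset_gt_5y", eye)
        elif eye.prior_idebenone:
            ledger.exclude("prior_idebenone", eye)
        else:
            retained.append(eye)
    ledger.eyes_retained = len(retained)
    return retained, ledger


def apply_nh_eligibility(
    histories: Sequence[EyeHistory],
) -> Tuple[List[EyeHistory], ExclusionLedger]:
    """Natural-history rules, in order: age >= 12; known onset; onset no
    more than 5 years before the first post-onset visit; at least two VA
    assessments after onset; no previous idebenone use.

    When onset is unknown the age check (which needs elapsed time from
    onset) cannot be evaluated and the eye falls to the unknown-onset
    rule.
    """
    ledger = ExclusionLedger(eyes_in=len(histories))
    ledger.add_rule("age_lt_12", "younger than 12 years at first post-onset visit")
    ledger.add_rule("unknown_onset", "unknown year of symptom onset")
    ledger.add_rule("onset_gt_5y", "symptom onset more than 5 years before first visit")
    ledger.add_rule("lt_2_assessments", "fewer than 2 VA assessments after onset")
    ledger.add_rule("prior_idebenone", "previous idebenone use")
    retained = []
    for eye in histories:
        post_onset = (
            eye.visits_after(eye.onset_date) if eye.onset_date is not None else []
        )
        age = _age_at(eye, post_onset[0][0]) if post_onset else float("nan")
        if age == age and age < 12.0:
            ledger.exclude("age_lt_12", eye)
        elif eye.onset_date is None:
            ledger.exclude("unknown_onset", eye)
        elif post_onset and months_since_onset(eye.onset_date, post_onset[0][0]) > MAX_MONTHS:
            ledger.exclude("onset_gt_5y", eye)
        elif len(post_onset) < 2:
            ledger.exclude("lt_2_assessments", eye)
        elif eye.prior_idebenone:
            ledger.exclude("prior_idebenone", eye)
        else:
            retained.append(eye)
    ledger.eyes_retained = len(retained)
    return retained, ledger


def restrict_to_common_mutations(
    histories: Sequence[EyeHistory],
) -> Tuple[List[EyeHistory], ExclusionLedger]:
    """mITT construction: keep only the three common primary mutations."""
    ledger = ExclusionLedger(eyes_in=len(histories))
    ledger.add_rule("uncommon_mutation", "mutation outside the three common primary mutations")
    retained = []
    for eye in histories:
        if eye.mutation in COMMON_MUTATIONS:
            retained.append(eye)
        else:
            ledger.exclude("uncommon_mutation", eye)
    ledger.eyes_retained = len(retained)
    return retained, ledger


def drop_duplicate_patients(
    histories: Sequence[EyeHistory],
) -> Tuple[List[EyeHistory], ExclusionLedger]:
    """Generic duplicate (patient_id, eye) drop, keeping the first seen."""
    ledger = ExclusionLedger(eyes_in=len(histories))
    ledger.add_rule("duplicate_eye", "duplicate patient-eye record")
    seen = set()
    retained = []
    for eye in histories:
        if (eye.patient_id, eye.eye) in seen:
            ledger.exclude("duplicate_eye", eye)
        else:
            seen.add((eye.patient_id, eye.eye))
            retained.append(eye)
    ledger.eyes_retained = len(retained)
    return retained, ledger
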