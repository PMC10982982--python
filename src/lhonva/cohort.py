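"""Patient-eye histories and the long-format visit-table CSV schema.

The analysis unit is the eye. An :class:`EyeHistory` bundles one eye's
symptom-onset date, its time-ordered acuity series on the canonical
logMAR scale, and the patient covariates the comparative models use
(gender, mtDNA mutation, age at onset, cohort membership).

CSV schema (header mandatory, one row per patient-eye-visit)::

    patient_id, eye, visit_date, va_notation, va_value, cohort,
    gender, mutation, onset_date, age_at_onset, prior_idebenone

``visit_date``/``onset_date`` are ISO-8601; ``onset_date`` may be empty
(unknown onset, handled by eligibility). ``age_at_onset`` and
``prior_idebenone`` are optional extras needed by the eligibility rules.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, List, Optional, Tuple

import pandas as pd

from .va import Eye, Notation, RawVARecord, VAMeasure, VAParseError, parse_va

__all__ = [
    "Gender",
    "Mutation",
    "Cohort",
    "EyeHistory",
    "REQUIRED_COLUMNS",
    "read_visit_table",
    "histories_from_frame",
    "histories_to_frame",
    "write_visit_table",
]

REQUIRED_COLUMNS = [
    "patient_id",
    "eye",
    "visit_date",
    "va_notation",
    "va_value",
    "cohort",
    "gender",
    "mutation",
    "onset_date",
]

OPTIONAL_COLUMNS = {"age_at_onset": float("nan"), "prior_idebenone": False}


class Gender(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Mutation(str, Enum):
    M11778GA = "m11778GA"
    M3460GA = "m3460GA"
    M14484TC = "m14484TC"
    OTHER = "other"


#: The three common primary mutations forming the mITT set.
COMMON_MUTATIONS = (Mutation.M11778GA, Mutation.M3460GA, Mutation.M14484TC)


class Cohort(str, Enum):
    TREATED = "treated"
    NATURAL_HISTORY = "natural_history"


@dataclass
class EyeHistory:
    """One eye's covariates plus its time-ordered visit series."""

    patient_id: str
    eye: Eye
    gender: Gender
    mutation: Mutation
    onset_date: Optional[dt.date]
    age_at_onset: float
    cohort: Cohort
    visits: List[Tuple[dt.date, VAMeasure]] = field(default_factory=list)
    prior_idebenone: bool = False

    def __post_init__(self):
        if not self.visits:
            raise ValueError(f"{self.key}: at least one visit required")
        dates = [d for d, _ in self.visits]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"{self.key}: visits must be strictly date-ordered")
        if self.age_at_onset == self.age_at_onset and self.age_at_onset < 0:
            raise ValueError(f"{self.key}: age_at_onset must be nonnegative")

    @property
    def key(self) -> str:
        return f"{self.patient_id}/{self.eye.value}"

    @property
    def baseline(self) -> Tuple[dt.date, VAMeasure]:
        """First recorded visit (the treated arm's baseline visit)."""
        return self.visits[0]

    def visits_after(self, date: dt.date) -> List[Tuple[dt.date, VAMeasure]]:
        return [(d, m) for d, m in self.visits if d >= date]


def _parse_date(value) -> Optional[dt.date]:
    if value is None or (isinstance(value, float) and value != value):
        return None
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    text = str(value).strip()
    if not text or text.lower() in {"nan", "none", "na", "unknown"}:
        return None
    return dt.date.fromisoformat(text)


def read_visit_table(path) -> pd.DataFrame:
    """Read the visit-table CSV, validating the schema."""
    df = pd.read_csv(path, dtype={"va_value": str, "patient_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"visit table {path} is missing columns: {missing}")
    for col, default in OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = default
    return df


def _raw_record(row) -> RawVARecord:
    notation = Notation(row.va_notation)
    return RawVARecord(
        patient_id=str(row.patient_id),
        eye=Eye(row.eye),
        visit_date=_parse_date(row.visit_date),
        notation=notation,
        value=row.va_value if notation in (Notation.SNELLEN_FRACTION, Notation.OFF_CHART)
        else float(row.va_value),
    )


def histories_from_frame(df: pd.DataFrame) -> List[EyeHistory]:
    """Group a visit table into per-eye histories, converting VA to logMAR.

    Rows are sorted by visit date within each eye; duplicate same-day
    visits raise, since visit ordering would be ambiguous.
    """
    work = df.sort_values(["patient_id", "eye", "visit_date"], kind="mergesort")
    pids = [str(p) for p in work["patient_id"]]
    eyes = list(work["eye"])
    dates = list(work["visit_date"])
    notations = list(work["va_notation"])
    values = list(work["va_value"])
    genders = list(work["gender"])
    mutations = list(work["mutation"])
    onsets = list(work["onset_date"])
    ages = list(work["age_at_onset"]) if "age_at_onset" in work.columns else [float("nan")] * len(work)
    cohorts = list(work["cohort"])
    priors = list(work["prior_idebenone"]) if "prior_idebenone" in work.columns else [False] * len(work)

    histories: List[EyeHistory] = []
    i, n = 0, len(work)
    while i < n:
        j = i
        while j < n and pids[j] == pids[i] and eyes[j] == eyes[i]:
            j += 1
        visits = []
        for k in range(i, j):
            notation = Notation(notations[k])
            rec = RawVARecord(
                patient_id=pids[k],
                eye=Eye(eyes[k]),
                visit_date=_parse_date(dates[k]),
                notation=notation,
                value=values[k]
                if notation in (Notation.SNELLEN_FRACTION, Notation.OFF_CHART)
                else float(values[k]),
            )
            if rec.visit_date is None:
                raise VAParseError(f"record {pids[k]}/{eyes[k]}: missing visit_date")
            visits.append((rec.visit_date, parse_va(rec)))
        try:
            age = float(ages[i])
        except (TypeError, ValueError):
            age = float("nan")
        histories.append(
            EyeHistory(
                patient_id=pids[i],
                eye=Eye(eyes[i]),
                gender=Gender(genders[i]),
                mutation=Mutation(mutations[i]),
                onset_date=_parse_date(onsets[i]),
                age_at_onset=age,
                cohort=Cohort(cohorts[i]),
                visits=visits,
                prior_idebenone=bool(priors[i]),
            )
        )
        i = j
    return histories


def augment_with_logmar(df: pd.DataFrame) -> pd.DataFrame:
    """Return the visit table with logmar / off_chart / parse_warnings columns."""
    out = df.copy()
    logmars, offs, warns = [], [], []
    for row in df.itertuples():
        try:
            measure = parse_va(_raw_record(row))
        except (VAParseError, ValueError) as err:
            logmars.append(float("nan"))
            offs.append(False)
            warns.append(str(err))
            continue
        logmars.append(measure.logmar)
        offs.append(measure.off_chart)
        warns.append("on-chart value above 1.68" if measure.flagged else "")
    out["logmar"] = logmars
    out["off_chart"] = offs
    out["parse_warnings"] = warns
    return out


def histories_to_frame(histories: Iterable[EyeHistory]) -> pd.DataFrame:
    """Serialise histories back to the visit-table schema (logMAR notation).

    Off-chart measures keep their subcategory token; everything else is
    written as logMAR, so the round-trip through
    :func:`histories_from_frame` is exact.
    """
    rows = []
    for h in histories:
        for date, m in h.visits:
            rows.append(
                {
                    "patient_id": h.patient_id,
                    "eye": h.eye.value,
                    "visit_date": date.isoformat(),
                    "va_notation": Notation.OFF_CHART.value if m.off_chart else Notation.LOGMAR.value,
                    "va_value": m.subcategory.value if m.off_chart else f"{m.logmar:.6f}",
                    "cohort": h.cohort.value,
                    "gender": h.gender.value,
                    "mutation": h.mutation.value,
                    "onset_date": h.onset_date.isoformat() if h.onset_date else "",
                    "age_at_onset": h.age_at_onset,
                    "prior_idebenone": h.prior_idebenone,
                }
            )
    return pd.DataFrame(rows)


def write_visit_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
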