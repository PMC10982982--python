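"""Visual-acuity scale handling.

Heterogeneous acuity records (Snellen fractions, decimal scores, logMAR,
off-chart categories) are normalised to a canonical logMAR scale:

* logMAR = -log10(decimal acuity); lower values mean better vision.
* Off-chart readings (counting fingers, hand motion, light perception,
  no light perception) carry no chart measurement and are all imputed
  as 1.8 logMAR; the subcategory is retained for provenance only.
* 1.68 logMAR is the worst measurable on-chart value; values in
  (1.68, 1.8) can occur in converted records and are kept but flagged.

ETDRS chart arithmetic: one chart line = 0.1 logMAR = 5 letters, so a
logMAR change maps to letters at 50 letters per logMAR unit.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Union

__all__ = [
    "Eye",
    "Notation",
    "OffChart",
    "RawVARecord",
    "VAMeasure",
    "VAParseError",
    "ON_CHART_BOUND",
    "OFF_CHART_LOGMAR",
    "LETTERS_PER_LOGMAR",
    "snellen_to_decimal",
    "decimal_to_logmar",
    "off_chart_logmar",
    "parse_va",
    "parse_snellen_string",
    "logmar_delta_to_letters",
]

#: Worst acuity measurable on an ETDRS chart, in logMAR.
ON_CHART_BOUND = 1.68
#: Canonical logMAR value imputed for every off-chart reading.
OFF_CHART_LOGMAR = 1.8
#: ETDRS letters per unit logMAR (5 letters per 0.1-logMAR line).
LETTERS_PER_LOGMAR = 50


class VAParseError(ValueError):
    """Raised when an acuity record cannot be interpreted."""


class Eye(str, Enum):
    RIGHT = "right"
    LEFT = "left"


class Notation(str, Enum):
    SNELLEN_FRACTION = "snellen_fraction"
    DECIMAL = "decimal"
    LOGMAR = "logmar"
    OFF_CHART = "off_chart"


class OffChart(str, Enum):
    COUNTING_FINGERS = "counting_fingers"
    HAND_MOTION = "hand_motion"
    LIGHT_PERCEPTION = "light_perception"
    NO_LIGHT_PERCEPTION = "no_light_perception"


@dataclass(frozen=True)
class RawVARecord:
    """One acuity reading as recorded, before scale conversion.

    ``value`` is notation dependent: a ``(numerator, denominator)`` pair
    (or a string such as ``"20/200"``) for Snellen fractions, a positive
    real for decimal, a real for logMAR, and an :class:`OffChart`
    subcategory (or its string name) for off-chart readings.
    """

    patient_id: str
    eye: Eye
    visit_date: object  # datetime.date
    notation: Notation
    value: Union[tuple, str, float, OffChart]


@dataclass(frozen=True)
class VAMeasure:
    """An acuity reading on the canonical logMAR scale.

    ``off_chart`` readings are always exactly 1.8 logMAR; on-chart
    readings above the 1.68 bound are legal but flagged.
    """

    logmar: float
    off_chart: bool = False
    subcategory: Optional[OffChart] = None
    source_notation: Notation = Notation.LOGMAR
    flagged: bool = False

    def __post_init__(self):
        if not math.isfinite(self.logmar):
            raise VAParseError(f"non-finite logMAR value {self.logmar!r}")
        if self.off_chart and self.logmar != OFF_CHART_LOGMAR:
            raise VAParseError(
                f"off-chart measure must be {OFF_CHART_LOGMAR} logMAR, got {self.logmar}"
            )


def snellen_to_decimal(numerator: float, denominator: float) -> float:
    """Convert a Snellen fraction to a decimal acuity score.

    Only the ratio matters, so feet (20/x) and metre (6/x) notations are
    handled identically.
    """
    if not (numerator > 0 and denominator > 0):
        raise VAParseError(
            f"Snellen numerator and denominator must be positive, got {numerator}/{denominator}"
        )
    return numerator / denominator


def decimal_to_logmar(decimal_acuity: float) -> float:
    """logMAR = -log10(decimal acuity); requires a strictly positive score.

    Off-chart readings have no decimal score and must go through
    :func:`off_chart_logmar` instead.
    """
    if not decimal_acuity > 0:
        raise VAParseError(
            f"decimal acuity must be strictly positive, got {decimal_acuity!r} "
            "(off-chart readings are imputed separately)"
        )
    return -math.log10(decimal_acuity)


def off_chart_logmar(subcategory: Union[OffChart, str]) -> VAMeasure:
    """Impute 1.8 logMAR for an off-chart reading, keeping the subcategory.

    All four subcategories map identically; changes within them are not
    analysed.
    """
    try:
        sub = OffChart(subcategory)
    except ValueError:
        raise VAParseError(f"unknown off-chart subcategory {subcategory!r}") from None
    return VAMeasure(
        logmar=OFF_CHART_LOGMAR,
        off_chart=True,
        subcategory=sub,
        source_notation=Notation.OFF_CHART,
    )


_SNELLEN_RE = re.compile(r"^\s*([0-9]+(?:\.[0-9]+)?)\s*/\s*([0-9]+(?:\.[0-9]+)?)\s*$")


def parse_snellen_string(text: str) -> tuple:
    """Parse ``"20/200"``-style fractions; '/' is the only separator."""
    m = _SNELLEN_RE.match(text)
    if m is None:
        raise VAParseError(f"cannot parse Snellen fraction {text!r}")
    return float(m.group(1)), float(m.group(2))


def parse_va(record: RawVARecord) -> VAMeasure:
    """Normalise one raw record to a :class:`VAMeasure`.

    Dispatch: Snellen → decimal → logMAR; decimal → logMAR; logMAR
    passes through; off-chart is imputed at 1.8. On-chart values above
    the 1.68 bound are kept as given but flagged.
    """
    try:
        if record.notation == Notation.OFF_CHART:
            return off_chart_logmar(record.value)
        if record.notation == Notation.SNELLEN_FRACTION:
            if isinstance(record.value, str):
                num, den = parse_snellen_string(record.value)
            else:
                num, den = record.value
            logmar = decimal_to_logmar(snellen_to_decimal(num, den))
        elif record.notation == Notation.DECIMAL:
            logmar = decimal_to_logmar(float(record.value))
        elif record.notation == Notation.LOGMAR:
            logmar = float(record.value)
            if not math.isfinite(logmar):
                raise VAParseError(f"non-finite logMAR {record.value!r}")
        else:  # pragma: no cover - enum is exhaustive
            raise VAParseError(f"unknown notation {record.notation!r}")
    except VAParseError as err:
        raise VAParseError(
            f"record {record.patient_id}/{record.eye.value}@{record.visit_date}: {err}"
        ) from None
    return VAMeasure(
        logmar=logmar,
        off_chart=False,
        source_notation=record.notation,
        flagged=logmar > ON_CHART_BOUND,
    )


def logmar_delta_to_letters(delta: float, rounding: str = "floor") -> int:
    """ETDRS letters equivalent to a logMAR change (5 letters / 0.1 logMAR).

    The magnitude is used; the default truncation convention reproduces
    published logMAR↔letter pairs (e.g. −0.17 → 8, −0.53 → 26) that
    round-half-up does not. ``rounding`` may be ``"floor"`` or
    ``"nearest"``.
    """
    if not math.isfinite(delta):
        raise VAParseError(f"logMAR delta must be finite, got {delta!r}")
    letters = LETTERS_PER_LOGMAR * abs(delta)
    if rounding == "floor":
        # guard against float droop (0.12*50 = 5.999...)
        return math.floor(round(letters, 9))
    if rounding == "nearest":
        return math.floor(round(letters, 9) + 0.5)  # half rounds up
    raise ValueError(f"rounding must be 'floor' or 'nearest', got {rounding!r}")
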