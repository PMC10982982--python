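import datetime as dt

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from lhonva.cohort import Cohort, EyeHistory, Gender, Mutation
from lhonva.va import Eye, VAMeasure

ONSET = dt.date(2020, 1, 1)
DAYS_PER_MONTH = 30.4375


def months_to_date(months: float, onset: dt.date = ONSET) -> dt.date:
    return onset + dt.timedelta(days=round(months * DAYS_PER_MONTH))


def measure(logmar: float, off_chart: bool = False) -> VAMeasure:
    return VAMeasure(logmar=1.8 if off_chart else logmar, off_chart=off_chart)


def make_eye(
    visit_months,
    values=None,
    *,
    patient_id="P1",
    eye=Eye.RIGHT,
    onset=ONSET,
    cohort=Cohort.NATURAL_HISTORY,
    gender=Gender.MALE,
    mutation=Mutation.M11778GA,
    age_at_onset=30.0,
    prior_idebenone=False,
) -> EyeHistory:
    """Build an eye history from visit times in months since onset."""
    if values is None:
        values = [1.0] * len(visit_months)
    visits = [
        (months_to_date(m, onset), v if isinstance(v, VAMeasure) else measure(v))
        for m, v in zip(visit_months, values)
    ]
    return EyeHistory(
        patient_id=patient_id,
        eye=eye,
        gender=gender,
        mutation=mutation,
        onset_date=onset,
        age_at_onset=age_at_onset,
        cohort=cohort,
        visits=visits,
        prior_idebenone=prior_idebenone,
    )


@pytest.fixture(scope="session")
def small_cohorts():
    """A 40-patient simulated pair of cohorts, shared across tests."""
    from lhonva.simulate import SimConfig, simulate_cohorts

    return simulate_cohorts(SimConfig(seed=7, n_patients=40))
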