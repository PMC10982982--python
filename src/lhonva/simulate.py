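"""Synthetic LHON cohort generator.

Emulates the longitudinal, notational and biological structure of the
treated trial arm and the retrospective natural-history (NH) surveys:

* subacute decline from near-normal acuity to a nadir within about six
  months of symptom onset, then a plateau;
* mutation-dependent spontaneous recovery (m.14484T>C carries the most
  favourable prognosis) beginning 6-18 months after onset and ramping
  in over several months;
* an optional treatment effect: an additive log-odds shift on the
  probability of recovery and/or an additive logMAR drift from
  treatment start;
* trial-style scheduled visits for the treated cohort (baseline plus
  months 1, 3, 6, 12, 18, 24) versus irregular record-survey visits
  for the NH cohort;
* mixed NH notations (Snellen fractions snapped to standard chart
  lines, decimal scores, logMAR) with measurement noise, off-chart
  records whenever the measured value exceeds the 1.68 on-chart bound,
  and configurable unknown-onset / single-visit injections.

The generator is a study-conditions definition, not a fitting target:
its defaults are fixed, documented choices, and a fixed seed reproduces
every record exactly.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .cohort import Cohort, Gender, Mutation
from .va import ON_CHART_BOUND, OffChart

__all__ = ["SimConfig", "Trajectory", "simulate_trajectory", "emit_visits", "simulate_cohorts"]

#: Standard Snellen chart lines (feet notation denominators).
SNELLEN_DENOMINATORS = (
    20, 25, 32, 40, 50, 63, 80, 100, 125, 160, 200, 250, 320, 400, 500, 640, 800, 1000,
)
_SNELLEN_LOGMAR = np.array([-math.log10(20.0 / d) for d in SNELLEN_DENOMINATORS])

TREATED_SCHEDULE = (0.0, 1.0, 3.0, 6.0, 12.0, 18.0, 24.0)


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic cohort generator.

    All times are months since symptom onset unless noted; acuities are
    logMAR. Defaults describe a subacute/dynamic-phase study population.
    """

    n_patients: int = 100
    phase: str = "subacute_dynamic"  # baseline placement: <=1y or >1-5y
    mutation_mix: Dict[str, float] = field(
        default_factory=lambda: {"m11778GA": 0.60, "m3460GA": 0.20, "m14484TC": 0.20}
    )
    male_fraction: float = 0.75
    age_mean: float = 32.5
    age_sd: float = 14.0
    age_min: float = 8.0
    nadir_time_mean: float = 6.0
    nadir_time_sd: float = 2.0
    rapid_drop_months: float = 1.5  # steep initial loss completes here
    rapid_drop_fraction: float = 0.85  # fraction of nadir depth lost by then
    nadir_depth_mean: float = 1.45
    nadir_depth_sd: float = 0.35
    nadir_depth_range: Tuple[float, float] = (0.3, 1.8)
    recovery_prob: Dict[str, float] = field(
        default_factory=lambda: {"m11778GA": 0.15, "m3460GA": 0.20, "m14484TC": 0.50}
    )
    recovery_onset_range: Tuple[float, float] = (6.0, 18.0)
    recovery_ramp_months: float = 6.0
    recovered_level_mean: float = 0.5
    recovered_level_sd: float = 0.25
    recovered_level_range: Tuple[float, float] = (0.0, 1.0)
    recovery_margin_min: float = 0.25  # recovery improves >= this from nadir
    treatment_log_odds: float = 0.8
    treatment_drift: float = 0.0  # logMAR per year from treatment start
    noise_sd: float = 0.05
    visit_jitter_sd: float = 0.3
    notation_mix: Dict[str, float] = field(
        default_factory=lambda: {"snellen_fraction": 0.653, "decimal": 0.185, "logmar": 0.162}
    )
    missing_visit_prob: float = 0.10
    p_unknown_onset: float = 0.05
    p_single_visit: float = 0.05
    nh_extra_visits_mean: float = 4.0
    baseline_month_mean: float = 6.0
    baseline_month_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name, mix in (("mutation_mix", self.mutation_mix), ("notation_mix", self.notation_mix)):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1, got {total}")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{name} proportions must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for p in (self.missing_visit_prob, self.p_unknown_onset, self.p_single_visit,
                  self.male_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if self.phase not in ("subacute_dynamic", "chronic"):
            raise ValueError(f"phase must be subacute_dynamic or chronic, got {self.phase!r}")


@dataclass
class Trajectory:
    """Latent (noise-free) logMAR course of one eye.

    Piecewise linear decline from ~0 logMAR, steep at first (a fraction
    ``rapid_fraction`` of the depth is lost by ``rapid_months``), then
    creeping to ``nadir_depth`` at ``nadir_time``; a plateau; and, for
    recoverers, a linear improvement toward the drawn
    ``recovered_level`` starting at ``recovery_onset`` and completing
    over ``recovery_ramp`` months. Values are clipped to [-0.3, 1.8].
    """

    nadir_time: float
    nadir_depth: float
    recoverer: bool
    recovery_onset: float
    recovered_level: float
    recovery_ramp: float
    rapid_months: float = 1.5
    rapid_fraction: float = 0.85
    drift_per_year: float = 0.0
    drift_start: float = 0.0

    @property
    def recovery_amount(self) -> float:
        """Improvement from nadir once recovery has completed."""
        return self.nadir_depth - self.recovered_level if self.recoverer else 0.0

    def value(self, months):
        t = np.asarray(months, dtype=float)
        if self.nadir_time > self.rapid_months:
            frac = np.where(
                t <= self.rapid_months,
                self.rapid_fraction * t / self.rapid_months,
                self.rapid_fraction
                + (1.0 - self.rapid_fraction)
                * np.clip(
                    (t - self.rapid_months) / (self.nadir_time - self.rapid_months),
                    0.0,
                    1.0,
                ),
            )
        else:
            frac = np.minimum(t / self.nadir_time, 1.0)
        v = frac * self.nadir_depth
        if self.recoverer:
            progress = np.clip((t - self.recovery_onset) / self.recovery_ramp, 0.0, 1.0)
            v = v - progress * (self.nadir_depth - self.recovered_level)
        if self.drift_per_year != 0.0:
            v = v + self.drift_per_year * np.maximum(t - self.drift_start, 0.0) / 12.0
        return np.clip(v, -0.3, 1.8)


def simulate_trajectory(
    rng: np.random.Generator,
    mutation: Mutation,
    treated: bool,
    config: SimConfig,
    treatment_start: float = 0.0,
) -> Trajectory:
    """Draw one eye's latent disease course."""
    nadir_time = max(1.0, rng.normal(config.nadir_time_mean, config.nadir_time_sd))
    nadir_depth = float(
        np.clip(
            rng.normal(config.nadir_depth_mean, config.nadir_depth_sd),
            *config.nadir_depth_range,
        )
    )
    p = config.recovery_prob[mutation.value]
    if p <= 0.0 or p >= 1.0:
        p_eff = p  # degenerate propensity: treatment cannot move it
    else:
        logit = math.log(p / (1.0 - p))
        if treated:
            logit += config.treatment_log_odds
        p_eff = 1.0 / (1.0 + math.exp(-logit))
    recoverer = bool(rng.random() < p_eff)
    level = float(
        np.clip(
            rng.normal(config.recovered_level_mean, config.recovered_level_sd),
            *config.recovered_level_range,
        )
    )
    # a recovery always improves by at least the margin from nadir
    level = min(level, nadir_depth - config.recovery_margin_min)
    return Trajectory(
        nadir_time=nadir_time,
        nadir_depth=nadir_depth,
        recoverer=recoverer,
        recovery_onset=float(rng.uniform(*config.recovery_onset_range)),
        recovered_level=level,
        recovery_ramp=config.recovery_ramp_months,
        rapid_months=config.rapid_drop_months,
        rapid_fraction=config.rapid_drop_fraction,
        drift_per_year=config.treatment_drift if treated else 0.0,
        drift_start=treatment_start,
    )


def _off_chart_subcategory(value: float) -> OffChart:
    """Assign an off-chart subcategory by latent severity band."""
    if value <= 1.72:
        return OffChart.COUNTING_FINGERS
    if value <= 1.76:
        return OffChart.HAND_MOTION
    if value < 1.80:
        return OffChart.LIGHT_PERCEPTION
    return OffChart.NO_LIGHT_PERCEPTION


def _snap_snellen(logmar: float) -> Tuple[int, int]:
    """Nearest standard Snellen line to a logMAR value (feet notation)."""
    idx = int(np.argmin(np.abs(_SNELLEN_LOGMAR - logmar)))
    return 20, SNELLEN_DENOMINATORS[idx]


def emit_visits(
    trajectory: Trajectory,
    visit_months: np.ndarray,
    rng: np.random.Generator,
    config: SimConfig,
    mixed_notation: bool,
) -> List[Tuple[float, str, str]]:
    """Render a latent trajectory as (months, notation, value) records.

    Gaussian measurement noise is added, values above the 1.68 on-chart
    bound become off-chart subcategory records, and on-chart values are
    emitted in a notation drawn from the configured mix (all-logMAR for
    the chart-based treated arm).
    """
    latent = trajectory.value(visit_months)
    noise = rng.normal(0.0, config.noise_sd, size=len(visit_months)) if config.noise_sd else 0.0
    measured = np.clip(latent + noise, -0.3, 1.8)
    if mixed_notation:
        names = list(config.notation_mix)
        notations = rng.choice(names, size=len(visit_months), p=[config.notation_mix[n] for n in names])
    else:
        notations = ["logmar"] * len(visit_months)
    records = []
    for months, value, notation in zip(visit_months, measured, notations):
        if value > ON_CHART_BOUND:
            records.append((float(months), "off_chart", _off_chart_subcategory(float(value)).value))
        elif notation == "snellen_fraction":
            num, den = _snap_snellen(float(value))
            records.append((float(months), "snellen_fraction", f"{num}/{den}"))
        elif notation == "decimal":
            decimal = max(0.01, round(10.0 ** (-float(value)), 2))
            records.append((float(months), "decimal", f"{decimal:g}"))
        else:
            records.append((float(months), "logmar", f"{float(value):.2f}"))
    return records


def _draw_age(rng: np.random.Generator, config: SimConfig) -> float:
    for _ in range(100):
        age = rng.normal(config.age_mean, config.age_sd)
        if age >= config.age_min:
            return float(round(age, 1))
    return config.age_min


def _months_to_date(onset: dt.date, months: float) -> dt.date:
    return onset + dt.timedelta(days=round(months * 30.4375))


def _simulate_one_cohort(
    rng: np.random.Generator, config: SimConfig, cohort: Cohort, id_prefix: str
) -> pd.DataFrame:
    mutations = list(config.mutation_mix)
    mut_probs = [config.mutation_mix[m] for m in mutations]
    treated = cohort == Cohort.TREATED
    rows = []
    for i in range(config.n_patients):
        pid = f"{id_prefix}{i:04d}"
        gender = Gender.MALE if rng.random() < config.male_fraction else Gender.FEMALE
        mutation = Mutation(rng.choice(mutations, p=mut_probs))
        age = _draw_age(rng, config)
        onset_first = dt.date(2008, 1, 1) + dt.timedelta(days=int(rng.integers(0, 3653)))
        second_gap = float(rng.uniform(0.0, 3.0))
        unknown_onset = (not treated) and rng.random() < config.p_unknown_onset
        if treated:
            # one baseline visit per patient, after both eyes' onsets and
            # inside the requested phase window for both eyes
            if config.phase == "subacute_dynamic":
                # enrollment follows established vision loss: at least the
                # rapid-drop period after the later eye's onset
                baseline_month = float(
                    np.clip(
                        rng.normal(config.baseline_month_mean, config.baseline_month_sd),
                        second_gap + config.rapid_drop_months,
                        11.5,
                    )
                )
            else:
                baseline_month = float(rng.uniform(12.5 + second_gap, 57.0))
        for eye_name, onset_gap in (("right", 0.0), ("left", second_gap)):
            onset = _months_to_date(onset_first, onset_gap)
            # visit times are months since this eye's own onset
            eye_baseline = (baseline_month - onset_gap) if treated else 0.0
            trajectory = simulate_trajectory(
                rng, mutation, treated, config, treatment_start=eye_baseline
            )
            if treated:
                # scheduled follow-up; baseline visit itself is never dropped
                months = [eye_baseline]
                for offset in TREATED_SCHEDULE[1:]:
                    if rng.random() < config.missing_visit_prob:
                        continue
                    jitter = rng.normal(0.0, config.visit_jitter_sd)
                    months.append(eye_baseline + offset + jitter)
            else:
                n_visits = 2 + int(rng.poisson(config.nh_extra_visits_mean))
                months = sorted(float(m) for m in rng.uniform(0.5, 59.0, size=n_visits))
                if rng.random() < config.p_single_visit:
                    months = months[:1]
            records = emit_visits(
                trajectory, np.asarray(months), rng, config, mixed_notation=not treated
            )
            seen_days = set()
            for visit_months, notation, value in records:
                date = _months_to_date(onset, visit_months)
                if date in seen_days:  # one visit per calendar day
                    continue
                seen_days.add(date)
                rows.append(
                    {
                        "patient_id": pid,
                        "eye": eye_name,
                        "visit_date": date.isoformat(),
                        "va_notation": notation,
                        "va_value": value,
                        "cohort": cohort.value,
                        "gender": gender.value,
                        "mutation": mutation.value,
                        "onset_date": "" if unknown_onset else onset.isoformat(),
                        "age_at_onset": age,
                        "prior_idebenone": False,
                    }
                )
    return pd.DataFrame(rows)


def simulate_cohorts(config: SimConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (treated, natural-history) visit tables.

    Both frames follow the visit-table CSV schema. The treated cohort
    gets a baseline visit inside the requested phase window and the
    trial's scheduled follow-up; the NH cohort gets irregular survey
    visits plus the configured unknown-onset and single-visit
    injections. ``config.n_patients`` patients (two eyes each) are
    drawn per cohort; the same seed reproduces the output exactly.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    treated = _simulate_one_cohort(
        np.random.default_rng(seeds[0]), config, Cohort.TREATED, "T"
    )
    nh = _simulate_one_cohort(
        np.random.default_rng(seeds[1]), config, Cohort.NATURAL_HISTORY, "N"
    )
    return treated, nh
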