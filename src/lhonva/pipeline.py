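"""End-to-end pipeline: convert -> filter -> match -> classify -> compare.

The stages compose the analysis in its natural order: raw visit tables
are normalised to logMAR, eligibility rules produce the analysis
cohorts with an exclusion ledger, natural-history baselines are matched
on time since onset, eyes are classified into responder outcomes, and
the comparative models are fitted per phase and timepoint. All outputs
are plain CSV/JSON and a fixed seed makes reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    EyeHistory,
    histories_from_frame,
    read_visit_table,
    write_visit_table,
)
from .eligibility import (
    Phase,
    apply_nh_eligibility,
    apply_treated_eligibility,
    restrict_to_common_mutations,
)
from .matching import MatchingConfig, build_matched_dataset, compute_onset_L
from .responder import classify_dataset, rates_report, responder_rates
from .simulate import SimConfig, simulate_cohorts
from .stats import ancova_va_change, km_first_crr, logistic_compare

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source is active: either both CSV paths or
    ``simulate=True`` (with ``sim`` parameterising the generator).
    """

    treated_path: Optional[str] = None
    nh_path: Optional[str] = None
    simulate: bool = False
    sim: Optional[SimConfig] = None
    phase: Phase = Phase.SUBACUTE_DYNAMIC
    timepoints: Tuple[float, ...] = (12.0, 24.0)
    window_halfwidth: float = 3.0
    onset_L_override: Optional[float] = None
    outcomes: Tuple[str, ...] = ("crb", "crr", "crs", "crw")
    covariates: Tuple[str, ...] = ("treatment", "gender", "mutation")
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        has_paths = self.treated_path is not None and self.nh_path is not None
        if has_paths == self.simulate:
            raise ValueError(
                "exactly one of (treated+nh input paths, simulate) must be active"
            )
        if self.simulate and self.sim is None:
            self.sim = SimConfig(seed=self.seed)


@dataclass
class PipelineResult:
    """Bundle of every table a run produces."""

    matched: Dict[float, pd.DataFrame]
    rates: Dict[float, pd.DataFrame]
    comparisons: pd.DataFrame
    ancova: pd.DataFrame
    km_table: pd.DataFrame
    km_incidence: pd.DataFrame
    ledgers: Dict[str, pd.DataFrame]
    onset_L: float
    config: PipelineConfig


def _load_histories(config: PipelineConfig) -> Tuple[List[EyeHistory], List[EyeHistory]]:
    if config.simulate:
        treated_df, nh_df = simulate_cohorts(config.sim)
    else:
        treated_df = read_visit_table(config.treated_path)
        nh_df = read_visit_table(config.nh_path)
    return histories_from_frame(treated_df), histories_from_frame(nh_df)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis; optionally write the output bundle.

    Raises when the matched dataset is empty at every timepoint (there
    is nothing to compare).
    """
    treated_all, nh_all = _load_histories(config)

    treated, led_t = apply_treated_eligibility(treated_all)
    treated, led_tm = restrict_to_common_mutations(treated)
    nh, led_n = apply_nh_eligibility(nh_all)
    nh, led_nm = restrict_to_common_mutations(nh)
    ledgers = {
        "treated_eligibility": led_t.to_frame(),
        "treated_mitt": led_tm.to_frame(),
        "nh_eligibility": led_n.to_frame(),
        "nh_mitt": led_nm.to_frame(),
    }

    onset_L = (
        config.onset_L_override
        if config.onset_L_override is not None
        else compute_onset_L(treated)
    )
    match_config = MatchingConfig(
        onset_L=onset_L, window_halfwidth=config.window_halfwidth
    )

    matched: Dict[float, pd.DataFrame] = {}
    rates: Dict[float, pd.DataFrame] = {}
    comparison_rows = []
    ancova_rows = []
    for tp in config.timepoints:
        table, led_match = build_matched_dataset(
            treated, nh, config.phase, tp, match_config
        )
        ledgers[f"matching_{int(tp)}m"] = led_match.to_frame()
        if table.empty:
            matched[tp] = table
            rates[tp] = pd.DataFrame()
            continue
        classified = classify_dataset(table)
        matched[tp] = classified
        rates[tp] = responder_rates(classified)
        for outcome in config.outcomes:
            result = logistic_compare(classified, outcome, config.covariates)
            row = result.to_row()
            row["timepoint"] = tp
            for group, (num, den) in result.counts.items():
                row[f"{group}_n"] = f"{num}/{den}"
            comparison_rows.append(row)
        both_groups = classified["group"].nunique() == 2
        if both_groups:
            try:
                anc = ancova_va_change(classified)
            except ValueError:
                anc = None  # aliased design (tiny/degenerate dataset)
        if both_groups and anc is not None:
            ancova_rows.append(
                {
                    "timepoint": tp,
                    "lsmean_difference": anc.lsmean_difference,
                    "ci_low": anc.ci95[0],
                    "ci_high": anc.ci95[1],
                    "p_value": anc.p_value,
                    "n_treated": anc.n[Cohort.TREATED.value],
                    "n_natural_history": anc.n[Cohort.NATURAL_HISTORY.value],
                }
            )
    if all(df.empty for df in matched.values()):
        raise RuntimeError("matched dataset is empty at every timepoint")

    km = km_first_crr(treated) if treated else None
    km_incidence = pd.DataFrame(
        [{"month": m, "cumulative_incidence": v} for m, v in km.incidence_at.items()]
    )

    result = PipelineResult(
        matched=matched,
        rates=rates,
        comparisons=pd.DataFrame(comparison_rows),
        ancova=pd.DataFrame(ancova_rows),
        km_table=km.table,
        km_incidence=km_incidence,
        ledgers=ledgers,
        onset_L=onset_L,
        config=config,
    )
    if config.out_dir is not None:
        _write_bundle(result, Path(config.out_dir))
    return result


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["phase"] = config.phase.value
    echo.pop("out_dir", None)  # analysis config only, not output location
    return echo


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    """Write every table; contents depend only on config+seed, so two
    identical runs produce byte-identical bundles."""
    out_dir.mkdir(parents=True, exist_ok=True)
    for tp, df in result.matched.items():
        write_visit_table(df, out_dir / f"matched_{int(tp)}m.csv")
    for tp, df in result.rates.items():
        write_visit_table(df, out_dir / f"responder_rates_{int(tp)}m.csv")
        if not df.empty:
            (out_dir / f"responder_report_{int(tp)}m.txt").write_text(
                rates_report(df) + "\n"
            )
    write_visit_table(result.comparisons, out_dir / "comparisons.csv")
    write_visit_table(result.ancova, out_dir / "ancova.csv")
    write_visit_table(result.km_table, out_dir / "km_first_crr.csv")
    write_visit_table(result.km_incidence, out_dir / "km_incidence.csv")
    for name, df in result.ledgers.items():
        write_visit_table(df, out_dir / f"ledger_{name}.csv")
    metadata = {
        "package_version": __version__,
        "seed": result.config.seed,
        "onset_L_months": result.onset_L,
        "config": _config_echo(result.config),
    }
    (out_dir / "run_metadata.json").write_text(
        json.dumps(metadata, indent=2, sort_keys=True, default=str) + "\n"
    )
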