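"""Comparative statistics for matched treated-vs-natural-history datasets.

Responder outcomes are compared with a logistic regression including
treatment, gender and mutation as fixed factors (treatment effect
reported as an odds ratio with a Wald 95% CI and two-sided p); change
in acuity with an ANCOVA on baseline logMAR plus the same factors; time
to first recovery with Kaplan-Meier product-limit estimates; and the
trial-design sample size with the normal-approximation two-proportion
formula (variance pooled under the null, unpooled under the
alternative). All p values are exploratory: no multiplicity adjustment
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort, EyeHistory
from .eligibility import DAYS_PER_MONTH
from .responder import TriState, classify_crr, classify_dataset

__all__ = [
    "ComparisonResult",
    "SampleSizeSpec",
    "KMEstimate",
    "crude_odds_ratio",
    "logistic_compare",
    "ancova_va_change",
    "km_first_crr",
    "sample_size_two_proportions",
    "sensitivity_window_rerun",
]

Z975 = sps.norm.ppf(0.975)


@dataclass
class ComparisonResult:
    """Treatment-effect estimate for one outcome."""

    outcome: str
    odds_ratio: float
    ci95: Tuple[float, float]
    p_value: float
    counts: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    covariates: Tuple[str, ...] = ()
    estimable: bool = True
    warnings: List[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "p_value": self.p_value,
            "estimable": self.estimable,
            "covariates": "+".join(self.covariates),
            "warnings": "; ".join(self.warnings),
        }


@dataclass
class SampleSizeSpec:
    """Inputs of the two-proportion sample-size calculation."""

    p_control: float
    p_treated: float
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self):
        for p in (self.p_control, self.p_treated):
            if not 0.0 < p < 1.0:
                raise ValueError(f"proportions must lie in (0,1), got {p}")
        if self.p_control == self.p_treated:
            raise ValueError("p_control and p_treated must differ (effect size zero)")
        if not 0.0 < self.alpha < 1.0 or not 0.0 < self.power < 1.0:
            raise ValueError("alpha and power must lie in (0,1)")


@dataclass
class KMEstimate:
    """Product-limit estimate of cumulative incidence of first recovery."""

    table: pd.DataFrame  # time, at_risk, events, censored, incidence
    incidence_at: Dict[float, float]
    n_eyes: int
    n_events: int

    def incidence(self, month: float) -> float:
        return self.incidence_at[month]


def crude_odds_ratio(a: int, b: int, c: int, d: int) -> ComparisonResult:
    """2x2 cross-product odds ratio with a Wald CI on the log scale.

    Layout: a/b = treated responders/non-responders, c/d = control. A
    0.5 continuity correction is applied to every cell iff any cell is
    zero; a table with an empty margin is not estimable.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return ComparisonResult(
            outcome="crude",
            odds_ratio=float("nan"),
            ci95=(float("nan"), float("nan")),
            p_value=float("nan"),
            counts={"treated": (a, a + b), "natural_history": (c, c + d)},
            estimable=False,
            warnings=["empty table margin"],
        )
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if min(a, b, c, d) == 0 else (a, b, c, d)
    )
    log_or = math.log((aa * dd) / (bb * cc))
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = log_or / se
    return ComparisonResult(
        outcome="crude",
        odds_ratio=math.exp(log_or),
        ci95=(math.exp(log_or - Z975 * se), math.exp(log_or + Z975 * se)),
        p_value=2 * sps.norm.sf(abs(z)),
        counts={"treated": (a, a + b), "natural_history": (c, c + d)},
        warnings=["continuity correction applied"] if min(a, b, c, d) == 0 else [],
    )


def _design_matrix(
    df: pd.DataFrame, covariates: Sequence[str], extra_numeric: Sequence[str] = ()
) -> Tuple[np.ndarray, List[str]]:
    """Intercept + treatment indicator + dummy-coded factors (+ numeric
    columns). The treatment column is always index 1."""
    cols: List[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    cols.append((df["group"] == Cohort.TREATED.value).to_numpy(dtype=float))
    names.append("treatment")
    for cov in covariates:
        if cov == "treatment":
            continue
        levels = sorted(df[cov].astype(str).unique())
        for level in levels[1:]:  # first level is the reference
            cols.append((df[cov].astype(str) == level).to_numpy(dtype=float))
            names.append(f"{cov}[{level}]")
    for cov in extra_numeric:
        cols.append(df[cov].to_numpy(dtype=float))
        names.append(cov)
    return np.column_stack(cols), names


def _fit_logit(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """Newton-Raphson ML logistic fit (optionally L2-penalised).

    Iterates to relative log-likelihood change < 1e-8, at most 100
    iterations. Returns (beta, covariance, converged).
    """
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -np.inf
    cov = None
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + ridge * np.eye(k)
        g = X.T @ (y - mu) - ridge * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        eta = np.clip(X @ beta, -30, 30)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum()) - 0.5 * ridge * beta @ beta
        if abs(ll - ll_old) < 1e-8 * (abs(ll_old) + 1e-8):
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            H = X.T @ (X * w[:, None]) + ridge * np.eye(k)
            cov = np.linalg.inv(H)
            return beta, cov, True
        ll_old = ll
    mu = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
    w = mu * (1.0 - mu)
    H = X.T @ (X * w[:, None]) + ridge * np.eye(k)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = None
    return beta, cov, False


def logistic_compare(
    classified: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = ("treatment", "gender", "mutation"),
    age_interaction: bool = False,
) -> ComparisonResult:
    """Treatment odds ratio for a responder outcome, adjusted for the
    fixed factors, from a maximum-likelihood logistic fit.

    Rows ineligible for the outcome are dropped (they are outside the
    denominator). Complete or quasi-complete separation triggers a
    ridge-penalised refit, flagged in ``warnings``. With
    ``age_interaction`` an under/over-18 age-group factor and its
    treatment interaction are added.
    """
    df = classified
    if outcome in ("crs", "crw"):
        df = df[df[outcome] != TriState.NOT_ELIGIBLE.value]
        y = (df[outcome] == TriState.TRUE.value).to_numpy(dtype=float)
    else:
        y = df[outcome].to_numpy(dtype=float)
    counts = {}
    for group in (Cohort.TREATED.value, Cohort.NATURAL_HISTORY.value):
        mask = (df["group"] == group).to_numpy()
        counts[group] = (int(y[mask].sum()), int(mask.sum()))
    if min(n for _, n in counts.values()) == 0:
        return ComparisonResult(
            outcome=outcome,
            odds_ratio=float("nan"),
            ci95=(float("nan"), float("nan")),
            p_value=float("nan"),
            counts=counts,
            covariates=tuple(covariates),
            estimable=False,
            warnings=["a group has no eligible eyes"],
        )
    if y.min() == y.max():
        return ComparisonResult(
            outcome=outcome,
            odds_ratio=float("nan"),
            ci95=(float("nan"), float("nan")),
            p_value=float("nan"),
            counts=counts,
            covariates=tuple(covariates),
            estimable=False,
            warnings=["outcome constant in both groups"],
        )
    work = df.copy()
    extra_numeric: List[str] = []
    factor_covs = [c for c in covariates if c != "treatment"]
    if age_interaction:
        work["age_group"] = np.where(
            work["age_at_onset"].to_numpy(dtype=float) < 18.0, "lt18", "ge18"
        )
        factor_covs.append("age_group")
        work["treat_x_age"] = (
            (work["group"] == Cohort.TREATED.value) & (work["age_group"] == "lt18")
        ).astype(float)
        extra_numeric.append("treat_x_age")
    if "time_since_onset" in covariates:
        factor_covs.remove("time_since_onset")
        work = work.rename(columns={"months_since_onset": "time_since_onset"})
        extra_numeric.append("time_since_onset")
    X, names = _design_matrix(work, factor_covs, extra_numeric)
    # drop constant dummy columns (factors without variation in this subset)
    keep = [i for i in range(X.shape[1]) if i == 0 or X[:, i].std() > 0]
    X, names = X[:, keep], [names[i] for i in keep]
    warnings: List[str] = []
    beta, cov, converged = _fit_logit(X, y)
    separated = (
        cov is None
        or not converged
        or not np.all(np.isfinite(np.sqrt(np.clip(np.diag(cov), 0, None))))
        or np.sqrt(max(cov[1, 1], 0.0)) > 50
    )
    if separated:
        warnings.append("separation detected; ridge-penalised fit used")
        beta, cov, _ = _fit_logit(X, y, ridge=1e-3)
        if cov is None:
            return ComparisonResult(
                outcome=outcome,
                odds_ratio=float("nan"),
                ci95=(float("nan"), float("nan")),
                p_value=float("nan"),
                counts=counts,
                covariates=tuple(covariates),
                estimable=False,
                warnings=warnings + ["penalised fit failed"],
            )
    i = names.index("treatment")
    log_or = float(beta[i])
    se = float(math.sqrt(max(cov[i, i], 0.0)))
    z = log_or / se if se > 0 else float("nan")
    return ComparisonResult(
        outcome=outcome,
        odds_ratio=math.exp(log_or),
        ci95=(math.exp(log_or - Z975 * se), math.exp(log_or + Z975 * se)),
        p_value=2 * sps.norm.sf(abs(z)) if se > 0 else float("nan"),
        counts=counts,
        covariates=tuple(covariates),
        warnings=warnings,
    )


@dataclass
class AncovaResult:
    """Adjusted treatment difference in logMAR change from baseline."""

    lsmean_difference: float  # treated minus NH; negative favours treatment
    ci95: Tuple[float, float]
    p_value: float
    n: Dict[str, int]
    terms: pd.DataFrame


def ancova_va_change(classified: pd.DataFrame) -> AncovaResult:
    """ANCOVA of endpoint-minus-baseline logMAR change on treatment,
    gender, mutation and baseline logMAR (the covariate).

    The treatment coefficient is the adjusted (LS-mean) treated-minus-NH
    difference. A rank-deficient design raises, naming the aliased term.
    """
    import statsmodels.api as sm

    df = classified
    X, names = _design_matrix(df, ["gender", "mutation"], ["baseline_logmar"])
    keep = [i for i in range(X.shape[1]) if i == 0 or X[:, i].std() > 0]
    X, names = X[:, keep], [names[i] for i in keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the first column linearly dependent on its predecessors
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                raise ValueError(f"design is rank deficient: term {names[j]!r} is aliased")
        raise ValueError("design is rank deficient")
    y = (df["endpoint_logmar"] - df["baseline_logmar"]).to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    i = names.index("treatment")
    ci = fit.conf_int()[i]
    terms = pd.DataFrame(
        {
            "term": names,
            "estimate": fit.params,
            "se": fit.bse,
            "ci_low": fit.conf_int()[:, 0],
            "ci_high": fit.conf_int()[:, 1],
            "p_value": fit.pvalues,
        }
    )
    n = {
        g: int((df["group"] == g).sum())
        for g in (Cohort.TREATED.value, Cohort.NATURAL_HISTORY.value)
    }
    return AncovaResult(
        lsmean_difference=float(fit.params[i]),
        ci95=(float(ci[0]), float(ci[1])),
        p_value=float(fit.pvalues[i]),
        n=n,
        terms=terms,
    )


def km_first_crr(
    histories: Sequence[EyeHistory],
    report_months: Sequence[float] = (6.0, 12.0, 18.0, 24.0),
    max_months: float = 24.0,
) -> KMEstimate:
    """Kaplan-Meier cumulative incidence of a first recovery (CRR) from
    baseline as a function of treatment duration.

    Each eye's event is the first post-baseline visit at which the CRR
    criterion from its baseline acuity is met; otherwise the eye is
    censored at its last visit (capped at ``max_months``). Event times
    are visit times; interval censoring between visits is ignored.
    """
    from lifelines import KaplanMeierFitter

    if not histories:
        raise ValueError("no eyes provided")
    durations, events = [], []
    for eye in histories:
        b_date, b_meas = eye.baseline
        t_event = None
        t_last = 0.0
        for f_date, f_meas in eye.visits[1:]:
            t = (f_date - b_date).days / DAYS_PER_MONTH
            if t > max_months + 1e-9:
                break
            t_last = t
            if classify_crr(b_meas, f_meas):
                t_event = t
                break
        if t_event is not None:
            durations.append(t_event)
            events.append(1)
        else:
            durations.append(t_last)
            events.append(0)
    if all(d == 0 for d in durations):
        raise ValueError("no follow-up time observed")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    ev = kmf.event_table
    incidence = 1.0 - kmf.survival_function_["KM_estimate"]
    table = pd.DataFrame(
        {
            "time": ev.index.to_numpy(dtype=float),
            "at_risk": ev["at_risk"].to_numpy(dtype=int),
            "events": ev["observed"].to_numpy(dtype=int),
            "censored": ev["censored"].to_numpy(dtype=int),
            "incidence": incidence.to_numpy(dtype=float),
        }
    )
    incidence_at = {
        float(m): float(1.0 - kmf.predict(m)) for m in report_months
    }
    return KMEstimate(
        table=table,
        incidence_at=incidence_at,
        n_eyes=len(durations),
        n_events=int(sum(events)),
    )


def sample_size_two_proportions(spec: SampleSizeSpec) -> int:
    """Per-group n for a two-sided normal-approximation test of two
    proportions: variance pooled under the null, unpooled under the
    alternative, rounded up."""
    p1, p2 = spec.p_control, spec.p_treated
    pbar = 0.5 * (p1 + p2)
    z_a = sps.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = sps.norm.ppf(spec.power)
    num = z_a * math.sqrt(2.0 * pbar * (1.0 - pbar)) + z_b * math.sqrt(
        p1 * (1.0 - p1) + p2 * (1.0 - p2)
    )
    return math.ceil((num / (p1 - p2)) ** 2 - 1e-9)


def sensitivity_window_rerun(
    treated: Sequence[EyeHistory],
    nh: Sequence[EyeHistory],
    phase,
    timepoint: float,
    windows: Iterable[float] = (3.0, 3.5, 4.0),
    outcome: str = "crb",
    onset_L: Optional[float] = None,
) -> pd.DataFrame:
    """Rerun matching + responder classification + the logistic
    comparison with widened follow-up windows, side by side."""
    from .matching import MatchingConfig, build_matched_dataset, compute_onset_L
    from .responder import responder_rates

    if onset_L is None:
        onset_L = compute_onset_L(treated)
    rows = []
    for window in windows:
        config = MatchingConfig(onset_L=onset_L, window_halfwidth=window)
        matched, _ = build_matched_dataset(treated, nh, phase, timepoint, config)
        classified = classify_dataset(matched)
        rates = responder_rates(classified)
        result = logistic_compare(classified, outcome)
        for row in rates[rates["outcome"] == outcome].itertuples():
            rows.append(
                {
                    "window": window,
                    "group": row.group,
                    "outcome": outcome,
                    "responders": row.responders,
                    "eligible": row.eligible,
                    "rate_percent": row.rate_percent,
                    "odds_ratio": result.odds_ratio,
                    "ci_low": result.ci95[0],
                    "ci_high": result.ci95[1],
                    "p_value": result.p_value,
                }
            )
    return pd.DataFrame(rows)
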