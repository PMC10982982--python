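"""Comparative statistics: crude/adjusted odds ratios, ANCOVA,
Kaplan-Meier product-limit, and the two-proportion sample size."""

import math
import random

import numpy as np
import pandas as pd
import pytest

from conftest import make_eye
from lhonva.cohort import Cohort
from lhonva.eligibility import Phase
from lhonva.stats import (
    SampleSizeSpec,
    ancova_va_change,
    crude_odds_ratio,
    km_first_crr,
    logistic_compare,
    sample_size_two_proportions,
    sensitivity_window_rerun,
)


class TestCrudeOddsRatio:
    def test_cross_product_by_hand(self):
        # 60*153 / (82*40) = 9180/3280
        r = crude_odds_ratio(60, 82, 40, 153)
        assert r.odds_ratio == pytest.approx(9180 / 3280, rel=1e-12)
        assert r.odds_ratio == pytest.approx(2.799, abs=5e-4)

    def test_symmetric_table(self):
        assert crude_odds_ratio(10, 10, 10, 10).odds_ratio == pytest.approx(1.0)

    def test_continuity_correction_on_zero_cell(self):
        r = crude_odds_ratio(5, 0, 3, 7)
        expected = (5.5 * 7.5) / (0.5 * 3.5)
        assert math.isfinite(r.odds_ratio)
        assert r.odds_ratio == pytest.approx(expected, rel=1e-12)
        assert any("continuity" in w for w in r.warnings)

    def test_wald_ci_closed_form(self):
        a, b, c, d = 60, 82, 40, 153
        r = crude_odds_ratio(a, b, c, d)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = math.exp(math.log(a * d / (b * c)) - 1.959963984540054 * se)
        hi = math.exp(math.log(a * d / (b * c)) + 1.959963984540054 * se)
        assert r.ci95 == (pytest.approx(lo, rel=1e-9), pytest.approx(hi, rel=1e-9))
        assert r.ci95[0] <= r.odds_ratio <= r.ci95[1]

    def test_empty_margin_not_estimable(self):
        assert not crude_odds_ratio(0, 0, 3, 7).estimable


def outcome_frame(a, b, c, d, rng=None):
    """Binary-outcome analysis table from 2x2 counts (no covariates)."""
    rows = (
        [("treated", 1)] * a
        + [("treated", 0)] * b
        + [("natural_history", 1)] * c
        + [("natural_history", 0)] * d
    )
    df = pd.DataFrame(rows, columns=["group", "crb"])
    df["gender"] = "male"
    df["mutation"] = "m11778GA"
    return df


class TestLogisticCompare:
    def test_no_covariate_fit_equals_crude_or(self):
        df = outcome_frame(60, 82, 40, 153)
        r = logistic_compare(df, "crb", covariates=("treatment",))
        crude = crude_odds_ratio(60, 82, 40, 153)
        assert r.odds_ratio == pytest.approx(crude.odds_ratio, rel=1e-4)

    def test_constant_covariates_collapse_to_crude(self):
        df = outcome_frame(25, 30, 12, 41)
        r = logistic_compare(df, "crb")  # gender/mutation constant, dropped
        assert r.odds_ratio == pytest.approx(
            crude_odds_ratio(25, 30, 12, 41).odds_ratio, rel=1e-4
        )

    def test_constant_outcome_not_estimable(self):
        df = outcome_frame(10, 0, 12, 0)
        assert not logistic_compare(df, "crb", covariates=("treatment",)).estimable

    def test_agrees_with_statsmodels_glm(self):
        # independent route: same model through statsmodels IRLS
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 400
        df = pd.DataFrame(
            {
                "group": rng.choice(["treated", "natural_history"], n),
                "gender": rng.choice(["male", "female"], n),
                "mutation": rng.choice(["m11778GA", "m3460GA", "m14484TC"], n),
            }
        )
        eta = (
            -0.5
            + 0.8 * (df.group == "treated")
            + 0.3 * (df.gender == "male")
            - 0.4 * (df.mutation == "m3460GA")
        )
        df["crb"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        mine = logistic_compare(df, "crb")
        X = pd.get_dummies(
            df[["gender", "mutation"]], drop_first=True, dtype=float
        )
        X.insert(0, "treatment", (df.group == "treated").astype(float))
        X = sm.add_constant(X)
        fit = sm.GLM(df["crb"], X, family=sm.families.Binomial()).fit()
        assert math.log(mine.odds_ratio) == pytest.approx(
            fit.params["treatment"], abs=1e-6
        )
        se = math.log(mine.ci95[1] / mine.odds_ratio) / 1.959963984540054
        assert se == pytest.approx(fit.bse["treatment"], rel=1e-4)

    def test_separation_falls_back_to_penalised_fit(self):
        df = outcome_frame(20, 0, 0, 20)  # outcome == treatment exactly
        r = logistic_compare(df, "crb", covariates=("treatment",))
        assert any("separation" in w for w in r.warnings)
        assert math.isfinite(r.odds_ratio)


def change_frame(n_per_group, effect, slope, noise_sd, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for group, shift in (("treated", effect), ("natural_history", 0.0)):
        baseline = rng.uniform(0.5, 1.5, n_per_group)
        change = shift + slope * baseline + rng.normal(0, noise_sd, n_per_group)
        for b, ch in zip(baseline, change):
            rows.append(
                {
                    "group": group,
                    "gender": rng.choice(["male", "female"]),
                    "mutation": "m11778GA",
                    "baseline_logmar": b,
                    "endpoint_logmar": b + ch,
                }
            )
    return pd.DataFrame(rows)


class TestAncova:
    def test_zero_slope_balanced_equals_raw_difference(self):
        df = change_frame(200, -0.1, 0.0, 0.0, seed=1)
        res = ancova_va_change(df)
        raw = (
            df[df.group == "treated"].endpoint_logmar
            - df[df.group == "treated"].baseline_logmar
        ).mean() - (
            df[df.group == "natural_history"].endpoint_logmar
            - df[df.group == "natural_history"].baseline_logmar
        ).mean()
        assert res.lsmean_difference == pytest.approx(raw, abs=1e-6)

    def test_identical_groups_zero_difference(self):
        df = change_frame(100, 0.0, 0.3, 0.0, seed=2)
        res = ancova_va_change(df)
        assert res.lsmean_difference == pytest.approx(0.0, abs=1e-9)

    def test_recovers_injected_effect(self):
        df = change_frame(500, -0.15, 0.2, 0.1, seed=3)
        res = ancova_va_change(df)
        assert res.lsmean_difference == pytest.approx(-0.15, abs=0.02)
        assert res.ci95[0] <= res.lsmean_difference <= res.ci95[1]

    def test_rank_deficient_design_names_alias(self):
        df = change_frame(50, 0.0, 0.0, 0.05, seed=4)
        df["gender"] = np.where(df.group == "treated", "male", "female")
        with pytest.raises(ValueError, match="gender"):
            ancova_va_change(df)


def km_eyes(event_months, censor_months):
    """Treated-style eyes with known first-recovery / censoring times."""
    eyes = []
    for i, m in enumerate(event_months):
        # baseline 1.2, recovery visible (0.9) at the event visit
        months = [1.0] + [1.0 + t for t in (m / 2, m)] + [1.0 + m + 6]
        values = [1.2, 1.15, 0.9, 0.85]
        eyes.append(make_eye(months, values, patient_id=f"E{i}", cohort=Cohort.TREATED))
    for i, m in enumerate(censor_months):
        months = [1.0, 1.0 + m / 2, 1.0 + m]
        values = [1.2, 1.15, 1.1]
        eyes.append(make_eye(months, values, patient_id=f"C{i}", cohort=Cohort.TREATED))
    return eyes


def brute_product_limit(durations, events, t):
    surv = 1.0
    for ti in sorted({d for d, e in zip(durations, events) if e}):
        if ti > t + 1e-9:
            break
        at_risk = sum(1 for d in durations if d >= ti - 1e-9)
        d_i = sum(1 for d, e in zip(durations, events) if e and abs(d - ti) < 1e-9)
        surv *= 1.0 - d_i / at_risk
    return 1.0 - surv


class TestKaplanMeier:
    def test_single_event_in_ten(self):
        est = km_first_crr(km_eyes([6.0], [24.0] * 9), report_months=(7.0,))
        assert est.incidence(7.0) == pytest.approx(0.1, abs=1e-9)

    def test_no_events_zero_everywhere(self):
        est = km_first_crr(km_eyes([], [20.0] * 5))
        assert all(v == 0.0 for v in est.incidence_at.values())

    def test_hand_product_limit_four_eyes(self):
        # events at 3 and 9, censored at 6, survivor to 24:
        # 1 - (3/4)(1/2) = 0.625 just after the second event
        est = km_first_crr(km_eyes([3.0, 9.0], [6.0, 23.0]), report_months=(10.0,))
        assert est.incidence(10.0) == pytest.approx(0.625, abs=0.01)

    def test_matches_brute_force_on_random_instances(self):
        rng = random.Random(5)
        for trial in range(15):
            n_ev = rng.randint(0, 8)
            n_cs = rng.randint(1, 12)
            ev = [round(rng.uniform(2, 22), 1) for _ in range(n_ev)]
            cs = [round(rng.uniform(2, 23), 1) for _ in range(n_cs)]
            eyes = km_eyes(ev, cs)
            est = km_first_crr(eyes)
            durations, events = [], []
            for eye in eyes:
                b_date, b = eye.baseline
                t_ev, t_last = None, 0.0
                for d, m in eye.visits[1:]:
                    t = (d - b_date).days / 30.4375
                    if t > 24.0 + 1e-9:
                        break
                    t_last = t
                    if b.logmar - m.logmar >= 0.2 - 1e-9:
                        t_ev = t
                        break
                durations.append(t_ev if t_ev is not None else t_last)
                events.append(t_ev is not None)
            for month, inc in est.incidence_at.items():
                assert inc == pytest.approx(
                    brute_product_limit(durations, events, month), abs=1e-9
                )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_first_crr([])


class TestSampleSize:
    def test_trial_recalculation(self):
        assert sample_size_two_proportions(SampleSizeSpec(0.22, 0.40)) == 137

    def test_initial_trial_calculation(self):
        assert sample_size_two_proportions(SampleSizeSpec(0.24, 0.40)) == 177

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(0.3, 0.3)

    def test_nonincreasing_in_effect_size(self):
        sizes = [
            sample_size_two_proportions(SampleSizeSpec(0.40 - d, 0.40))
            for d in (0.10, 0.16, 0.18, 0.25)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_nondecreasing_in_power(self):
        sizes = [
            sample_size_two_proportions(SampleSizeSpec(0.22, 0.40, power=p))
            for p in (0.70, 0.80, 0.90, 0.95)
        ]
        assert sizes == sorted(sizes)


class TestSensitivityWindows:
    def _cohorts(self):
        treated = [
            make_eye([5.0, 16.6], [1.3, 1.0], cohort=Cohort.TREATED, patient_id="T1"),
            make_eye([6.0, 18.0], [1.2, 1.4], cohort=Cohort.TREATED, patient_id="T2"),
        ]
        nh = [
            make_eye([5.0, 17.0], [1.2, 1.4], patient_id="N1"),
            # only qualifying follow-up sits 15.7 months out: needs +-4
            make_eye([5.0, 20.7], [1.1, 1.3], patient_id="N2"),
        ]
        return treated, nh

    def test_wider_window_adds_eyes(self):
        treated, nh = self._cohorts()
        out = sensitivity_window_rerun(treated, nh, Phase.SUBACUTE_DYNAMIC, 12.0)
        n_nh = {
            w: int(out[(out.window == w) & (out.group == "natural_history")].eligible.iloc[0])
            for w in (3.0, 4.0)
        }
        assert n_nh[4.0] == n_nh[3.0] + 1

    def test_no_extra_visits_identical_across_windows(self):
        treated, nh = self._cohorts()
        out = sensitivity_window_rerun(treated, nh[:1], Phase.SUBACUTE_DYNAMIC, 12.0)
        rates = [
            out[(out.window == w) & (out.group == "natural_history")].rate_percent.iloc[0]
            for w in (3.0, 3.5, 4.0)
        ]
        assert rates[0] == rates[1] == rates[2]
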