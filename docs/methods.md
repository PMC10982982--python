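# Methods

This note documents the analysis pipeline's models and conventions,
the synthetic-cohort generator it is validated on, and the numerical
and design choices made where the published description left the
behaviour open.

## Acuity scale

All analysis happens on the logMAR scale, `logMAR = -log10(decimal
acuity)`; lower is better, 0.0 ≈ 20/20. Snellen fractions enter as a
ratio (so feet and metre charts are equivalent), decimal scores
directly, and the four off-chart categories (counting fingers, hand
motion, light perception, no light perception) are all imputed at
**1.8 logMAR** with the subcategory retained only for provenance —
changes within off-chart categories are never analysed. The worst
measurable on-chart value is **1.68 logMAR**; converted values in
(1.68, 1.8) are kept as given but flagged, and remain outside the
on-chart-only denominators. Negative logMAR (better than 20/20) passes
through unchanged.

Letter arithmetic uses the ETDRS chart's 5 letters per 0.1 logMAR
line. A logMAR change Δ maps to `floor(50·|Δ|)` letters: the published
pairs (−0.17 → 8, −0.53 → 26, −0.11 → 5) are consistent with
truncation but not with round-half-up, so truncation is the default
and `nearest` is available as an option.

## Time axis and phases

All durations are computed in months of 365.25/12 = 30.4375 days from
per-eye symptom-onset dates. Disease phase at a baseline visit:
subacute < 6 months, dynamic 6–12 months (the 12-month boundary is
inclusive), pooled as subacute/dynamic ≤ 1 year; chronic > 1 to ≤ 5
years. Beyond 5 years an eye is ineligible.

Eligibility rules are applied in a declared order and each eye is
excluded under exactly its first failing rule, so the exclusion ledger
satisfies `eyes_in = retained + Σ excluded`. Treated arm: known onset;
age ≥ 12 at baseline; onset ≤ 5 years before baseline;
treatment-naïve. NH arm: age ≥ 12 at the first post-onset visit (this
check needs elapsed time from onset, so eyes with unknown onset fall
to the unknown-onset rule); known onset; onset ≤ 5 years before the
first visit; ≥ 2 post-onset VA assessments; no prior idebenone.
Efficacy sets are additionally restricted to the three common primary
mtDNA mutations (m.11778G>A, m.3460G>A, m.14484T>C). Eyes are the
analysis unit and are treated as independent; no correction for the
interdependence of fellow eyes is attempted.

## Matching

The treated cohort enters at its actual baseline (first visit), with
the endpoint taken from the scheduled visit closest to the analysis
timepoint within ± window (default 3 months). NH baselines are chosen
by phase:

* **Subacute/dynamic.** `onset_L` = mean months from second-eye onset
  (the later of a patient's two onset dates) to the baseline visit,
  over treated patients, computed once on the full treated cohort. For
  each NH eye, all ordered visit pairs separated by timepoint ± window
  are enumerated; among pairs whose baseline lies within 1 year of
  onset, the pair whose baseline time-since-onset is closest to
  `onset_L` is selected.
* **Chronic.** Pairs are binned by baseline time-since-onset into
  half-open bins (12, 24], (24, 36], (36, 48], (48, 60] months; within
  a bin the baseline closest to the bin midpoint (18/30/42/54 months)
  wins, and one eye may contribute a pair to every bin. The bins place
  baselines only; follow-ups use the same ± window around the
  timepoint.

Conventions the source description does not fix, chosen for
determinism: equidistant candidates resolve to the earlier baseline
date; several pairs sharing one baseline first reduce to the follow-up
closest to baseline + timepoint; selection depends only on dates, so
it is invariant to input row order. Widening the window (3 → 3.5 → 4
months, the sensitivity rerun) can only add candidate pairs, never
remove them.

## Responder classification

From baseline measure b to endpoint measure e:

* CRR: if b is off-chart, e on-chart with e ≤ 1.6; else b − e ≥ 0.2.
* CRS: eligible iff b < 1.0 (all off-chart baselines ineligible);
  true iff e < 1.0.
* CRW: eligible iff b on-chart (≤ 1.68); true iff e off-chart or
  e − b ≥ 0.2.
* CRB: CRR and/or CRS; its denominator is all eyes (an eye ineligible
  for CRS can still reach CRB through CRR).

Threshold comparisons carry a 1e−9 tolerance to absorb decimal
representation error from converted Snellen fractions. "Maintenance"
in CRS is read literally, without a no-worsening side condition, so an
eye can be CRS and CRW simultaneously (e.g. 0.5 → 0.9); the dataset
audit counts such eyes. Rates are reported as percentages to one
decimal over each outcome's eligible denominator; a zero denominator
is not estimable.

## Statistics

* **Logistic comparison** (each responder outcome): maximum-likelihood
  fit of outcome ~ treatment + gender + mutation (factors dummy-coded,
  first level as reference; optional under/over-18 age group with
  treatment interaction, optional time-since-onset covariate).
  Newton–Raphson iterated to relative log-likelihood change < 1e−8,
  max 100 iterations. The treatment effect is reported as an odds
  ratio with Wald 95% CI and two-sided Wald p. Complete or
  quasi-complete separation (non-convergence, infinite or huge
  standard error) triggers a ridge-penalised refit (λ = 1e−3), flagged
  in the result. All p values are exploratory; no multiplicity
  adjustment.
* **Crude odds ratio** (oracle for the logistic route): cross-product
  (a·d)/(b·c) with a 0.5 continuity correction added to every cell iff
  any cell is zero, Wald CI on the log scale.
* **ANCOVA** of endpoint-minus-baseline logMAR on treatment + gender +
  mutation + baseline logMAR (statsmodels OLS). The treatment
  coefficient is the adjusted (LS-mean) treated-minus-NH difference;
  negative favours treatment. Rank-deficient designs raise an error
  naming the first aliased term.
* **Kaplan–Meier first CRR**: per treated eye, the event is the first
  post-baseline visit whose CRR criterion from baseline is met;
  otherwise censoring at the last visit, capped at 24 months. Event
  times are visit times (interval censoring between visits is
  ignored, matching visit-driven trial reporting). Cumulative
  incidence 1 − Ŝ(t) is reported at months 6, 12, 18, 24 (lifelines).
* **Sample size** for two proportions, two-sided α and power 1 − β:
  `n = ceil((z_{1−α/2}·sqrt(2·p̄·(1−p̄)) + z_{1−β}·sqrt(p₁q₁ + p₂q₂))²
  / (p₁ − p₂)²)` with p̄ the simple average — pooled variance under the
  null, unpooled under the alternative. This form reproduces both
  published design numbers (137 at 22% vs 40%; 177 at 24% vs 40%);
  pooled-only and unpooled-only variants do not (139 and 134 for the
  22% case).

## Synthetic cohorts

The generator defines the study conditions under which the pipeline is
validated; it emulates structure, not any real patient's data.

Each eye's latent logMAR course is piecewise linear: decline from ~0
with a steep initial phase (85% of the nadir depth lost by 1.5 months
— LHON vision loss is rapid over weeks) creeping to the full depth at
the nadir time (6 ± 2 months); a plateau; and, for recoverers, linear
improvement toward a drawn recovered level starting 6–18 months after
onset and completing over 6 months. Values are clipped to [−0.3, 1.8].
Modelling recovery as a return toward a *level* (0.5 ± 0.25 logMAR,
clipped to [0, 1] and kept at least 0.25 below the nadir) rather than
a fixed improvement amount reflects how spontaneous LHON recovery is
described clinically and makes recovery visible from any
post-vision-loss baseline — with a slow linear decline, eyes enrolled
early would have baselines better than their recovered level and a
real recovery would produce no measurable improvement, structurally
attenuating any treatment effect expressed through recovery odds.

Key defaults (all in `SimConfig`, fixed once): nadir depth 1.45 ± 0.35
logMAR clipped to [0.3, 1.8] (≈ 30% of eyes off-chart at nadir);
untreated spontaneous-recovery probabilities by mutation 0.15
(m.11778G>A), 0.20 (m.3460G>A), 0.50 (m.14484T>C) — ballpark prognosis
ordering, not literature estimates; treatment adds +0.8 to the
recovery log-odds (an optional logMAR drift is off by default);
measurement noise 0.05 logMAR per visit (ETDRS test–retest 95% limits
are about ± 0.1 logMAR); mutation mix 0.60/0.20/0.20; 75% male; age at
onset 32.5 ± 14 years truncated at ≥ 8.

Treated patients receive one baseline visit per patient, drawn at
6 ± 3 months since first-eye onset (matching the reported distribution
of time since onset at baseline) but no earlier than the rapid-drop
period after the later eye's onset — patients present after
established vision loss — then scheduled follow-ups at months 1, 3, 6,
12, 18, 24 with 0.3-month jitter and 10% missingness; all treated
records are chart logMAR (or off-chart). NH eyes get 2 + Poisson(4)
visits uniform over 0.5–59 months since onset; 5% of NH patients have
their onset date blanked and 5% of NH eyes are truncated to a single
visit, to exercise the eligibility ledger. On-chart NH values are
emitted in a notation drawn from snellen 0.653 / decimal 0.185 /
logmar 0.162 — the reported record mix (51.3/14.5/12.7 plus ~21.5%
off-chart) renormalised to on-chart records, because off-chart status
is an outcome of the latent severity (any measured value above 1.68
becomes an off-chart record, with the subcategory assigned by severity
band), not a chart choice. Snellen emission snaps to the nearest
standard chart line; decimal and logMAR values are reported to two
decimals. A fixed seed reproduces every record byte-for-byte.

What the generator does **not** model: correlation between fellow
eyes beyond the shared covariates, secular trends across survey
periods, inter-chart measurement bias (Snellen vs ETDRS), informative
missingness, and measurement-error structure specific to off-chart
assessment. Passing the validation suite therefore demonstrates that
the pipeline recovers known truth under these idealised conditions; it
does not quantify robustness to those real-data features.

## Validation design

Beyond unit and property tests (brute-force enumeration oracles for
matching, a hand product-limit oracle for KM, a transcription oracle
for the responder truth table, statsmodels as an independent route for
the logistic fit), two stochastic calibration studies run against the
full pipeline:

* **CI coverage**: 200 replicates at 500 patients (1,000 eyes) per
  cohort with +0.8 injected recovery log-odds; the 95% Wald CI of the
  24-month CRR odds ratio should cover 0.8 about 95% of the time. The
  24-month timepoint is used because recovery (drawn to start 6–18
  months after onset) has fully manifested by then; at 12 months part
  of the recoveries have not yet occurred and the 12-month odds ratio
  estimates a smaller, attenuated quantity.
* **Test size**: 2,000 null replicates (no treatment effect, realistic
  covariate mix) at 150 eyes per group; the two-sided Wald test of the
  treatment term should reject at 5% ± 1 point. The null study feeds
  simulated responder outcomes directly to the logistic comparison —
  the property under test is the size of the test itself.

Problem sizes for these studies (200 and 2,000 replicates, 500 and 150
per group) were chosen to give Monte-Carlo standard errors well inside
the asserted tolerances.

## Known limitations

* The NH age-eligibility rule cannot be evaluated for eyes with
  unknown onset (no time axis); such eyes are excluded as
  unknown-onset, which matches the rule ordering but may differ from
  how a registry with partial birth dates would count them.
* Onset dates are carried at day precision; month-known/day-unknown
  dates should be imputed to the 15th upstream.
* The chronic matching branch reuses the subacute ± window for
  follow-ups; the source description fixes only the bins.
* `onset_L` is computed once from the whole treated cohort, not per
  analysis timepoint; an override is available in `MatchingConfig`.
* No propensity or covariate matching: baselines are matched on time
  since onset only, so covariate imbalance between cohorts is handled
  entirely by the regression adjustment.
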