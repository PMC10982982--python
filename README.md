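# lhonva

Externally controlled visual-acuity (VA) analysis for Leber hereditary
optic neuropathy (LHON), built for biostatisticians and trialists who
need to compare a treated cohort against an untreated natural-history
(NH) control assembled from retrospective case records.

LHON causes rapid, usually sequential bilateral central vision loss.
Because the disease is rare and an approved therapy exists, a
placebo-controlled trial is not feasible; efficacy is instead assessed
against an external NH cohort. That design raises three methodological
problems this package solves as a reusable pipeline:

1. **Scale conversion.** NH records mix Snellen fractions, decimal
   scores, logMAR values and off-chart categories (counting fingers,
   hand motion, light/no light perception). Everything is normalised to
   logMAR via `-log10(decimal acuity)`; off-chart readings are imputed
   at **1.8 logMAR**; 1.68 logMAR is the worst measurable on-chart
   value. ETDRS-letter arithmetic uses 50 letters per logMAR unit with
   a truncation convention.
2. **Baseline matching.** Any untreated NH visit could serve as a
   baseline, so baselines are chosen to match the treated cohort on
   time since symptom onset — the dominant prognostic factor. For
   subacute/dynamic eyes (≤ 1 year since onset) the algorithm
   enumerates visit pairs whose separation is within ±3 months of the
   analysis timepoint and picks the pair whose baseline is closest to
   *onset_L*, the treated cohort's mean time from second-eye onset to
   baseline. For chronic eyes (> 1–5 years), pairs are binned by
   baseline time since onset (>1–2, >2–3, >3–4, >4–5 years) and the
   baseline closest to the bin midpoint wins; an eye may contribute one
   pair per bin.
3. **Responder endpoints.** Each (baseline, endpoint) pair is
   classified as clinically relevant recovery (CRR: off-chart → ≤ 1.6
   logMAR, or on-chart improvement ≥ 0.2 logMAR = 10 ETDRS letters),
   stabilization (CRS: maintenance < 1.0 logMAR; denominator restricted
   to baselines < 1.0), worsening (CRW: on- to off-chart, or loss ≥ 0.2
   logMAR; denominator restricted to on-chart baselines ≤ 1.68), and the
   composite benefit (CRB = CRR and/or CRS).

Comparative statistics follow the trial's analysis plan: logistic
regression of each responder outcome on treatment, gender and mtDNA
mutation (treatment effect as odds ratio with Wald 95% CI); ANCOVA of
logMAR change on the same factors plus baseline VA; Kaplan–Meier
cumulative incidence of first CRR; and the two-proportion
normal-approximation sample size

n = ⌈(z₁₋α/₂·√(2·p̄·q̄) + z₁₋β·√(p₁q₁ + p₂q₂))² / (p₁ − p₂)²⌉,

with the variance pooled under the null and unpooled under the
alternative.

A bundled simulator (`lhonva.simulate`) generates synthetic treated and
NH cohorts with the longitudinal and notational structure the analysis
assumes (subacute decline to a nadir, mutation-dependent spontaneous
recovery, mixed NH notations, irregular survey visits), so every stage
is testable without confidential patient data. See `docs/methods.md`
for the model and all parameter choices.

## Worked example

Simulate 60 patients per cohort and run the full pipeline:

```bash
lhonva run --simulate --n-patients 60 --seed 11 --out demo_bundle
```

prints (abridged):

```
onset_L = 4.54 months

-- 12-month responder rates --
outcome  group             rate      n/N
CRB      natural_history    33.3%  10/30
CRR      natural_history    23.3%  7/30
CRS      natural_history    80.0%  4/5
CRW      natural_history    22.2%  6/27
CRB      treated            35.6%  36/101
CRR      treated            30.7%  31/101
CRS      treated            60.0%  6/10
CRW      treated            23.5%  20/85
```

`onset_L` is the matching target computed from the simulated treated
cohort. Each rate line gives responders over the outcome's eligible
denominator — note the CRS/CRW denominators are restricted subsets, and
the matched NH group is smaller than the treated group because only NH
eyes with a qualifying visit pair enter the comparison. The output
bundle contains the matched per-eye datasets, rate tables, adjusted
odds-ratio comparisons (`comparisons.csv`), the ANCOVA of VA change,
Kaplan–Meier tables, per-rule exclusion ledgers, and a
`run_metadata.json` echoing the configuration; reruns with the same
seed are byte-identical.

The same stages are available individually (`lhonva simulate`,
`convert`, `filter`, `match`, `classify`, `compare`) and as library
functions.

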