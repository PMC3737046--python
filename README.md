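# claimscope

Administrative drug-claims analysis of antipsychotic prescribing in young
people, packaged as a reusable, tested pipeline.

Publicly funded drug programs record every dispensed prescription, but the
individual-level tables (beneficiary registry, pharmacy claims, physician
billings, hospital discharge abstracts, death records) are confidential.
`claimscope` implements the full analysis such a linkage supports —
incident and prevalent antipsychotic users, a most-attributable-diagnosis
hierarchy, co-prescribing and comorbidity windows, dose equivalence,
trend, association and survival statistics — together with a seeded
synthetic generator of the five linked tables, so that every stage can be
developed, tested and demonstrated without access to real data.  It is
aimed at pharmacoepidemiologists and health-services researchers working
with claims extracts of this shape.

## What it computes

**Cohorts.** An *incident* user's first antipsychotic fill is the earliest
in the observation window, after a 6-month washout free of antipsychotic
claims.  A *prevalent* user in a quarter is anyone dispensed an
antipsychotic in it (dispensing-based, not supply-based).  A *long-term*
user has ≥ 2 fills within 180 days whose summed days supply is ≥ 90.
Rates are users per 1000 beneficiaries eligible in the quarter, by fiscal
quarter (year starting April 1, so October–December of year Y is YQ3).

**Diagnosis attribution.** Claims carry no indication, so the diagnosis
most plausibly behind an antipsychotic start is resolved from diagnoses
dated within ±90 days of the incident fill, stepwise: hospital-discharge
(ICD-10) diagnoses outrank physician-billing (ICD-9) ones; within
billings, psychiatrists outrank other providers; among what survives, the
lowest level of a ten-level hierarchy wins (1 = psychotic disorders,
2 = bipolar, … 6 = ADHD, … 10 = other).

**Trend model.** A quarterly rate series Y(t) is modelled as a linear
trend with stationary AR(1) errors,

    Y(t) = A + B·t + a(t),      a(t) = k·a(t−1) + e(t),   e(t) ~ N(0, σ²),

fitted by whitening + profile restricted likelihood over k ∈ (−1, 1); the
no-trend hypothesis B = 0 is tested by a Wald t statistic on n − 3 df.

**Association, dosing, costs, survival.** 2×2 odds ratios with Woolf
(log-normal) intervals and Pearson chi-square; prescribed daily dose
(strength × quantity / days supply) with annual claim-level summaries and
fixed olanzapine-equivalence ratios (haloperidol 2, loxapine 0.33,
quetiapine 0.027, risperidone 3.33); annual program cost net of copay;
Kaplan–Meier curves and age/sex-adjusted Cox hazard ratios comparing
users, other beneficiaries and a general-population comparator.

## Worked example

Reconstructing the male/female × user/non-user table from whole-period
margins (43 888 beneficiaries, 44.5% male, 1134 male and 581 female
antipsychotic users) and testing the association:

```sh
$ claimscope assoc --table 1134,18396,581,23777
{"odds_ratio": 2.523, "ci": [2.278, 2.793], "chi_square": 337.9, "df": 1, "p": 1.86e-75}
```

The odds of being dispensed an antipsychotic are about 2.5 times higher
for males, with a Woolf 95% interval of roughly (2.3, 2.8) and an
overwhelming chi-square on 1 df.

Fitting the trend model to a simulated 28-quarter series generated with
A = 3, B = 0.12, k = 0.4:

```python
>>> from claimscope.trend import fit_ar1_trend
>>> print(fit_ar1_trend(y).summary())
Linear trend with AR(1) errors
==============================================
n quarters                28
method                  reml
log-likelihood        -6.916
----------------------------------------------
A  (intercept)        2.6312  se 0.3707
B  (slope/quarter)    0.1390  se 0.0211
   95% CI for B   [0.0956, 0.1824]
k  (autocorr)         0.7714
p (H0: B = 0)      6.513e-07  (t, df=25)
==============================================
```

The slope estimate 0.139 ± 0.021 covers the generating value 0.12; the
tiny p-value rejects "no change over time" for this series.

An end-to-end run — simulate the reference population, build cohorts,
attribute diagnoses, scan exposure windows, summarize doses and costs,
fit trends, and compare survival — is one command:

```sh
claimscope run --out report/ --seed 42
```

The bundle contains CSV analogues of the study's tables and figures
(users by age/sex, quarterly rates, attribution shares, dose summaries,
co-prescribing by age, comorbidity counts, costs by year, trend fits,
survival curves and hazard ratios) plus a run log carrying the seed and a
configuration hash; repeated runs with the same seed are byte-identical.

## Layout

- `claimscope.io` – the five linked tables, validation, CSV round-trip
- `claimscope.catalogs` – ATC antipsychotic catalog, ICD hierarchy,
  psychotropic classes, comorbidity targets, equivalence ratios
- `claimscope.simulate` – seeded synthetic-linkage generator
- `claimscope.cohort` – incident/prevalent/long-term users, rates,
  duration, prescriber shares
- `claimscope.attribution` – the stepwise most-attributable diagnosis
- `claimscope.windows` – co-prescribing and comorbidity windows
- `claimscope.dosing` – daily doses, equivalents, annual costs
- `claimscope.trend` – AR(1)-error trend model, odds ratio, chi-square
- `claimscope.survival` – Kaplan–Meier and Cox comparisons (lifelines)
- `claimscope.pipeline` / `claimscope.cli` – orchestration and the
  `claimscope` command

See `docs/methods.md` for the modelling assumptions, calibration of the
synthetic generator, and numerical choices.
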