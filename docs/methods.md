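# Methods

This note documents the models, conventions and design choices behind
`claimscope`, in the order the pipeline runs them.

## Data model

Five linked tables emulate a provincial drug-benefit linkage: a
beneficiary registry (id, sex, birth date, region), eligibility spells
(benefits can be interrupted and resumed; spells never overlap), pharmacy
claims (date, 7-level ATC, DIN, strength, quantity, days supply ≤ 100 —
the program cap per fill — amounts and prescriber specialty), diagnoses
(ICD-9 from fee-for-service physician billings, ICD-10 from hospital
discharge abstracts) and death records (at most one per beneficiary).
Referential integrity is enforced at load: every satellite record must
reference a registry id.

ICD codes are matched as dotted strings with the dot stripped internally,
so `296.2` and `2962` are interchangeable; classification is
longest-prefix against the ten-level hierarchy, per ICD version.  Two
ICD-10 codes appear under two hierarchy levels in the source coding
table (F06 under 1 and 10, F07 under 8 and 10); the loader resolves such
duplicates to the lower level number — the higher attribution priority —
and logs a warning.

## Synthetic linkage generator

The generator emulates the study conditions the analysis assumes, so all
downstream stages are testable without confidential data.  Its reference
configuration fixes:

- 43 888 beneficiaries aged 0–25 with the published age-band sizes
  (14 800 / 7 474 / 6 693 / 6 834 / 8 087) and per-band male fractions
  (51.6 / 51.8 / 47.6 / 35.4 / 29.9%);
- per age-and-sex whole-period antipsychotic-user probabilities
  (males 0.5–19.3%, females 0.1–5.4% across the bands), which jointly
  imply ~3.9% users overall and a male:female odds ratio of ~2.5 — the
  `male_female_or_target` field documents and validates that implication
  but is not sampled from;
- observation window 2000-10-01 to 2007-09-30 (28 fiscal quarters), a
  risperidone formulary step on 2003-12-01, and 66% of diagnosed users
  carrying ≥ 2 diagnoses.

Quarterly dispensing per drug follows a linear trend with AR(1) noise on
the log scale: the quarter-t claim count is Poisson with mean
`n · rate_t/1000 · exp(a_t − Var(a)/2)`, where `rate_t = baseline +
slope·t` (times the formulary multiplier, pro-rated within the quarter
containing the step date) and `a_t` is stationary AR(1).  The variance
offset keeps the expected count on the configured trend line, so
averaged-over-seeds counts recover the configured slope and the
detrended log series recovers the configured autocorrelation.  Sampled
users are drawn without replacement per quarter from the drug's user
pool restricted to beneficiaries eligible (and alive) in that quarter;
claim dates are uniform over the user's eligible days, so no claim ever
falls in an eligibility gap.  Flagged users never reached by quarterly
sampling receive one rescue claim placed proportionally to the trend
profile (~1% of users at reference intensity), keeping the registry user
flag and the claims-derived user set equal.

Per-quarter trend parameters are not published numerically (the source
figures are graphical), so the per-drug baselines and slopes are chosen
once as plausible values consistent with the printed whole-period
totals: risperidone dominant and rising (baseline 1.2/1000, +0.16 per
quarter, 1.35× step), quetiapine rising, olanzapine nearly flat, the
first-generation agents slowly declining.  Dose profiles per drug
(tablet strength, typical daily dose, lognormal spread, price per day)
are typical clinical values; days supply is drawn from {30, 60, 90, 100}.

Diagnoses are anchored on the user's first fill: dates are uniform
within ±90 days (10% deliberately outside, exercising the
no-information path; 17% of users carry no mappable diagnosis at all),
sources follow the 36/16/48% hospital/psychiatrist/other mixture, and
codes are drawn from the hierarchy's prefixes by a configured level
mixture.  A 3% share of users also receives a washout-period fill and is
therefore excluded by the incident rule.  Deaths are Bernoulli at
configured per-person-year rates (defaults ~0.00135 users, ~0.00043
non-users); claims, diagnoses and eligibility are truncated at death.

What the generator does **not** emulate: dose titration and switching
dynamics, pharmacy-level behaviour, seasonal prescribing, realistic
cause-of-death coding, regional confounding, or correlation between
diagnosis level and drug choice.  Passing tests therefore demonstrate
that the pipeline recovers the structure it is told to expect, not that
real claims data satisfy that structure.

## Cohort conventions

- **Quarter scheme** — fiscal, year starting April 1 (October–December of
  year Y is YQ3); calendar quarters available by option.
- **Washout** — "6 months" is operationalized as 182 days before the
  study start; any antipsychotic fill there excludes the beneficiary
  from the *incident* cohort entirely.  The *user universe* for
  whole-period tabulations is everyone dispensed an antipsychotic inside
  the window; the incident cohort (a subset) anchors prescriber,
  attribution and exposure-window analyses, which need a well-defined
  first exposure.
- **Ages** — user tabulations use age at study start (back-computed birth
  dates); denominators use eligibility overlap per quarter.  Rates with a
  zero denominator are reported as undefined (NaN), never as zero.
- **Long-term rule** — a window of ≤ 180 days (first to last fill,
  inclusive) holding ≥ 2 fills with total days supply ≥ 90.  Because
  supplies are positive, only maximal windows anchored at each fill need
  checking; the earliest qualifying window is reported.  The
  implementation is property-tested against a subset-enumeration oracle.
- **Duration of use** — evaluable only for beneficiaries with ≥ 365 days
  of cohort membership; defined as last fill date + its days supply −
  first fill date, all antipsychotics pooled, no truncation of
  overlapping supplies and no subtraction of gaps (the simplest
  first-to-last-coverage reading; per-drug and per-user variants are
  option flags).

## Attribution

Candidates are level-resolvable diagnoses within [incident − 90,
incident + 90] days (both window arms configurable; a second mode
extends the after-arm to the user's last fill).  Resolution is
equivalent to the lexicographic minimum of (source rank, provider rank,
hierarchy level) with hospital < billing and psychiatrist < other
provider, and is property-tested against that oracle.  The reported
`deciding_rule` is the first step that actually discriminated.  Ties at
the winning level are immaterial to the output; the earliest service
date is kept as the representative record.

## Exposure windows

Co-prescribing flags a psychotropic class (antidepressants N06A; mood
stabilizers N03A + lithium N05AN01; anxiolytics N05B; ADHD-related N06BA
+ clonidine) when any class claim is dispensed within −90/+180 days of
the incident fill; antipsychotic claims never flag.  Comorbidity flags a
target condition when it appears within 730 days *after* the anchor and
not in the 365 days up to and including it (the anchor day counts as
washout, the conservative reading).  Window arithmetic is day-based
(2 years = 730 d, 12 months = 365 d).  Flags are monotone in the
after-window length by construction.

## Dosing and costs

Prescribed daily dose is strength × quantity / days supply.  Annual
summaries average over *claims* (their Ns are claim counts, matching how
dispensing programs tabulate dose by fill); a per-user mode averages
each beneficiary's fills first.  Olanzapine equivalence is a fixed
multiplicative ratio per drug.  Annual cost is Σ(amount paid − copay)
over the calendar year, rounded to cents; the per-user mean is left at
full precision (it is a mean, not a ledger amount).

## Trend statistics

The quarterly model is Y(t) = A + B·t + a(t) with stationary AR(1)
errors a(t) = k·a(t−1) + e(t), |k| < 1; k is written in the standard
autocorrelation convention.  For fixed k the series and design are
whitened with the exact stationary transform (Prais–Winsten first row),
A and B fall out by least squares, and k is found by bounded scalar
search on the profile criterion.  The default criterion is the
*restricted* likelihood: at 28 quarters, profile ML estimates of k are
biased toward zero (simulation at k = 0.4: mean ML k̂ ≈ 0.27 versus
REML ≈ 0.38), which understates the slope's standard error and inflated
the trend test to ~10% size in a 1000-replicate null simulation; with
REML the same simulation gave ~6.5% size and ~92% interval coverage.
Exact ML and conditional least squares remain available
(`method="mle"`/`"cls"`), and the ML path is cross-checked in the test
suite against an independent state-space implementation.  The trend test
is Wald t on n − 3 df; α = 0.05 two-sided throughout.  Undefined-rate
quarters are dropped (and counted), never imputed.  Series shorter than
8 finite quarters are refused.

Association uses OR = ad/bc with the Woolf interval
exp(log OR ± z√(1/a + 1/b + 1/c + 1/d)); zero cells raise unless the
Haldane–Anscombe +0.5 correction is requested.  The chi-square is
Pearson's without continuity correction.

## Survival

Subject-level records (entry at study start, censoring at window end or
death) are compared across antipsychotic users, other beneficiaries and
a general-population comparator with the product-limit estimator and a
Cox model adjusting for age (continuous, years at entry) and sex, Efron
ties, via lifelines.  Published comparators exist only as aggregates, so
a documented recipe expands group totals into synthetic pseudo-records
(exponential event times at the implied constant hazard, censored at end
of follow-up); in the pipeline the general-population arm is scaled to
10% of its nominal size to keep the record count tractable.
Non-convergence and separation raise rather than returning a silent fit.

## Problem sizes and tolerances

The default test run simulates 6 000-beneficiary linkages for shared
fixtures and one full 43 888-beneficiary run for the end-to-end
determinism and calibration check; property tests use 400–1000 random
cases.  Recovery simulations use 500 series of 28 quarters for the trend
model (coverage band 90–99%, type-I band 2.5–8.5%, acknowledging
small-sample Wald distortion plus Monte-Carlo error) and 200 replicates
of n = 5000 for the Cox model (coverage band 91–98.5%).  Simulation
marginal checks use exact binomial standard errors at 4σ.

## Known limitations

- The generator's trend shapes are calibrated to printed totals, not to
  per-quarter counts (none are published); quarterly-level comparisons
  with the source study are therefore qualitative.
- Attribution reports one level per user; secondary diagnoses are only
  counted, not ranked.
- The duration definition neither truncates overlapping supplies nor
  subtracts gaps; episode-based definitions (grace periods, stockpiling)
  are out of scope.
- The mortality comparison inherits the pseudo-record construction for
  the general population; its hazard ratios validate the machinery, not
  provincial mortality.
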