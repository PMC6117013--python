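# Methods

## Exposure ascertainment

Dates carry day resolution only; all windows are closed intervals on
calendar dates.  Conception is imputed as the last menstrual period plus
two weeks: `delivery − (7·gestation_weeks − 14)` days, with gestation in
completed weeks restricted to [20, 45].  The dispensing ascertainment
window runs from 100 days before conception (long enough to see a
12-week course at 80 % possession started pre-conception) to the
delivery date.  Supplies dispensed after delivery never enter a course.

Days covered by a supply are `quantity / doses_per_day` from the therapy
catalog; fractional values are carried exactly, and comparisons of
"date + fractional days" against conception are done as real-valued day
offsets.  The dispensed strength is deliberately ignored — only count
and daily dosing enter the conversion.

All SCP types are pooled into a single course per pregnancy: one index
(earliest) supply, one total, one MPR.  Same-date index ties break
deterministically on (date, ATC code, input row order).  Per-therapy
use (for the utilisation tables) re-applies the exposure rule to the
subset of supplies with that ATC code.  When a course mixes therapy
types, the timing lead and minimum course are taken from the index
supply's therapy; mixed courses are rare in practice (the motivating
cohort had a median of one supply), and the catalog is configurable if
a user prefers different constants.

Exposure is strict: coverage ending exactly on the conception date does
not count as during-pregnancy use.  The two-clause rule (any supply's
coverage past conception, or index plus total days past conception) is
implemented literally; a property test checks the implementation against
a direct transcription of the two clauses on randomised courses.

## Recorded smoking status

The perinatal smoking items come in two dialects — an any-time item in
the earlier collection era, half-of-pregnancy items afterwards (the
switch is 2010 for WA records, 2011 for NSW) — and a record is positive
if any populated item is positive.  The hospital source is the ICD-10-AM
code Z72.0 (tobacco use within the last 28 days) on the separation
related to the delivery, operationalised as the separation whose
admission–separation interval contains the delivery date, with an
earliest-admission tie-break and an optional ± day tolerance for
transfer records.  Z72.0 matching is exact after period/whitespace
normalisation ("Z720" ≡ "Z72.0"); sibling codes such as Z72.1 never
match, and codes on non-delivery admissions are ignored.

Missing items are pooled with negative responses for classification (a
non-response cannot establish smoking) but an `all_missing` flag is kept
per pregnancy so that audits can separate "reported not smoking" from
"nothing reported".  A pregnancy whose items are all missing and whose
delivery separation carries no Z72.0 still enters the cascade if
exposed, carrying that flag.

## The cascade

The three criteria use closed thresholds throughout ("at least", "equal
or longer", "equal to or greater"): an index supply exactly at the lead
time, a course exactly at the minimum, or an MPR of exactly 80.0 all
pass.  The criteria form a conjunction, so the reclassification decision
is order-independent (verified over all six orderings); the fixed
evaluation order — timing, then duration, then adherence — matters only
for attributing a multi-criterion failure to its first failing criterion
in the flow counts.  Exposed pregnancies already recorded as smoking
bypass the criteria entirely.  The MPR is deliberately uncapped:
overlapping supplies can push it above 100, which still passes the
adherence criterion.

The cascade is conservative by design: it reclassifies only when the
supply pattern is inconsistent with a successful pre-conception quit, so
the maintained group may still contain continuing smokers whose pattern
merely looked like a quit attempt.

## Utilisation bounds

Prevalence is users/smokers among pregnancy episodes (denominators are
episodes, not distinct women).  The lower bound uses recorded smokers;
the upper bound adds reclassified pregnancies, each of which is an SCP
user by construction, so the upper bound can only be ≥ the lower bound
whenever the lower bound is below 100 %.  The upper bound may
nevertheless overestimate, because smokers without any claims cannot be
detected and never enter its denominator; this caveat is carried in the
report metadata rather than corrected for.  Each therapy is measured
only over conception dates on or after its subsidy listing (bupropion
2001-02-01, varenicline 2008-01-10, NRT patches 2011-02-01; "any"
therapy from the latest of these) up to a configurable cohort-end
delivery date (default 2012-12-31).  Prevalences are reported to one
decimal place with raw counts alongside; an empty denominator yields a
NaN sentinel, never a division error.

## Face validity

Crude odds ratios use the Wald log-OR interval with z = 1.959964 at
95 %; this exactly reproduces the published validation study's printed
ORs and CIs from its printed counts at two decimals, which is the
reason no exact or mid-p interval is offered.  A Haldane–Anscombe 0.5
correction is available behind a flag for zero cells and is off by
default.  SEIFA quintiles are compared against quintile 5 as reference;
episodes missing a factor are excluded from that factor's table only,
with the exclusion count reported.  The adjusted model is a generic
maximum-likelihood logistic fit (statsmodels) over all binary factors
jointly, with the design matrix condition number reported as the
collinearity check; on separation or non-convergence it emits a flag
and no estimates.  A single-covariate logistic OR equals the 2×2 crude
OR, which the tests exploit as an analytic cross-check between the two
routes.

## Synthetic data

The generator emulates the statistical structure of the linked sources,
not prescribing behaviour: each exposed pregnancy draws one supply-
pattern scenario constructed to land on a known side of one criterion
(timely full consecutive course for true quitters; late index, short
course, or a gap forcing MPR < 80 for continuing smokers).  Defaults
mirror the motivating cohort's composition: 14 % smoking prevalence,
5 % of pregnancies exposed, scenario shares 13 % quitters / 57.5 % late
starters / 23.1 % short courses / 6.4 % low adherence, and a reporting
logit whose intercept (1.65) gives a mean recording probability of
about 0.62 among continuing smokers, with negative coefficients on
married (−0.72), private hospital (−0.99), general beneficiary (−1.04),
age ≥ 30 (−0.24) and top SEIFA quintile (−0.75) so that reclassified
women show the expected over-representation of those factors.
Deliveries span 2009–2012 so the varenicline and NRT listing eras are
both exercised.  A single seeded NumPy generator drives all sampling,
so outputs are byte-identical per seed.

The truth table (scenario, true smoking, true quit) is written next to
the record streams but is never read by the pipeline.  Because the
default scenarios are separable — every generated quitter passes all
three criteria, every generated continuing smoker fails at least one —
perfect sensitivity and specificity in the exposed-unrecorded stratum
demonstrates that the cascade implements its definition, *not* that it
would be error-free on real data, where quit attempts and relapses
produce supply patterns on both sides of every threshold.  The generator
also omits several features of real data: multiple pregnancies per
woman, over-the-counter NRT (invisible to claims), off-label bupropion
use, transfer chains around delivery, and any correlation structure
among demographics.

## Problem sizes and numerics

Tests and the acceptance script use synthetic cohorts of 10,000
pregnancies (2,000–20,000 where a check needs more or fewer), sizes at
which every binomial recovery check has comfortable power while the
whole suite runs in seconds.  Monte-Carlo recovery checks use 3-SE
bands.  MPR and day arithmetic are exact rational operations on floats
(halves at worst), so no tolerance is needed on criterion boundaries;
odds ratios are compared at the two-decimal reporting precision and the
logit cross-check at 1e-6.
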