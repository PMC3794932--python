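# Methods

## The statistic and its assumptions

`pacekit` measures prescriber reaction to a clinical event as the ratio of
prescription activity just after the event to that just before it. For one
drug, prescriptions are counted per calendar day at day offsets D−4 … D+1
around each eligible event day D0 and pooled over windows. The prescription
change index is

PCI = slope_after / slope_before,

where slope_before is the average slope of the pooled cumulative count over
[D−4, D−2] and slope_after over [D−1, D+1]. Because a cumulative curve's
average slope over an interval is just the counts accumulated inside it,
the index reduces exactly to (n_D0 + n_D+1) / (n_D−3 + n_D−2): the counts
on D−4 and D−1 anchor the curve but never enter the index. The two
equivalent formulations are both implemented and tested against each other
(the anchor form reproduces the reference arithmetic (54−20)/2 = 17,
(74−62)/2 = 6, PCI = 6/17 = 0.353).

Assumptions worth stating explicitly:

* **Day resolution.** Prescriptions are binned by calendar day; intra-day
  administration times are truncated on load. Multiple records of the same
  drug on the same day each count (the index counts prescription records,
  not distinct exposure days).
* **Counts, not doses.** A dose increase at constant daily frequency is
  invisible to the index.
* **Inpatient, acute-response focus.** The window must fit inside the
  hospitalization (event at least 4 days after admission, at least 1 day
  before discharge), so only 6-day reactions to in-hospital events are
  measured. Outpatient prescribing and slow responses are out of scope.
* **Every event counts.** Repeated events in one admission each anchor
  their own window; windows may overlap.

Degenerate cases are tagged rather than raised: zero before-counts with
positive after-counts give PCI = +inf (an arbitrarily strong increase,
classified intervention); zero on both sides leaves the index undefined
(indeterminate, excluded from pattern summaries and from kappa).

## Patterns and cut-offs

A 1.5-fold change separates the three patterns: PCI ≤ 0.667 (= 1/1.5,
stored to the reported three-decimal precision) is discontinuation,
PCI > 1.500 intervention, anything between maintenance. The boundary
conventions are part of the contract: 0.667 itself is discontinuation,
1.500 itself maintenance. Both cut-offs are configuration
(`CutoffConfig`), with these values as defaults.

## Events and eligibility

* **Threshold events** fire on quantitative lab values strictly above the
  configured threshold (default: serum potassium > 5.5 mmol/L,
  hyperkalemia). D0 is the result date — the day the value became known;
  specimen-collection time is not modelled.
* **Nominal test events** (positive/negative outcomes, e.g. the
  *C. difficile* toxin assay) can be anchored to the order date, the
  result date stratified by outcome, or a configurable number of days
  before the order (default 5) as a no-suspicion reference condition.
* **Baseline exclusion** (threshold events only): if the chronologically
  first measurement of the analyte in the admission exceeds the upper
  reference limit, the window is excluded. The limit defaults to the event
  threshold itself. Exclusion requires evidence of abnormality: admissions
  with no measurement are kept and flagged `no_baseline` instead.
* **Diagnosis exclusion**: patients carrying any ICD-10 code matching a
  configured prefix list are excluded; the default list covers
  renal-failure codes (I12.0, I13.0, I13.1, N17–N19), a pragmatic proxy
  for dialysis-dependent potassium homeostasis. An empty list disables the
  filter.
* Filters only ever flip windows from eligible to ineligible and append
  tagged reasons, so the eligible set is independent of filter order and
  the partition |eligible| + |ineligible| = |events| always holds.
* An optional `min_event_gap_days` (default 0 = keep everything) thins
  events that follow a kept event too closely, for users who prefer
  de-duplicated episodes.

## The binomial alternative

For comparison, the same two-day counts (n_before on D−3/D−2, n_after on
D0/D+1) feed an exact two-sided binomial test of n_after successes in
n_before + n_after trials against probability 0.5 (scipy's `binomtest`,
"minlike" convention: the p-value sums all outcome probabilities no larger
than the observed one). Significant excess after the event is called
intervention, significant deficit discontinuation, otherwise maintenance.
Unlike the PCI it yields a p-value but no effect-size interpretation; on
strong simulated effects (|log r| ≥ log 3, a few hundred windows) the two
calls agree in ≥95% of replicates, which the test suite checks.

## Per-prescriber patterns and agreement

A prescriber's own pattern per drug is the pooled PCI computed from only
that prescriber's prescriptions written within a lookback window (default
365 days before the most recent prescription in the cohort), over the same
hospital-wide eligible event windows. Pairs supported by fewer than
`min_prescriptions` (default 10) prescriptions of the drug inside the
pooled windows are omitted as unreliable. Agreement with externally stated
labels (one of the three substantive patterns per prescriber × drug,
supplied as CSV) is unweighted Cohen's kappa over the three nominal
categories, κ = (p_o − p_e)/(1 − p_e), reported with the observed and
expected agreement and the full 3×3 confusion table. Indeterminate
calculated patterns are treated as missing. When expected agreement is 1
the statistic is undefined and reported as NaN rather than forced to a
number.

## Profiles

A severity sweep re-runs the entire pipeline independently at each
threshold of a strictly increasing grid (default 4.50–7.00 mmol/L in 0.25
steps, 11 points), re-evaluating the baseline exclusion at each threshold
unless a fixed `upper_ref` is given; no caching shortcuts are taken, so any
sweep point is identical to the corresponding single-threshold run (tested
bit-for-bit). Condition profiles run the pipeline once per nominal
condition in clinical order (before order → order → negative → positive).
Points with fewer than `min_windows` (default 5) pooled windows are still
reported but flagged `low_n`; undefined PCIs are exported as missing
values, never zeros. The long-format export table plots directly with any
layer; a convenience matplotlib renderer draws the two cut-off guide
lines.

## The synthetic-data generator

The generator produces the statistical structure the index assumes, so
every module is testable without clinical data. Per patient: one
admission, stay length uniform on 8–20 days, staggered admission dates
over a year; the analyte (serum potassium, mmol/L) measured daily around a
normal baseline (Gaussian, mean 4.2, sd 0.3); excursion days with per-day
hazard 0.05 on which the value is drawn from a configurable magnitude
distribution (default uniform 5.6–7.0, optionally a mixture of uniform
components); each admission assigned one prescriber uniformly. Each drug
is an independent daily Bernoulli draw at `baseline_daily_prob` that
switches to `r × baseline_daily_prob` once its trigger fires (the
excursion — optionally only above a `trigger_level` —, a test order, or a
positive result), from `onset_offset` days after the trigger onward.
Per-prescriber multiplier overrides exercise the agreement module.

Under this model the pooled PCI of a drug converges to its multiplier r,
and `expected_pci` returns that analytic limit (for delayed onsets, the
piecewise two-day expectation, e.g. onset at D+1 with r = 3 gives
(1 + 3)/2 = 2). Two design choices matter for that consistency:

* **One realized excursion per admission (default).** Excursion days carry
  a memoryless per-day hazard, but only the first is realized
  (`max_events_per_admission=1`): an acute episode is detected once and
  treated. If every excursion day were realized, the before-days of
  later-event windows would already sit on the post-event rate and the
  pooled index would be biased toward 1 — the estimator is only consistent
  for r when pre-event days are genuinely pre-event. Setting
  `max_events_per_admission=None` restores fully memoryless events
  (used in tests that exercise the separate-counting rule).
* **Deterministic per-patient substreams.** Each patient consumes an
  independent random substream spawned from (seed, patient index), so the
  same seed reproduces the cohort bit-for-bit and growing `n_patients`
  never reshuffles existing patients.

What the generator does **not** emulate: correlated comorbidity, dosing,
calendar/weekday effects, repeat admissions per patient, measurement
error in the analyte beyond i.i.d. noise, and informative lab-ordering
(potassium is measured every day regardless of suspicion). Passing
parameter-recovery tests therefore show estimator correctness under the
assumed sampling model, not robustness to real-world confounding such as
protopathic prescribing or severity-driven testing.

## Problem sizes and numerical choices

* Parameter-recovery checks run three intents (r = 0.25, 1, 3) on one
  simulated cohort of 16 000 patients, yielding ≈5 000 pooled eligible
  windows; at that size the relative sampling error of the pooled index is
  below ~5%, comfortably inside the ±10% assertion band. Method-
  concordance checks use 20 replicates of 800-patient cohorts (≈250
  windows each). The severity-sweep scenario uses 3 000 patients with a
  mild-dominated magnitude mixture (80% uniform 5.6–5.99, 20% uniform
  6.05–7.0) so that a drug discontinued only above 6.0 mmol/L keeps a
  pooled index above the 0.667 boundary at sub-reaction thresholds — with
  a severe-dominated mixture the pooled index would cross early simply
  because most pooled windows already carry the reaction.
* PCI and slopes are computed in full double precision and reported to
  three decimals; +inf and undefined values are spelled `inf`/`NA` in
  tabular output.
* Ties and boundaries: thresholds are strict (value > t), eligibility
  bounds are inclusive (admit+4 and discharge−1 are eligible), baselines
  use the first result by date with input order as tie-break.
* CSV input is UTF-8 with a header; delimiter and date format are
  configurable (ISO-8601 default). Every rejected row is reported with its
  table, line number and reason; loading never silently drops rows.

## Known limitations

* No confidence interval accompanies the PCI; the binomial alternative
  provides significance but not a compatible interval on the ratio scale.
* The index ignores dose changes and counts duplicate same-day records as
  separate prescriptions; systems that split one order into several rows
  will inflate counts symmetrically (the ratio is scale-invariant, so the
  pattern call is unaffected, but n_prescriptions is not).
* Dialysis status is approximated by diagnosis prefixes, not procedure
  records.
* Pooled windows from repeated events in one admission are not
  independent; the per-drug index is a descriptive ratio, not a model with
  within-patient correlation structure.
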