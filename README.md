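# pacekit

Prescription patterns around clinical events from inpatient EHR data.

## The problem

When a clinical event happens during a hospital stay — serum potassium
crossing 5.5 mmol/L, or a *C. difficile* toxin test being ordered or coming
back positive — prescribers react: they start an antidote, stop an
offending drug, or carry on unchanged. `pacekit` quantifies that reaction
per drug directly from four flat EHR tables (prescriptions, laboratory
results, admissions, diagnoses), so that adherence to treatment guidelines
can be monitored without building a bespoke quality indicator for every
event. It is aimed at pharmacoepidemiologists and clinical-informatics
teams working with inpatient EHR extracts.

## The statistic

Around each eligible event (day **D0**) a six-day observation window
**D−4 … D+1** is anchored, confined to the hospitalization: the event must
fall at least 4 days after admission and at least 1 day before discharge,
and every event occurrence is counted separately. Prescriptions of a drug
are counted per window day and pooled over all eligible windows. With
cumulative count *C(t)*, two average slopes of the cumulative curve are
taken:

```
slope_before = (C(D−2) − C(D−4)) / 2        # counts on D−3, D−2
slope_after  = (C(D+1) − C(D−1)) / 2        # counts on D0,  D+1

PCI = slope_after / slope_before  =  (n_D0 + n_D+1) / (n_D−3 + n_D−2)
```

The **prescription change index (PCI)** classifies each drug into one of
three patterns using a 1.5-fold change as cut-off:

| PCI | pattern |
| --- | --- |
| ≤ 0.667 (= 1/1.5) | discontinuation |
| 0.667 < PCI ≤ 1.500 | maintenance |
| > 1.500 | intervention |

A zero before-count with a positive after-count maps to PCI = +inf
(intervention); zero on both sides is indeterminate. Two confounding
controls are applied to threshold events: admissions whose *baseline*
(first measured) value is already above the upper reference limit are
excluded, as are patients carrying configurable ICD-10 diagnoses (default:
renal-failure codes I12.0, I13.0, I13.1, N17–N19 for potassium).

Beyond the single-threshold analysis the package provides severity sweeps
(PCI versus event threshold over a grid, default 4.50–7.00 mmol/L in 0.25
steps), nominal-condition profiles (before order / order / negative /
positive result), an exact two-sided binomial test on the same two-day
counts as an alternative pattern call, per-prescriber patterns (own
prescriptions, 1-year lookback, minimum 10 prescriptions) with Cohen's
kappa against stated knowledge labels, and a seeded synthetic-cohort
generator for testing all of it.

## Worked example

```python
import pacekit as pk

params = pk.SyntheticCohortParams(
    n_patients=4000,
    seed=7,
    drugs=(
        pk.DrugIntent("C03DA01", 0.20, 0.25),   # potassium-sparing diuretic: stop
        pk.DrugIntent("C08CA01", 0.20, 1.0),    # calcium-channel blocker: unrelated
        pk.DrugIntent("A12AA03", 0.10, 3.0),    # calcium gluconate: treat
    ),
)
cohort = pk.simulate_cohort(params)
model = pk.PACE(cohort, drugs=["C03DA01", "C08CA01", "A12AA03"],
                event=pk.EventConfig(analyte="potassium", threshold=5.5))
res = model.fit(compare_binomial=True)
print(res.summary())
```

prints

```
PACE: Prescription pattern Around Clinical Event
========================================================================
Event:             potassium > 5.5 (lab_threshold)
Windows:           1241 eligible of 2119 detected
Exclusions:        {'too_early': 779, 'abnormal_baseline': 195, 'too_late': 99}
Cutoffs:           discontinuation <= 0.667 < maintenance <= 1.5 < intervention
------------------------------------------------------------------------
drug            n_win   n_rx   slopeA   slopeB      PCI  pattern
C03DA01          1241   1112  258.000   59.500    0.231  discontinuation
C08CA01          1241   1447  238.500  244.500    1.025  maintenance
A12AA03          1241   1273  130.500  374.000    2.866  intervention
========================================================================
```

Reading the table: 2119 hyperkalemic events were detected; 1241 windows
survived the hospitalization-fit and baseline checks. The diuretic's
prescriptions nearly vanish after the event (PCI 0.231, generated with a
post-event rate multiplier of 0.25 — the pooled PCI estimates exactly that
multiplier), the unrelated drug stays near 1, and the treatment drug
roughly triples (multiplier 3.0). The binomial columns
(`fit(compare_binomial=True)`) call the same three patterns with exact
two-sided p-values of 8.2e-60, 0.72 and 5.1e-55.

The same pipeline is scriptable from a shell:

```bash
pace simulate --params sim.yaml --out data/
pace compute --config run.yaml          # pace_results.tsv + JSON + manifest
pace sweep --config run.yaml --mode severity
pace agreement --config run.yaml --labels knowledge_labels.csv
```

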