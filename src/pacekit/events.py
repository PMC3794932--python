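"""Clinical-event detection, observation windows, and eligibility rules.

A clinical event anchors a six-day observation window spanning day offsets
D-4 .. D+1 around the event day D0.  Events come in two flavours:

* **lab_threshold** — a quantitative lab result strictly above a threshold
  (e.g. serum potassium > 5.5 mmol/L, a hyperkalemic event).  Each
  qualifying result is a separate event, even within one admission.
* **nominal test events** — for tests with a positive/negative outcome
  (e.g. the C. difficile toxin test) an event can be anchored to the day
  the test was ordered (``test_order``), the day a result came back
  (``test_result_positive`` / ``test_result_negative``), or a configurable
  number of days before the order (``before_order``, a pre-suspicion
  reference condition).

Eligibility: the window must fit inside the hospitalization, so the event
must fall at least 4 days after admission and at least 1 day before
discharge.  Two further exclusions mirror routine confounding control for
threshold events: admissions whose *baseline* value (first measurement of
the analyte after admission) is already above the upper reference limit,
and patients carrying diagnoses (ICD-10 prefixes) that independently
perturb the analyte, e.g. chronic renal failure for potassium.

Filters never resurrect a window: they only flip eligible -> ineligible,
appending tagged reasons, so the eligible set is independent of the order
in which the filters are applied.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ehr import CohortData

__all__ = [
    "EVENT_KINDS",
    "WINDOW_OFFSETS",
    "ClinicalEvent",
    "ObservationWindow",
    "EventConfig",
    "detect_lab_threshold_events",
    "detect_order_and_result_events",
    "detect_before_order_events",
    "dedupe_events",
    "apply_admission_eligibility",
    "apply_baseline_exclusion",
    "apply_diagnosis_exclusion",
    "extract_windows",
]

EVENT_KINDS = (
    "lab_threshold",
    "test_order",
    "test_result_positive",
    "test_result_negative",
    "before_order",
)

#: day offsets of the observation window relative to the event day D0
WINDOW_OFFSETS: tuple[int, ...] = (-4, -3, -2, -1, 0, 1)

#: ICD-10 prefixes for renal failure (the potassium-confounding exclusion)
RENAL_FAILURE_ICD10 = ("I12.0", "I13.0", "I13.1", "N17", "N18", "N19")


@dataclass(frozen=True)
class ClinicalEvent:
    """One occurrence of a clinical event; ``index_date`` is D0."""

    patient_id: str
    admission_id: str
    event_kind: str
    index_date: pd.Timestamp
    analyte: str
    severity_value: float | None = None  # lab value at D0; only for lab_threshold

    def __post_init__(self):
        if self.event_kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind '{self.event_kind}'")
        if (self.severity_value is not None) != (self.event_kind == "lab_threshold"):
            raise ValueError("severity_value is present iff event_kind is lab_threshold")


@dataclass(frozen=True)
class ObservationWindow:
    """A D-4..D+1 window anchored on one event, with its eligibility state.

    ``eligible`` is true exactly when ``exclusion_reasons`` is empty;
    ``flags`` carries advisory annotations (e.g. ``no_baseline``) that do
    not affect eligibility.
    """

    event: ClinicalEvent
    exclusion_reasons: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    @property
    def eligible(self) -> bool:
        return not self.exclusion_reasons

    @property
    def day_offsets(self) -> tuple[int, ...]:
        return WINDOW_OFFSETS

    def day(self, offset: int) -> pd.Timestamp:
        if offset not in WINDOW_OFFSETS:
            raise ValueError(f"offset {offset} outside window {WINDOW_OFFSETS}")
        return self.event.index_date + pd.Timedelta(days=offset)

    def excluded(self, reason: str) -> "ObservationWindow":
        return replace(self, exclusion_reasons=self.exclusion_reasons + (reason,))

    def flagged(self, flag: str) -> "ObservationWindow":
        return replace(self, flags=self.flags + (flag,))


@dataclass(frozen=True)
class EventConfig:
    """Event definition plus eligibility knobs for one analysis run.

    ``upper_ref=None`` ties the baseline upper reference limit to the event
    threshold itself (the analysis default for potassium, 5.5 mmol/L).
    ``min_event_gap_days=0`` keeps every event; a positive gap de-duplicates
    events within an admission that follow a kept event too closely.
    """

    analyte: str = "potassium"
    kind: str = "lab_threshold"
    threshold: float = 5.5
    upper_ref: float | None = None
    exclusion_icd10_prefixes: tuple[str, ...] = RENAL_FAILURE_ICD10
    min_event_gap_days: int = 0
    before_order_days: int = 5

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind '{self.kind}'")

    @property
    def effective_upper_ref(self) -> float:
        return self.threshold if self.upper_ref is None else self.upper_ref


def _quantitative_rows(labs: pd.DataFrame, analyte: str) -> pd.DataFrame:
    sub = labs[labs["analyte"] == analyte]
    if len(sub) and sub["value_num"].isna().any():
        raise TypeError(f"analyte '{analyte}' has nominal values; a quantitative analyte is required")
    return sub


def detect_lab_threshold_events(
    labs: pd.DataFrame, analyte: str, threshold: float
) -> list[ClinicalEvent]:
    """Events where a quantitative lab value is strictly above ``threshold``.

    D0 is the result date (the day the value became known).  Every
    qualifying record yields its own event: multiple crossings within one
    admission are counted separately.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    sub = _quantitative_rows(labs, analyte)
    hits = sub[sub["value_num"] > threshold]
    events = [
        ClinicalEvent(
            patient_id=row.patient_id,
            admission_id=row.admission_id,
            event_kind="lab_threshold",
            index_date=row.result_date,
            analyte=analyte,
            severity_value=float(row.value_num),
        )
        for row in hits.itertuples()
    ]
    events.sort(key=lambda e: (e.patient_id, e.admission_id, e.index_date))
    return events


def detect_order_and_result_events(labs: pd.DataFrame, analyte: str) -> list[ClinicalEvent]:
    """Order-day and result-day events for a nominal (positive/negative) test.

    Each test record yields a ``test_order`` event at its order date and a
    ``test_result_positive``/``test_result_negative`` event at its result
    date.  Records without a usable result token are skipped with a warning;
    records without an order date yield only the result event.
    """
    sub = labs[labs["analyte"] == analyte]
    events: list[ClinicalEvent] = []
    for row in sub.itertuples():
        token = row.value_str
        if token not in ("positive", "negative"):
            warnings.warn(
                f"{analyte} record for admission {row.admission_id} has no usable "
                f"positive/negative result; skipped",
                stacklevel=2,
            )
            continue
        if not pd.isna(row.order_date):
            events.append(
                ClinicalEvent(row.patient_id, row.admission_id, "test_order", row.order_date, analyte)
            )
        events.append(
            ClinicalEvent(
                row.patient_id, row.admission_id, f"test_result_{token}", row.result_date, analyte
            )
        )
    events.sort(key=lambda e: (e.patient_id, e.admission_id, e.index_date, e.event_kind))
    return events


def detect_before_order_events(
    labs: pd.DataFrame, analyte: str, days_before: int = 5
) -> list[ClinicalEvent]:
    """Reference events anchored ``days_before`` days before each test order.

    Used as the no-suspicion baseline condition in condition profiles.
    """
    sub = labs[(labs["analyte"] == analyte) & labs["order_date"].notna()]
    events = [
        ClinicalEvent(
            row.patient_id,
            row.admission_id,
            "before_order",
            row.order_date - pd.Timedelta(days=days_before),
            analyte,
        )
        for row in sub.itertuples()
    ]
    events.sort(key=lambda e: (e.patient_id, e.admission_id, e.index_date))
    return events


def dedupe_events(events: Sequence[ClinicalEvent], min_gap_days: int = 0) -> list[ClinicalEvent]:
    """Optionally thin events within an admission.

    With ``min_gap_days=0`` (default) every event is kept — each occurrence
    counts separately.  With a positive gap, an event is dropped when a kept
    event of the same kind in the same admission occurred fewer than
    ``min_gap_days`` days earlier.
    """
    if min_gap_days <= 0:
        return list(events)
    kept: list[ClinicalEvent] = []
    last_kept: dict[tuple[str, str], pd.Timestamp] = {}
    for ev in sorted(events, key=lambda e: (e.admission_id, e.event_kind, e.index_date)):
        key = (ev.admission_id, ev.event_kind)
        prev = last_kept.get(key)
        if prev is not None and (ev.index_date - prev).days < min_gap_days:
            continue
        kept.append(ev)
        last_kept[key] = ev.index_date
    kept.sort(key=lambda e: (e.patient_id, e.admission_id, e.index_date, e.event_kind))
    return kept


def apply_admission_eligibility(
    events: Sequence[ClinicalEvent], admissions: pd.DataFrame
) -> list[ObservationWindow]:
    """Anchor windows and require them to fit within the hospitalization.

    Eligible iff index_date is at least 4 days after admission and at least
    1 day before discharge; otherwise tagged ``too_early``/``too_late``.
    """
    span = admissions.set_index("admission_id")[["admit_date", "discharge_date"]]
    unknown = [e for e in events if e.admission_id not in span.index]
    if unknown:
        raise KeyError(
            "events reference unknown admissions: "
            + ", ".join(f"{e.admission_id}@{e.index_date.date()}" for e in unknown[:5])
        )
    windows = []
    for ev in events:
        w = ObservationWindow(ev)
        admit = span.at[ev.admission_id, "admit_date"]
        discharge = span.at[ev.admission_id, "discharge_date"]
        if (ev.index_date - admit).days < 4:
            w = w.excluded("too_early")
        if (discharge - ev.index_date).days < 1:
            w = w.excluded("too_late")
        windows.append(w)
    return windows


def apply_baseline_exclusion(
    windows: Sequence[ObservationWindow],
    labs: pd.DataFrame,
    analyte: str,
    upper_ref: float,
) -> list[ObservationWindow]:
    """Exclude windows whose admission started with an abnormal baseline.

    The baseline is the chronologically first value of ``analyte`` in the
    admission; if it exceeds ``upper_ref`` the window is tagged
    ``abnormal_baseline``.  Exclusion requires evidence: admissions with no
    measurement at all are kept and flagged ``no_baseline``.
    """
    if not np.isfinite(upper_ref):
        raise ValueError("upper_ref must be finite")
    sub = _quantitative_rows(labs, analyte)
    first = (
        sub.sort_values("result_date", kind="mergesort")
        .groupby("admission_id", sort=False)["value_num"]
        .first()
    )
    out = []
    for w in windows:
        base = first.get(w.event.admission_id)
        if base is None or pd.isna(base):
            out.append(w.flagged("no_baseline"))
        elif base > upper_ref:
            out.append(w.excluded("abnormal_baseline"))
        else:
            out.append(w)
    return out


def apply_diagnosis_exclusion(
    windows: Sequence[ObservationWindow],
    diagnoses: pd.DataFrame,
    icd10_prefixes: Sequence[str],
) -> list[ObservationWindow]:
    """Exclude windows of patients carrying any diagnosis matching a prefix.

    An empty prefix list disables the filter.
    """
    prefixes = tuple(icd10_prefixes)
    if not prefixes:
        return list(windows)
    flagged_patients = set(
        diagnoses.loc[
            diagnoses["icd10_code"].map(lambda c: c.startswith(prefixes)), "patient_id"
        ]
    )
    return [
        w.excluded("excluded_diagnosis") if w.event.patient_id in flagged_patients else w
        for w in windows
    ]


def extract_windows(cohort: CohortData, config: EventConfig) -> list[ObservationWindow]:
    """Full event-to-window pipeline for one event definition.

    Detect events of ``config.kind``, optionally thin them, anchor windows,
    then apply hospitalization eligibility, the abnormal-baseline exclusion
    (threshold events only) and the diagnosis exclusion.
    """
    if config.kind == "lab_threshold":
        events = detect_lab_threshold_events(cohort.labs, config.analyte, config.threshold)
    elif config.kind in ("test_order", "test_result_positive", "test_result_negative"):
        events = [
            e
            for e in detect_order_and_result_events(cohort.labs, config.analyte)
            if e.event_kind == config.kind
        ]
    elif config.kind == "before_order":
        events = detect_before_order_events(cohort.labs, config.analyte, config.before_order_days)
    else:  # pragma: no cover - guarded by EventConfig
        raise ValueError(f"unknown event kind '{config.kind}'")

    events = dedupe_events(events, config.min_event_gap_days)
    windows = apply_admission_eligibility(events, cohort.admissions)
    if config.kind == "lab_threshold":
        windows = apply_baseline_exclusion(
            windows, cohort.labs, config.analyte, config.effective_upper_ref
        )
    windows = apply_diagnosis_exclusion(windows, cohort.diagnoses, config.exclusion_icd10_prefixes)
    return windows
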