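"""Seeded synthetic inpatient cohorts with configurable prescriber intent.

The generator emulates the data structure the PACE statistic assumes: one
admission per patient with a stay of 8-20 days, a quantitative analyte
(serum potassium, mmol/L) measured every day around a normal baseline
(4.2 +/- 0.3), and occasional excursion days on which the value jumps above
the clinical threshold — a clinical event.  Each monitored drug is
administered as an independent daily Bernoulli draw whose probability
switches from ``baseline_daily_prob`` to ``post_event_multiplier x
baseline_daily_prob`` once the drug's trigger fires (the excursion, a test
order, or a positive test result), from ``onset_offset`` days after the
trigger onward.  Under this model the pooled PCI of a drug converges to its
multiplier ``r``, which makes parameter recovery directly testable.

Excursion days carry a per-day hazard (``event_day_prob``), but by default
only the first excursion of an admission is realized
(``max_events_per_admission=1``): an acute episode is detected once and
treated, and the pre-event days of every observation window are then
genuinely pre-event.  Setting ``max_events_per_admission=None`` realizes
every excursion day independently (memoryless), which produces admissions
with several events — useful for exercising the separate-counting rule,
at the price of event-contaminated before-windows that bias pooled PCI
toward 1.

Randomness: each patient consumes an independent substream spawned
deterministically from the cohort seed and the patient index, so the same
seed reproduces the cohort bit-for-bit and growing ``n_patients`` never
reshuffles existing patients.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .ehr import CohortData

__all__ = [
    "DrugIntent",
    "SyntheticCohortParams",
    "simulate_cohort",
    "expected_pci",
    "params_from_dict",
]

_BENIGN_DX = ("E11.9", "I10", "J45.9")


@dataclass(frozen=True)
class DrugIntent:
    """Generative intent for one drug.

    ``post_event_multiplier`` r encodes the prescriber's reaction: r > 1 is
    an intervention intent, r < 1 a discontinuation intent, r = 1
    maintenance.  ``trigger_level`` (threshold events only) makes the drug
    react only to excursions strictly above that value, modelling
    severity-dependent behaviour.  ``onset_offset`` delays (or advances)
    the switch relative to the trigger day.
    """

    drug_code: str
    baseline_daily_prob: float
    post_event_multiplier: float = 1.0
    trigger: str = "lab_threshold"  # lab_threshold | test_order | test_result_positive
    trigger_level: float | None = None
    onset_offset: int = 0

    def __post_init__(self):
        if not self.drug_code:
            raise ValueError("drug_code must be non-empty")
        if not 0 < self.baseline_daily_prob < 1:
            raise ValueError(f"baseline_daily_prob must lie in (0, 1), got {self.baseline_daily_prob}")
        if self.post_event_multiplier < 0:
            raise ValueError("post_event_multiplier must be nonnegative")
        if self.post_event_multiplier * self.baseline_daily_prob > 1:
            raise ValueError(
                f"infeasible probability: {self.post_event_multiplier} x "
                f"{self.baseline_daily_prob} > 1 for drug {self.drug_code}"
            )
        if self.trigger not in ("lab_threshold", "test_order", "test_result_positive"):
            raise ValueError(f"unknown trigger '{self.trigger}'")


MagnitudeMixture = tuple[tuple[float, float, float], ...]  # (weight, low, high) components


@dataclass(frozen=True)
class SyntheticCohortParams:
    """Generative parameters for one synthetic cohort; the seed is mandatory.

    ``event_magnitude`` is a mixture of uniform components
    ``(weight, low, high)`` — a plain ``(low, high)`` pair is accepted and
    treated as a single component.
    """

    n_patients: int
    drugs: tuple[DrugIntent, ...]
    seed: int
    n_prescribers: int = 10
    stay_days: tuple[int, int] = (8, 20)
    lab_analyte: str = "potassium"
    lab_baseline_mean: float = 4.2
    lab_baseline_sd: float = 0.3
    event_day_prob: float = 0.05
    event_magnitude: MagnitudeMixture = ((1.0, 5.6, 7.0),)
    max_events_per_admission: int | None = 1
    nominal_analyte: str | None = None
    nominal_order_day_prob: float = 0.0
    nominal_positive_prob: float = 0.5
    nominal_result_delay: int = 3
    prescriber_intents: Mapping[str, Mapping[str, float]] | None = None
    benign_dx_prob: float = 0.1
    excluded_dx_prob: float = 0.0
    excluded_dx_code: str = "N18.9"
    admit_start: str = "2021-01-01"
    admit_spread_days: int = 365

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be >= 1, got {self.n_patients}")
        if not self.drugs:
            raise ValueError("at least one DrugIntent is required")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for p in (self.event_day_prob, self.nominal_order_day_prob, self.nominal_positive_prob,
                  self.benign_dx_prob, self.excluded_dx_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.stay_days[0] < 1 or self.stay_days[0] > self.stay_days[1]:
            raise ValueError(f"invalid stay_days {self.stay_days}")
        mixture = self.magnitude_components
        if abs(sum(w for w, _, _ in mixture) - 1.0) > 1e-9:
            raise ValueError("event_magnitude component weights must sum to 1")
        if self.prescriber_intents:
            by_code = {d.drug_code: d for d in self.drugs}
            for overrides in self.prescriber_intents.values():
                for code, r in overrides.items():
                    if code not in by_code:
                        raise ValueError(f"prescriber intent for unknown drug '{code}'")
                    if r * by_code[code].baseline_daily_prob > 1:
                        raise ValueError(f"infeasible probability for override {code}: r={r}")

    @property
    def magnitude_components(self) -> MagnitudeMixture:
        mag = self.event_magnitude
        if mag and isinstance(mag[0], (int, float)):  # plain (low, high) pair
            lo, hi = mag  # type: ignore[misc]
            return ((1.0, float(lo), float(hi)),)
        return tuple((float(w), float(lo), float(hi)) for w, lo, hi in mag)


def expected_pci(intent: DrugIntent) -> float:
    """Analytic pooled-PCI limit for a drug under the generative model.

    With the switch active from ``onset_offset`` days after the event, the
    two after-days D0/D+1 and the two before-days D-3/D-2 have daily rates
    p or r*p depending on whether their offset is past the onset; the PCI
    limit is the ratio of the two-day rate sums.  For the default onset at
    D0 this is exactly r.
    """
    p, r = intent.baseline_daily_prob, intent.post_event_multiplier

    def rate(offset: int) -> float:
        return r * p if offset >= intent.onset_offset else p

    return (rate(0) + rate(1)) / (rate(-3) + rate(-2))


def _draw_magnitude(rng: np.random.Generator, mixture: MagnitudeMixture) -> float:
    u = rng.random()
    acc = 0.0
    for w, lo, hi in mixture:
        acc += w
        if u <= acc:
            return float(rng.uniform(lo, hi))
    return float(rng.uniform(mixture[-1][1], mixture[-1][2]))


def simulate_cohort(params: SyntheticCohortParams) -> CohortData:
    """Generate a synthetic cohort; identical for identical parameters."""
    mixture = params.magnitude_components
    overrides = params.prescriber_intents or {}
    stay_lo, stay_hi = params.stay_days

    adm_rows: list[tuple] = []  # patient, admission, admit_day, discharge_day
    lab_rows: list[tuple] = []  # patient, admission, analyte, num, token, order_day, result_day
    rx_rows: list[tuple] = []  # patient, admission, drug, prescriber, day
    dx_rows: list[tuple] = []

    for i in range(params.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=params.seed, spawn_key=(i,)))
        pid, aid = f"P{i:06d}", f"A{i:06d}"
        admit = int(rng.integers(0, params.admit_spread_days)) if params.admit_spread_days > 0 else 0
        stay = int(rng.integers(stay_lo, stay_hi + 1))
        prescriber = f"DR{int(rng.integers(params.n_prescribers)):03d}"
        adm_rows.append((pid, aid, admit, admit + stay))

        n_days = stay + 1  # days 0..stay relative to admission
        values = rng.normal(params.lab_baseline_mean, params.lab_baseline_sd, n_days)
        excursion = rng.random(n_days) < params.event_day_prob
        event_days = np.flatnonzero(excursion)
        if params.max_events_per_admission is not None:
            event_days = event_days[: params.max_events_per_admission]
        magnitudes = {}
        for d in event_days:
            magnitudes[int(d)] = _draw_magnitude(rng, mixture)
            values[d] = magnitudes[int(d)]
        for d in range(n_days):
            lab_rows.append((pid, aid, params.lab_analyte, float(values[d]), "", admit + d, admit + d))

        order_day = result_day = None
        positive = False
        if params.nominal_analyte is not None and params.nominal_order_day_prob > 0:
            orders = np.flatnonzero(rng.random(n_days) < params.nominal_order_day_prob)
            positive = bool(rng.random() < params.nominal_positive_prob)
            if len(orders):
                order_day = int(orders[0])
                result_day = min(order_day + params.nominal_result_delay, stay)
                lab_rows.append(
                    (
                        pid,
                        aid,
                        params.nominal_analyte,
                        np.nan,
                        "positive" if positive else "negative",
                        admit + order_day,
                        admit + result_day,
                    )
                )

        if rng.random() < params.benign_dx_prob:
            dx_rows.append((pid, _BENIGN_DX[int(rng.integers(len(_BENIGN_DX)))]))
        if params.excluded_dx_prob > 0 and rng.random() < params.excluded_dx_prob:
            dx_rows.append((pid, params.excluded_dx_code))

        my_overrides = overrides.get(prescriber, {})
        for intent in params.drugs:
            if intent.trigger == "lab_threshold":
                level = -np.inf if intent.trigger_level is None else intent.trigger_level
                hits = [d for d in event_days if magnitudes[int(d)] > level]
                trigger_day = int(hits[0]) if hits else None
            elif intent.trigger == "test_order":
                trigger_day = order_day
            else:  # test_result_positive
                trigger_day = result_day if positive else None
            r = my_overrides.get(intent.drug_code, intent.post_event_multiplier)
            probs = np.full(n_days, intent.baseline_daily_prob)
            if trigger_day is not None:
                onset = max(0, trigger_day + intent.onset_offset)
                probs[onset:] = min(1.0, r * intent.baseline_daily_prob)
            taken = np.flatnonzero(rng.random(n_days) < probs)
            for d in taken:
                rx_rows.append((pid, aid, intent.drug_code, prescriber, admit + int(d)))

    base = pd.Timestamp(params.admit_start)

    def days_to_dates(col: pd.Series) -> pd.Series:
        return base + pd.to_timedelta(col, unit="D")

    admissions = pd.DataFrame(adm_rows, columns=["patient_id", "admission_id", "admit_date", "discharge_date"])
    for col in ("admit_date", "discharge_date"):
        admissions[col] = days_to_dates(admissions[col])

    labs = pd.DataFrame(
        lab_rows,
        columns=["patient_id", "admission_id", "analyte", "value_num", "value_str", "order_date", "result_date"],
    )
    for col in ("order_date", "result_date"):
        labs[col] = days_to_dates(labs[col])

    prescriptions = pd.DataFrame(
        rx_rows, columns=["patient_id", "admission_id", "drug_code", "prescriber_id", "admin_date"]
    )
    prescriptions["admin_date"] = (
        days_to_dates(prescriptions["admin_date"])
        if len(prescriptions)
        else pd.to_datetime(prescriptions["admin_date"])
    )

    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "icd10_code"])

    return CohortData(prescriptions, labs, admissions, diagnoses)


def params_from_dict(raw: Mapping) -> SyntheticCohortParams:
    """Build parameters from a plain mapping (e.g. a parsed YAML file)."""
    d = dict(raw)
    drug_specs = d.pop("drugs", None)
    if not drug_specs:
        raise ValueError("params must define a non-empty 'drugs' list")
    drugs = tuple(DrugIntent(**spec) for spec in drug_specs)
    known = {f.name for f in dataclasses.fields(SyntheticCohortParams)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
    for key in ("stay_days", "event_magnitude"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(tuple(x) if isinstance(x, list) else x for x in d[key])
    return SyntheticCohortParams(drugs=drugs, **d)
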