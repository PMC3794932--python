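"""The prescription change index (PCI) and the three prescription patterns.

Around each eligible clinical event, prescriptions of a drug are counted per
window day D-4..D+1 and pooled over all eligible windows.  The cumulative
count curve yields two average slopes:

* slope_before — average slope over [D-4, D-2], i.e. the prescription count
  accumulated on the two pre-event days D-3 and D-2, divided by 2;
* slope_after  — average slope over [D-1, D+1], i.e. the count accumulated
  on the event day D0 and the day after, D+1, divided by 2.

``PCI = slope_after / slope_before``, which reduces exactly to
``(n_D0 + n_D+1) / (n_D-3 + n_D-2)``; the counts on D-4 and D-1 never enter
the index (they only anchor the cumulative curve).  The two published slope
anchors (the D-4/D-2 and D-1/D+1 cumulative values) and the two-day count
sums are therefore the same quantity written two ways, and both reproduce
the reference arithmetic slope_before = (54-20)/2 = 17,
slope_after = (74-62)/2 = 6, PCI = 6/17 = 0.353.

Classification: PCI <= 0.667 (= 1/1.5) is a discontinuation pattern,
PCI > 1.500 an intervention pattern, anything between a maintenance
pattern.  A zero before-count with a positive after-count is the limit of
an arbitrarily strong increase and maps to PCI = +inf (intervention); zero
counts on both sides leave the index undefined (pattern "indeterminate",
excluded from pattern summaries).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ehr import CohortData
from .events import WINDOW_OFFSETS, EventConfig, ObservationWindow, extract_windows

__all__ = [
    "PATTERNS",
    "PATTERN_CATEGORIES",
    "CutoffConfig",
    "WindowCounts",
    "CumulativeCurve",
    "PCIResult",
    "tabulate_window_counts",
    "cumulate",
    "average_slope",
    "compute_pci",
    "classify_pattern",
    "run_pace",
]

#: the three substantive patterns, plus the degenerate label
PATTERN_CATEGORIES = ("intervention", "maintenance", "discontinuation")
PATTERNS = PATTERN_CATEGORIES + ("indeterminate",)

_BEFORE_SPAN = (-4, -2)  # slope_before anchors; captures counts on D-3, D-2
_AFTER_SPAN = (-1, 1)  # slope_after anchors; captures counts on D0, D+1


@dataclass(frozen=True)
class CutoffConfig:
    """PCI cut-offs: a 1.5-fold change in prescription number.

    ``lower = 1/1.5 = 0.667`` (to the precision used in reporting) and
    ``upper = 1.500``; PCI <= lower is discontinuation, PCI > upper is
    intervention.
    """

    lower: float = 0.667
    upper: float = 1.500

    def __post_init__(self):
        if not (0 < self.lower < self.upper):
            raise ValueError(f"require 0 < lower < upper, got {self.lower}, {self.upper}")


DEFAULT_CUTOFFS = CutoffConfig()


@dataclass(frozen=True)
class WindowCounts:
    """Pooled per-day prescription counts for one drug over eligible windows."""

    drug_code: str
    counts_by_offset: tuple[int, ...]  # offsets -4..+1
    n_windows: int

    def __post_init__(self):
        if len(self.counts_by_offset) != len(WINDOW_OFFSETS):
            raise ValueError("exactly six day offsets (-4..+1) required")
        if any(c < 0 for c in self.counts_by_offset):
            raise ValueError("counts must be nonnegative")

    def count(self, offset: int) -> int:
        return self.counts_by_offset[WINDOW_OFFSETS.index(offset)]


@dataclass(frozen=True)
class CumulativeCurve:
    """Running total of pooled prescription counts across the window days."""

    drug_code: str
    cumulative_by_offset: tuple[float, ...]

    def __post_init__(self):
        c = self.cumulative_by_offset
        if len(c) != len(WINDOW_OFFSETS):
            raise ValueError("exactly six day offsets (-4..+1) required")
        if any(b < a for a, b in zip(c, c[1:])):
            raise ValueError("cumulative curve must be non-decreasing")

    def value(self, offset: int) -> float:
        return self.cumulative_by_offset[WINDOW_OFFSETS.index(offset)]

    @classmethod
    def from_anchors(
        cls,
        at_minus4: float,
        at_minus2: float,
        at_minus1: float,
        at_plus1: float,
        drug_code: str = "",
    ) -> "CumulativeCurve":
        """Build a curve from the four anchor values that determine the PCI.

        The unconstrained days D-3 and D0 are filled at the midpoint of
        their neighbours; they do not affect slopes or the index.
        """
        return cls(
            drug_code,
            (
                float(at_minus4),
                (at_minus4 + at_minus2) / 2.0,
                float(at_minus2),
                float(at_minus1),
                (at_minus1 + at_plus1) / 2.0,
                float(at_plus1),
            ),
        )


@dataclass(frozen=True)
class PCIResult:
    """PCI for one drug: the two slopes, the index, and its pattern.

    ``pci`` is a nonnegative float, ``math.inf`` (no pre-event
    prescriptions but some post-event ones), or ``math.nan`` when undefined
    (no prescriptions on either side).
    """

    drug_code: str
    slope_before: float
    slope_after: float
    pci: float
    n_windows: int
    n_prescriptions: int
    pattern: str

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pci)


def tabulate_window_counts(
    prescriptions: pd.DataFrame,
    windows: Sequence[ObservationWindow],
    drug_code: str,
) -> WindowCounts:
    """Pool per-day counts of ``drug_code`` over eligible windows.

    ``counts_by_offset[k]`` is the number of prescription records of the
    drug administered on index_date + k, summed over windows; every record
    counts once per window it falls into (multiple same-day records each
    count).  Prescriptions outside D-4..D+1, or in other admissions, are
    ignored.  An empty window list yields all-zero counts.
    """
    if not drug_code:
        raise ValueError("drug_code must be non-empty")
    ineligible = [w for w in windows if not w.eligible]
    if ineligible:
        raise ValueError(f"{len(ineligible)} ineligible windows passed to tabulate_window_counts")
    counts = np.zeros(len(WINDOW_OFFSETS), dtype=int)
    if windows:
        wdf = pd.DataFrame(
            {
                "admission_id": [w.event.admission_id for w in windows],
                "index_date": [w.event.index_date for w in windows],
            }
        )
        sub = prescriptions[prescriptions["drug_code"] == drug_code]
        if len(sub):
            merged = sub.merge(wdf, on="admission_id")
            if len(merged):
                offsets = (merged["admin_date"] - merged["index_date"]).dt.days
                inside = offsets.between(WINDOW_OFFSETS[0], WINDOW_OFFSETS[-1])
                binned = np.bincount(
                    (offsets[inside] - WINDOW_OFFSETS[0]).to_numpy(),
                    minlength=len(WINDOW_OFFSETS),
                )
                counts += binned.astype(int)
    return WindowCounts(drug_code, tuple(int(c) for c in counts), n_windows=len(windows))


def cumulate(counts: WindowCounts) -> CumulativeCurve:
    """Cumulative sum of the per-day counts from D-4 through D+1."""
    return CumulativeCurve(
        counts.drug_code, tuple(float(v) for v in np.cumsum(counts.counts_by_offset))
    )


def average_slope(curve: CumulativeCurve, t1: int, t2: int) -> float:
    """Average slope of the cumulative curve between day offsets t1 < t2."""
    if t1 >= t2:
        raise ValueError(f"require t1 < t2, got {t1} >= {t2}")
    if t1 not in WINDOW_OFFSETS or t2 not in WINDOW_OFFSETS:
        raise ValueError(f"offsets must lie in {WINDOW_OFFSETS}")
    return (curve.value(t2) - curve.value(t1)) / (t2 - t1)


def classify_pattern(pci: float, cutoffs: CutoffConfig = DEFAULT_CUTOFFS) -> str:
    """Map a PCI to its prescription pattern.

    pci <= lower -> discontinuation; pci > upper -> intervention;
    lower < pci <= upper -> maintenance; NaN (undefined) -> indeterminate.
    """
    if math.isnan(pci):
        return "indeterminate"
    if pci < 0:
        raise ValueError(f"PCI must be nonnegative, got {pci}")
    if pci <= cutoffs.lower:
        return "discontinuation"
    if pci > cutoffs.upper:
        return "intervention"
    return "maintenance"


def compute_pci(
    curve: CumulativeCurve,
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    n_windows: int = 0,
) -> PCIResult:
    """Slopes, PCI and pattern from a pooled cumulative curve.

    Degenerate denominators are tagged, not raised: a zero before-slope
    with a positive after-slope gives PCI = +inf (intervention); zero on
    both sides leaves the PCI undefined (indeterminate).
    """
    slope_before = average_slope(curve, *_BEFORE_SPAN)
    slope_after = average_slope(curve, *_AFTER_SPAN)
    if slope_before > 0:
        pci = slope_after / slope_before
    elif slope_after > 0:
        pci = math.inf
    else:
        pci = math.nan
    return PCIResult(
        drug_code=curve.drug_code,
        slope_before=slope_before,
        slope_after=slope_after,
        pci=pci,
        n_windows=n_windows,
        n_prescriptions=int(curve.value(WINDOW_OFFSETS[-1])),
        pattern=classify_pattern(pci, cutoffs),
    )


def run_pace(
    cohort: CohortData,
    event_config: EventConfig = EventConfig(),
    drug_list: Sequence[str] = (),
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    prescriptions: pd.DataFrame | None = None,
    windows: Sequence[ObservationWindow] | None = None,
) -> list[PCIResult]:
    """End-to-end PACE: events -> eligible windows -> pooled PCI per drug.

    Parameters
    ----------
    cohort
        Validated cohort tables.
    event_config
        Event definition and eligibility knobs.
    drug_list
        Drug codes to monitor (non-empty).
    cutoffs
        Pattern cut-offs.
    prescriptions
        Optional replacement prescription table (e.g. restricted to one
        prescriber); defaults to ``cohort.prescriptions``.
    windows
        Pre-extracted windows, to avoid re-running event extraction when
        several analyses share the same event definition.
    """
    if not drug_list:
        raise ValueError("drug_list must be non-empty")
    if windows is None:
        windows = extract_windows(cohort, event_config)
    eligible = [w for w in windows if w.eligible]
    if not eligible:
        warnings.warn(
            f"no eligible windows for {event_config.kind} events on "
            f"'{event_config.analyte}'; all patterns indeterminate",
            stacklevel=2,
        )
    rx = cohort.prescriptions if prescriptions is None else prescriptions
    results = []
    for drug in drug_list:
        counts = tabulate_window_counts(rx, eligible, drug)
        results.append(compute_pci(cumulate(counts), cutoffs, n_windows=counts.n_windows))
    return results
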