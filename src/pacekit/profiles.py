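"""PCI profiles across event severity and across nominal clinical conditions.

A severity sweep re-runs the full pipeline at each threshold of a strictly
increasing grid (default 4.50 to 7.00 mmol/L in 0.25 steps for serum
potassium), re-evaluating the baseline exclusion at each threshold, and
collects one PCI point per drug per threshold.  A condition profile runs
the pipeline once per nominal condition (before the test order, at the
order, at a negative result, at a positive result) for tests with a
positive/negative outcome.  Each point is an independent full pipeline run,
so any sweep point is identical to the corresponding single-threshold run.

Points supported by fewer than ``min_windows`` pooled windows (default 5)
are still reported but flagged ``low_n``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .core import DEFAULT_CUTOFFS, CutoffConfig, run_pace
from .ehr import CohortData
from .events import EventConfig

__all__ = [
    "ProfilePoint",
    "SeverityProfile",
    "ConditionProfile",
    "DEFAULT_CONDITIONS",
    "default_severity_grid",
    "severity_sweep",
    "condition_profile",
    "export_profile_plot_data",
    "plot_profiles",
]

#: nominal conditions in their clinical order, mapped to event kinds
DEFAULT_CONDITIONS = ("before_order", "order", "result_negative", "result_positive")
_CONDITION_KINDS = {
    "before_order": "before_order",
    "order": "test_order",
    "result_negative": "test_result_negative",
    "result_positive": "test_result_positive",
}


@dataclass(frozen=True)
class ProfilePoint:
    """One sweep point: x is a threshold (float) or a condition label (str)."""

    x: Union[float, str]
    pci: float  # NaN when undefined
    n_windows: int
    pattern: str
    low_n: bool


@dataclass(frozen=True)
class SeverityProfile:
    drug_code: str
    points: tuple[ProfilePoint, ...]


@dataclass(frozen=True)
class ConditionProfile:
    drug_code: str
    points: tuple[ProfilePoint, ...]


def default_severity_grid(
    start: float = 4.50, stop: float = 7.00, step: float = 0.25
) -> tuple[float, ...]:
    """The default potassium severity grid: 4.50..7.00 in 0.25 steps (11 points)."""
    n = int(round((stop - start) / step))
    return tuple(round(start + i * step, 10) for i in range(n + 1))


def severity_sweep(
    cohort: CohortData,
    thresholds: Sequence[float],
    drug_list: Sequence[str],
    event: EventConfig = EventConfig(),
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    min_windows: int = 5,
) -> list[SeverityProfile]:
    """PCI per drug at each event-severity threshold.

    At each threshold ``t`` the pipeline runs with threshold events at
    level ``t``; when ``event.upper_ref`` is None the abnormal-baseline
    exclusion is re-evaluated at ``t`` as well.
    """
    thresholds = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if event.kind != "lab_threshold":
        raise ValueError("severity sweeps require a lab_threshold event definition")
    points: dict[str, list[ProfilePoint]] = {d: [] for d in drug_list}
    import warnings

    for t in thresholds:
        cfg = replace(event, threshold=t)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-window thresholds are expected at the tail
            results = run_pace(cohort, cfg, drug_list, cutoffs)
        for res in results:
            points[res.drug_code].append(
                ProfilePoint(t, res.pci, res.n_windows, res.pattern, res.n_windows < min_windows)
            )
    return [SeverityProfile(d, tuple(points[d])) for d in drug_list]


def condition_profile(
    cohort: CohortData,
    analyte: str,
    drug_list: Sequence[str],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    event: EventConfig | None = None,
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    before_order_days: int = 5,
    min_windows: int = 5,
) -> list[ConditionProfile]:
    """PCI per drug at each nominal clinical condition.

    ``conditions`` is an ordered subset of :data:`DEFAULT_CONDITIONS`; the
    ``before_order`` condition anchors windows ``before_order_days`` days
    before the test order.
    """
    if not conditions:
        raise ValueError("condition set must be non-empty")
    unknown = [c for c in conditions if c not in _CONDITION_KINDS]
    if unknown:
        raise ValueError(f"unknown condition labels: {unknown}; expected {sorted(_CONDITION_KINDS)}")
    base = event if event is not None else EventConfig(analyte=analyte)
    points: dict[str, list[ProfilePoint]] = {d: [] for d in drug_list}
    import warnings

    for cond in conditions:
        cfg = replace(
            base, analyte=analyte, kind=_CONDITION_KINDS[cond], before_order_days=before_order_days
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = run_pace(cohort, cfg, drug_list, cutoffs)
        for res in results:
            points[res.drug_code].append(
                ProfilePoint(cond, res.pci, res.n_windows, res.pattern, res.n_windows < min_windows)
            )
    return [ConditionProfile(d, tuple(points[d])) for d in drug_list]


def export_profile_plot_data(
    profiles: Sequence[Union[SeverityProfile, ConditionProfile]],
) -> pd.DataFrame:
    """Long-format plot table: one row per (drug, x) point.

    Columns: drug_code, x, pci, n_windows, pattern, low_n.  Undefined and
    infinite PCIs are emitted as missing values (never zeros) so plotting
    layers skip them.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rows = []
    for profile in profiles:
        for pt in profile.points:
            pci = pt.pci if np.isfinite(pt.pci) else np.nan
            rows.append((profile.drug_code, pt.x, pci, pt.n_windows, pt.pattern, pt.low_n))
    return pd.DataFrame(rows, columns=["drug_code", "x", "pci", "n_windows", "pattern", "low_n"])


def plot_profiles(
    table: pd.DataFrame,
    path: Union[str, Path],
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    title: str = "PCI profile",
) -> None:
    """Line plot of PCI versus severity/condition per drug, with guide lines
    at the two pattern cut-offs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    xs = list(dict.fromkeys(table["x"]))  # preserve sweep order
    numeric_x = all(isinstance(x, (int, float, np.floating)) for x in xs)
    for drug, sub in table.groupby("drug_code", sort=True):
        x = sub["x"] if numeric_x else [xs.index(v) for v in sub["x"]]
        ax.plot(x, sub["pci"], marker="o", label=drug)
    if not numeric_x:
        ax.set_xticks(range(len(xs)))
        ax.set_xticklabels(xs, rotation=20)
    ax.axhline(cutoffs.lower, color="grey", linestyle="--", linewidth=1)
    ax.axhline(cutoffs.upper, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("event severity" if numeric_x else "clinical condition")
    ax.set_ylabel("PCI")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
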