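"""Model-style front end: a :class:`PACE` model whose :meth:`PACE.fit`
returns a :class:`PACEResults` object.

The model is built from a cohort plus an event definition and a drug panel;
fitting extracts the eligible observation windows once, pools the per-day
prescription counts per drug, and computes the PCI, its pattern, and
(optionally) the binomial-test alternative.  The results object carries the
per-drug table, the window/exclusion diagnostics, a ``summary()`` text
table, and TSV/JSON writers.  Severity sweeps and condition profiles hang
off the model as convenience methods.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__ as _version
from .binomial import binomial_from_counts
from .core import (
    DEFAULT_CUTOFFS,
    CutoffConfig,
    PCIResult,
    compute_pci,
    cumulate,
    tabulate_window_counts,
)
from .ehr import CohortData, read_cohort
from .events import EventConfig, ObservationWindow, extract_windows
from .profiles import condition_profile, severity_sweep

__all__ = ["PACE", "PACEResults"]


def _fmt(x: float, nd: int = 3) -> str:
    """Format a statistic for reporting: 3 decimals, inf/NA spelled out."""
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    if isinstance(x, float) and math.isinf(x):
        return "inf"
    return f"{x:.{nd}f}"


class PACE:
    """Prescription-pattern-around-clinical-event model for one event definition.

    Parameters
    ----------
    cohort : CohortData
        Validated cohort tables.
    drugs : sequence of str
        Drug codes to monitor.
    event : EventConfig
        Event definition (analyte, kind, threshold, exclusions).
    cutoffs : CutoffConfig
        Pattern cut-offs (defaults 0.667 / 1.500).

    Examples
    --------
    >>> model = PACE(cohort, drugs=["C03DA01"], event=EventConfig(threshold=5.5))
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        cohort: CohortData,
        drugs: Sequence[str],
        event: EventConfig = EventConfig(),
        cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    ):
        if not drugs:
            raise ValueError("at least one drug code is required")
        self.cohort = cohort
        self.drugs = list(drugs)
        self.event = event
        self.cutoffs = cutoffs

    @classmethod
    def from_csv(
        cls,
        paths,
        drugs: Sequence[str],
        event: EventConfig = EventConfig(),
        cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
        **read_kwargs,
    ) -> "PACE":
        """Build the model straight from the four delimited-text tables."""
        return cls(read_cohort(paths, **read_kwargs), drugs, event, cutoffs)

    # ------------------------------------------------------------------ fit
    def fit(self, compare_binomial: bool = False, alpha: float = 0.05) -> "PACEResults":
        """Extract windows, pool counts, and compute the per-drug PCI table."""
        windows = extract_windows(self.cohort, self.event)
        eligible = [w for w in windows if w.eligible]
        if not eligible:
            warnings.warn("no eligible windows; all patterns indeterminate", stacklevel=2)
        results: list[PCIResult] = []
        rows = []
        for drug in self.drugs:
            counts = tabulate_window_counts(self.cohort.prescriptions, eligible, drug)
            res = compute_pci(cumulate(counts), self.cutoffs, n_windows=counts.n_windows)
            results.append(res)
            row = {
                "drug_code": res.drug_code,
                "n_windows": res.n_windows,
                "n_prescriptions": res.n_prescriptions,
                "slope_before": res.slope_before,
                "slope_after": res.slope_after,
                "pci": res.pci,
                "pattern": res.pattern,
            }
            if compare_binomial:
                b = binomial_from_counts(counts, alpha=alpha)
                row.update(
                    n_before=b.n_before,
                    n_after=b.n_after,
                    binom_p=b.p_value,
                    binom_pattern=b.pattern,
                )
            rows.append(row)
        frame = pd.DataFrame(rows)
        return PACEResults(self, frame, results, windows)


class PACEResults:
    """Fitted PACE results: per-drug estimates plus window diagnostics.

    Attributes
    ----------
    results : pandas.DataFrame
        One row per drug: counts, slopes, PCI, pattern (and the binomial
        columns when the fit requested them).
    windows : list of ObservationWindow
        Every detected window with its eligibility state.
    exclusion_tally : dict
        Count of windows per exclusion reason.
    """

    def __init__(
        self,
        model: PACE,
        frame: pd.DataFrame,
        pci_results: Sequence[PCIResult],
        windows: Sequence[ObservationWindow],
    ):
        self.model = model
        self.results = frame
        self.pci_results = list(pci_results)
        self.windows = list(windows)

    # ------------------------------------------------------------- diagnostics
    @property
    def n_events(self) -> int:
        return len(self.windows)

    @property
    def n_eligible_windows(self) -> int:
        return sum(1 for w in self.windows if w.eligible)

    @property
    def exclusion_tally(self) -> dict[str, int]:
        tally: dict[str, int] = {}
        for w in self.windows:
            for reason in w.exclusion_reasons:
                tally[reason] = tally.get(reason, 0) + 1
        return tally

    # ------------------------------------------------------------------ output
    def summary(self) -> str:
        ev = self.model.event
        if ev.kind == "lab_threshold":
            event_desc = f"{ev.analyte} > {ev.threshold:g} (lab_threshold)"
        else:
            event_desc = f"{ev.analyte} ({ev.kind})"
        lines = [
            "PACE: Prescription pattern Around Clinical Event",
            "=" * 72,
            f"Event:             {event_desc}",
            f"Windows:           {self.n_eligible_windows} eligible of {self.n_events} detected",
            f"Exclusions:        {self.exclusion_tally or 'none'}",
            f"Cutoffs:           discontinuation <= {self.model.cutoffs.lower:g} < "
            f"maintenance <= {self.model.cutoffs.upper:g} < intervention",
            "-" * 72,
        ]
        header = f"{'drug':<14}{'n_win':>7}{'n_rx':>7}{'slopeA':>9}{'slopeB':>9}{'PCI':>9}  pattern"
        lines.append(header)
        for row in self.results.itertuples():
            lines.append(
                f"{row.drug_code:<14}{row.n_windows:>7}{row.n_prescriptions:>7}"
                f"{_fmt(row.slope_before):>9}{_fmt(row.slope_after):>9}{_fmt(row.pci):>9}"
                f"  {row.pattern}"
            )
        lines.append("=" * 72)
        return "\n".join(lines)

    def _formatted_frame(self) -> pd.DataFrame:
        out = self.results.copy()
        for col in ("slope_before", "slope_after", "pci"):
            out[col] = out[col].map(_fmt)
        if "binom_p" in out.columns:
            out["binom_p"] = out["binom_p"].map(lambda p: f"{p:.4g}")
        return out

    def to_tsv(self, path: Union[str, Path]) -> None:
        """Write the per-drug table as TSV (PCI and slopes to 3 decimals)."""
        self._formatted_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        """JSON mirror of the TSV table plus the window diagnostics."""
        payload = {
            "event": asdict(self.model.event),
            "cutoffs": asdict(self.model.cutoffs),
            "n_events": self.n_events,
            "n_eligible_windows": self.n_eligible_windows,
            "exclusions": self.exclusion_tally,
            "results": self._formatted_frame().to_dict(orient="records"),
            "pacekit_version": _version,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    # -------------------------------------------------------------- profiles
    def severity_sweep(self, thresholds: Sequence[float], min_windows: int = 5):
        """Re-run the fit across an increasing severity grid (see
        :func:`pacekit.profiles.severity_sweep`)."""
        return severity_sweep(
            self.model.cohort,
            thresholds,
            self.model.drugs,
            event=self.model.event,
            cutoffs=self.model.cutoffs,
            min_windows=min_windows,
        )

    def condition_profile(
        self, conditions: Sequence[str], before_order_days: int = 5, min_windows: int = 5
    ):
        """Re-run the fit across nominal clinical conditions (see
        :func:`pacekit.profiles.condition_profile`)."""
        return condition_profile(
            self.model.cohort,
            self.model.event.analyte,
            self.model.drugs,
            conditions=conditions,
            event=self.model.event,
            cutoffs=self.model.cutoffs,
            before_order_days=before_order_days,
            min_windows=min_windows,
        )
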