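"""Per-prescriber patterns and Cohen's-kappa agreement with stated knowledge.

A prescriber's own pattern for a drug is the pooled PCI computed from only
that prescriber's prescriptions written within a lookback period (default
one year before the most recent prescription in the cohort), over the same
hospital-wide eligible windows.  Pairs supported by fewer than a minimum
number of prescriptions (default 10) are omitted as unreliable.

Agreement between the calculated patterns and externally supplied knowledge
labels (e.g. questionnaire answers) is summarized by unweighted Cohen's
kappa over the three pattern categories, with the full confusion table.
Indeterminate calculated patterns are treated as missing, since a stated
label is always one of the three substantive patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .core import DEFAULT_CUTOFFS, CutoffConfig, compute_pci, cumulate, tabulate_window_counts
from .core import PATTERN_CATEGORIES
from .ehr import CohortData
from .events import EventConfig, extract_windows

__all__ = [
    "KnowledgeLabel",
    "PrescriberPattern",
    "KappaResult",
    "pattern_by_prescriber",
    "cohens_kappa",
    "read_knowledge_labels",
    "labels_from_patterns",
]

Key = tuple[str, str]  # (prescriber_id, drug_code)


@dataclass(frozen=True)
class KnowledgeLabel:
    """One externally stated pattern for a (prescriber, drug) pair."""

    prescriber_id: str
    drug_code: str
    stated_pattern: str

    def __post_init__(self):
        if self.stated_pattern not in PATTERN_CATEGORIES:
            raise ValueError(
                f"stated_pattern must be one of {PATTERN_CATEGORIES}, got '{self.stated_pattern}'"
            )


@dataclass(frozen=True)
class PrescriberPattern:
    """Calculated pattern for one prescriber and one drug."""

    prescriber_id: str
    drug_code: str
    pattern: str
    pci: float
    n_prescriptions: int
    n_windows: int


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its components and the 3x3 confusion table.

    ``kappa = (observed - expected) / (1 - expected)``; when expected
    agreement is 1 the statistic is undefined and reported as NaN.
    Rows of ``confusion`` index the first labelling, columns the second.
    """

    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_pairs: int
    confusion: pd.DataFrame

    @property
    def defined(self) -> bool:
        return not math.isnan(self.kappa)


def pattern_by_prescriber(
    cohort: CohortData,
    event_config: EventConfig = EventConfig(),
    drug_list: Sequence[str] = (),
    cutoffs: CutoffConfig = DEFAULT_CUTOFFS,
    min_prescriptions: int = 10,
    lookback_days: int = 365,
    reference_date: pd.Timestamp | None = None,
) -> list[PrescriberPattern]:
    """Pooled PCI per (prescriber, drug) from the prescriber's own orders.

    Windows are extracted once from the whole cohort; for each prescriber
    the pooled counts are taken from that prescriber's prescriptions whose
    administration date lies within ``lookback_days`` of ``reference_date``
    (default: the latest administration date in the cohort).  Pairs with
    fewer than ``min_prescriptions`` prescriptions of the drug inside the
    pooled windows are omitted.
    """
    if not drug_list:
        raise ValueError("drug_list must be non-empty")
    rx = cohort.prescriptions
    if reference_date is None:
        if not len(rx):
            return []
        reference_date = rx["admin_date"].max()
    recent = rx[rx["admin_date"] >= reference_date - pd.Timedelta(days=lookback_days)]

    windows = [w for w in extract_windows(cohort, event_config) if w.eligible]
    out: list[PrescriberPattern] = []
    for prescriber in sorted(set(recent["prescriber_id"]) - {""}):
        own = recent[recent["prescriber_id"] == prescriber]
        for drug in drug_list:
            counts = tabulate_window_counts(own, windows, drug)
            n_rx = sum(counts.counts_by_offset)
            if n_rx < min_prescriptions:
                continue
            res = compute_pci(cumulate(counts), cutoffs, n_windows=counts.n_windows)
            out.append(
                PrescriberPattern(prescriber, drug, res.pattern, res.pci, n_rx, res.n_windows)
            )
    return out


def labels_from_patterns(
    patterns: Iterable[Union[PrescriberPattern, KnowledgeLabel, tuple]],
) -> dict[Key, str]:
    """Normalize patterns/labels/(prescriber, drug, pattern) tuples to a mapping."""
    mapping: dict[Key, str] = {}
    for item in patterns:
        if isinstance(item, PrescriberPattern):
            mapping[(item.prescriber_id, item.drug_code)] = item.pattern
        elif isinstance(item, KnowledgeLabel):
            mapping[(item.prescriber_id, item.drug_code)] = item.stated_pattern
        else:
            prescriber, drug, pattern = item
            mapping[(prescriber, drug)] = pattern
    return mapping


def _as_mapping(labels) -> dict[Key, str]:
    if isinstance(labels, Mapping):
        return dict(labels)
    return labels_from_patterns(labels)


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Unweighted Cohen's kappa between two labelings of (prescriber, drug) pairs.

    Accepts mappings keyed by (prescriber_id, drug_code) or iterables of
    labels/patterns/tuples.  Only keys present in both labelings are
    compared; pairs where either side is indeterminate are dropped.
    """
    a = _as_mapping(labels_a)
    b = _as_mapping(labels_b)
    shared = sorted(
        k
        for k in set(a) & set(b)
        if a[k] in PATTERN_CATEGORIES and b[k] in PATTERN_CATEGORIES
    )
    if not shared:
        raise ValueError("no shared (prescriber_id, drug_code) keys with determinate patterns")
    confusion = pd.DataFrame(
        0, index=list(PATTERN_CATEGORIES), columns=list(PATTERN_CATEGORIES), dtype=int
    )
    for k in shared:
        confusion.at[a[k], b[k]] += 1
    n = len(shared)
    observed = float(sum(confusion.at[c, c] for c in PATTERN_CATEGORIES)) / n
    row = confusion.sum(axis=1) / n
    col = confusion.sum(axis=0) / n
    expected = float((row * col).sum())
    kappa = math.nan if expected >= 1.0 else (observed - expected) / (1.0 - expected)
    return KappaResult(kappa, observed, expected, n, confusion)


def read_knowledge_labels(path: Union[str, Path]) -> list[KnowledgeLabel]:
    """Read a knowledge-label CSV (prescriber_id, drug_code, stated_pattern)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("prescriber_id", "drug_code", "stated_pattern"):
        if col not in df.columns:
            raise ValueError(f"knowledge labels: missing column '{col}'")
    return [
        KnowledgeLabel(row.prescriber_id, row.drug_code, row.stated_pattern.lower())
        for row in df.itertuples()
    ]
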