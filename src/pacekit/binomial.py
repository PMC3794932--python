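"""Binomial-test pattern determination (the LEOPARD-style alternative).

Instead of the PCI ratio, compare the same two-day prescription counts —
n_before on D-3/D-2 and n_after on D0/D+1 — with an exact two-sided
binomial test of n_after successes in n_before + n_after trials against a
success probability of 0.5 (the "minlike" two-sided convention: sum of all
outcome probabilities no larger than that of the observed outcome).  A
significant excess after the event is an intervention pattern, a
significant deficit a discontinuation pattern, and a non-significant
difference a maintenance pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .core import WindowCounts

__all__ = ["BinomialResult", "binomial_pattern", "binomial_from_counts"]


@dataclass(frozen=True)
class BinomialResult:
    """Exact binomial pattern call for one drug."""

    drug_code: str
    n_before: int  # prescriptions on D-3 + D-2
    n_after: int  # prescriptions on D0 + D+1
    p_value: float
    pattern: str
    alpha: float


def binomial_pattern(
    n_before: int, n_after: int, alpha: float = 0.05, drug_code: str = ""
) -> BinomialResult:
    """Classify a before/after count pair with an exact binomial test.

    Zero counts on both sides carry no information and are labelled
    indeterminate (p-value 1).
    """
    if n_before < 0 or n_after < 0:
        raise ValueError(f"counts must be nonnegative, got {n_before}, {n_after}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    n = n_before + n_after
    if n == 0:
        return BinomialResult(drug_code, 0, 0, 1.0, "indeterminate", alpha)
    p_value = float(stats.binomtest(n_after, n, p=0.5, alternative="two-sided").pvalue)
    if p_value < alpha and n_after > n_before:
        pattern = "intervention"
    elif p_value < alpha and n_after < n_before:
        pattern = "discontinuation"
    else:
        pattern = "maintenance"
    return BinomialResult(drug_code, int(n_before), int(n_after), p_value, pattern, alpha)


def binomial_from_counts(counts: WindowCounts, alpha: float = 0.05) -> BinomialResult:
    """Binomial pattern from the same pooled window counts the PCI uses."""
    n_before = counts.count(-3) + counts.count(-2)
    n_after = counts.count(0) + counts.count(1)
    return binomial_pattern(n_before, n_after, alpha=alpha, drug_code=counts.drug_code)
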