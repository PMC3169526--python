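"""Spectrum comparisons and uncertainty estimates.

Mutation spectra of two conditions are compared on the 2x2 collapse
accurate vs mutagenic (targeted + semi-targeted + mixed, including
single-nucleotide deletions) using Pearson's chi-square without continuity
correction, with Fisher's exact test substituted automatically when any
expected cell count falls below 5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .classification import Category, EventClassification

__all__ = [
    "SpectrumComparison",
    "collapse_counts",
    "compare_spectra",
    "bootstrap_ci",
    "replicate_summary",
]

_MUTAGENIC = (Category.TARGETED, Category.SEMI_TARGETED, Category.MIXED)


@dataclass(frozen=True)
class SpectrumComparison:
    """Result of a 2x2 accurate-vs-mutagenic contingency test."""

    table: tuple[tuple[int, int], tuple[int, int]]  # rows: conditions; cols: acc, mut
    statistic: float  # Pearson chi-square statistic (also reported for FISHER)
    p_value: float
    method: str  # "CHI2" | "FISHER"
    expected: tuple[tuple[float, float], tuple[float, float]]


def collapse_counts(counts) -> tuple[int, int]:
    """(accurate, mutagenic) TLS counts from category counts or an event list."""
    if isinstance(counts, (tuple, list)) and len(counts) == 2 and all(
        isinstance(x, (int, np.integer)) for x in counts
    ):
        return int(counts[0]), int(counts[1])
    if isinstance(counts, dict):
        acc = int(counts.get(Category.ACCURATE.value, counts.get(Category.ACCURATE, 0)))
        mut = sum(int(counts.get(c.value, counts.get(c, 0))) for c in _MUTAGENIC)
        return acc, mut
    acc = sum(1 for e in counts if e.category is Category.ACCURATE)
    mut = sum(1 for e in counts if e.category in _MUTAGENIC)
    return acc, mut


def _chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square on a 2x2 table, n(ad-bc)^2 / product of margins."""
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def compare_spectra(a, b, method: str = "auto") -> SpectrumComparison:
    """Compare two conditions' accurate-vs-mutagenic TLS proportions.

    ``a`` and ``b`` may each be an (accurate, mutagenic) pair, a category
    count mapping, or a list of event classifications.  ``method`` is
    ``"chi2"``, ``"fisher"`` or ``"auto"`` (chi-square unless an expected
    count is below 5).  The comparison is symmetric in argument order and
    in the accurate/mutagenic column order.
    """
    (a_acc, a_mut), (b_acc, b_mut) = collapse_counts(a), collapse_counts(b)
    if a_acc + a_mut == 0 or b_acc + b_mut == 0:
        raise ValueError("compare_spectra: a condition has no TLS events")
    table = np.array([[a_acc, a_mut], [b_acc, b_mut]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    stat = _chi2_2x2(a_acc, a_mut, b_acc, b_mut)

    if method not in ("auto", "chi2", "fisher"):
        raise ValueError(f"unknown method {method!r}")
    use_fisher = method == "fisher" or (method == "auto" and expected.min() < 5)
    if use_fisher:
        _, p = sps.fisher_exact(table.astype(int), alternative="two-sided")
        chosen = "FISHER"
    else:
        p = float(sps.chi2.sf(stat, df=1))
        chosen = "CHI2"
    p = min(max(float(p), np.nextafter(0, 1)), 1.0)
    return SpectrumComparison(
        table=((a_acc, a_mut), (b_acc, b_mut)),
        statistic=stat,
        p_value=p,
        method=chosen,
        expected=tuple(map(tuple, expected)),
    )


def bootstrap_ci(
    values,
    B: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
    statistic=np.mean,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for a statistic of i.i.d. values.

    ``values`` may be numeric (e.g. per-replicate extents) or boolean clone
    labels, in which case the default statistic gives a proportion.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("bootstrap_ci: need at least 2 one-dimensional values")
    if B < 100:
        raise ValueError("bootstrap_ci: B must be at least 100")
    if not 0 < level < 1:
        raise ValueError("bootstrap_ci: level must be in (0, 1)")
    if seed is None:
        raise ValueError("bootstrap_ci: seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(B, arr.size))
    reps = statistic(arr[idx], axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(reps, [alpha, 1 - alpha])
    return float(lo), float(hi)


def replicate_summary(values) -> tuple[float, float, int]:
    """(mean, sample SD, n); SD is NaN (flagged undefined) when n = 1."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("replicate_summary: need a non-empty 1-d input")
    n = int(arr.size)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else math.nan
    return mean, sd, n
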