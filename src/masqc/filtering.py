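"""Per-feature cutoffs and peak intersection building the conservative 6mA set.

False-positive control starts from the observation that MeDIP-seq peak
regions are conservative and reliable, whereas individual SMRT kinetics
calls are noisy.  The pipeline therefore applies strict cutoffs to both
sides — peaks must reach fold enrichment >= 1 and -log10(q) >= 2, calls
must reach coverage >= 50, modification QV >= 30 and methylated
fraction >= 0.7 — and intersects the survivors.  Calls passing both
gates form the *conservative set*, treated downstream as close to fully
true and used to sample IPD ratios for the threshold.

All cutoff comparisons are inclusive (>=).  Peak membership uses the
half-open convention: a call whose 0-based position equals a peak's end
coordinate is outside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import ModificationCall, Peak

__all__ = [
    "ConservativeSet",
    "STRICT_CALL_CUTOFFS",
    "STRICT_PEAK_CUTOFFS",
    "BASIC_CALL_CUTOFFS",
    "filter_peaks",
    "filter_calls",
    "dedupe_calls",
    "drop_low_coverage_chromosomes",
    "intersect_calls_peaks",
    "build_conservative_set",
]

#: Strict call cutoffs used to build the conservative set.
STRICT_CALL_CUTOFFS = {"min_coverage": 50, "min_score": 30.0, "min_fraction": 0.7}
#: Strict peak cutoffs (fold enrichment, -log10 q-value).
STRICT_PEAK_CUTOFFS = {"min_enrichment": 1.0, "min_neglog10q": 2.0}
#: Basic genome-wide call filter (coverage only) applied before thresholding.
BASIC_CALL_CUTOFFS = {"min_coverage": 50, "min_score": 0.0, "min_fraction": None}


@dataclass
class ConservativeSet:
    """Calls passing strict filters that lie inside strictly-filtered peaks."""

    calls: list[ModificationCall]
    peaks: list[Peak]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.calls)

    def ipd_ratios(self) -> np.ndarray:
        return np.array([c.ipd_ratio for c in self.calls], dtype=float)


def filter_peaks(
    peaks: Iterable[Peak],
    min_enrichment: float = 1.0,
    min_neglog10q: float = 2.0,
) -> list[Peak]:
    """Keep peaks with enrichment >= ``min_enrichment`` and
    -log10(q) >= ``min_neglog10q`` (both inclusive), preserving order."""
    if min_enrichment < 0 or min_neglog10q < 0:
        raise ValueError("peak cutoffs must be non-negative")
    return [
        p
        for p in peaks
        if p.enrichment >= min_enrichment and p.neg_log10_q >= min_neglog10q
    ]


def filter_calls(
    calls: Iterable[ModificationCall],
    min_coverage: int = 50,
    min_score: float = 0.0,
    min_fraction: float | None = None,
) -> list[ModificationCall]:
    """Keep calls meeting every supplied cutoff (inclusive comparisons).

    A call with an absent ``fraction`` fails any finite ``min_fraction``.
    """
    if min_fraction is not None and not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must lie in [0, 1], got {min_fraction}")
    kept = []
    for c in calls:
        if c.coverage < min_coverage or c.score < min_score:
            continue
        if min_fraction is not None and (
            c.fraction is None or c.fraction < min_fraction
        ):
            continue
        kept.append(c)
    return kept


def dedupe_calls(calls: Sequence[ModificationCall]) -> list[ModificationCall]:
    """Collapse duplicate (chrom, position, strand) calls, keeping the first.

    Duplicates would double-count in every downstream proportion, so a
    warning is emitted when any are found.
    """
    seen: set[tuple[str, int, str]] = set()
    unique: list[ModificationCall] = []
    for c in calls:
        key = (c.chrom, c.position, c.strand)
        if key in seen:
            continue
        seen.add(key)
        unique.append(c)
    dropped = len(calls) - len(unique)
    if dropped:
        warnings.warn(
            f"collapsed {dropped} duplicate call(s) with identical "
            f"(chrom, position, strand)",
            stacklevel=2,
        )
    return unique


def drop_low_coverage_chromosomes(
    calls: Sequence[ModificationCall], min_mean_coverage: float = 50.0
) -> list[ModificationCall]:
    """Alternative coverage policy: drop every call on chromosomes whose
    mean call coverage falls below ``min_mean_coverage``.

    The default pipeline reads the coverage rule per site; this variant
    implements the per-chromosome reading for users who prefer it.
    """
    totals: dict[str, list[int]] = {}
    for c in calls:
        totals.setdefault(c.chrom, []).append(c.coverage)
    keep = {
        chrom for chrom, covs in totals.items() if np.mean(covs) >= min_mean_coverage
    }
    return [c for c in calls if c.chrom in keep]


def intersect_calls_peaks(
    calls: Sequence[ModificationCall], peaks: Sequence[Peak]
) -> ConservativeSet:
    """Calls whose position lies inside at least one peak on the same
    chromosome (peak strand ignored — MeDIP peaks are unstranded).

    Membership is half-open: 1-based position ``p`` is inside ``[start,
    end)`` iff ``start <= p-1 < end``.  A call covered by several peaks
    appears once; input order is preserved.
    """
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    inside = [
        c
        for c in calls
        if c.chrom in trees and trees[c.chrom].overlaps_point(c.position - 1)
    ]
    return ConservativeSet(
        calls=inside,
        peaks=list(peaks),
        provenance={"n_calls_in": len(calls), "n_peaks": len(peaks)},
    )


def build_conservative_set(
    calls: Sequence[ModificationCall],
    peaks: Sequence[Peak],
    min_coverage: int = 50,
    min_score: float = 30.0,
    min_fraction: float | None = 0.7,
    min_enrichment: float = 1.0,
    min_neglog10q: float = 2.0,
    deduplicate: bool = True,
) -> ConservativeSet:
    """Strictly filter peaks and calls, then intersect the survivors.

    Composition ``filter_peaks -> filter_calls -> intersect_calls_peaks``;
    every cutoff applied is recorded in the result's provenance.
    """
    if deduplicate:
        calls = dedupe_calls(calls)
    strict_peaks = filter_peaks(
        peaks, min_enrichment=min_enrichment, min_neglog10q=min_neglog10q
    )
    strict_calls = filter_calls(
        calls,
        min_coverage=min_coverage,
        min_score=min_score,
        min_fraction=min_fraction,
    )
    result = intersect_calls_peaks(strict_calls, strict_peaks)
    result.provenance = {
        "min_coverage": min_coverage,
        "min_score": min_score,
        "min_fraction": min_fraction,
        "min_enrichment": min_enrichment,
        "min_neglog10q": min_neglog10q,
        "n_calls_in": len(calls),
        "n_calls_strict": len(strict_calls),
        "n_peaks_in": len(peaks),
        "n_peaks_strict": len(strict_peaks),
        "n_conservative": len(result.calls),
    }
    return result
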