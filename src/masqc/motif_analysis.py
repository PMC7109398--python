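"""IUPAC motif scanning and motif-based evaluation statistics.

Methylation in prokaryotes is driven by restriction–modification systems
and lands almost exclusively (>95%) on short degenerate motifs such as
GATC, whereas eukaryotic 6mA is only weakly motif driven (<3% of calls on
motifs).  The share of calls sitting on known motifs therefore serves as
an external yardstick for filtering quality: a good false-positive filter
raises the motif proportion and lowers the non-motif proportion.

Four analysis states are compared: the raw call set ("PacBio"), the calls
inside strictly-filtered MeDIP peaks ("PacBio+MeDIP"), the calls passing
the IPD-ratio threshold ("PacBio+threshold") and both ("PacBio+MeDIP+
threshold").  For a single motif with m calls out of N in a state the
proportion is m/N (P1..P4 over the four states).  For all motifs together
(M calls on any motif out of N):

    I = M_thr/N_thr - M/N                       (increase of motif share)
    D = (1 - M/N) - (N_thr - M_thr)/N           (decrease of non-motif share)

where the "_thr" quantities refer to the thresholded state.  D*N equals
the number of non-motif calls the threshold removed — an algebraic
identity used as a cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import (
    A_COMPATIBLE,
    IUPAC_COMPLEMENT,
    IUPAC_SETS,
    GenomeSequence,
    ModificationCall,
    MotifSpec,
)

__all__ = [
    "STATES",
    "MotifOccurrence",
    "MotifProportionReport",
    "reverse_complement_pattern",
    "scan_motifs",
    "classify_calls",
    "compute_state_proportions",
    "compute_increase_decrease",
    "filtered_composition",
]

#: Canonical order of the four analysis states.
STATES = ("PacBio", "PacBio+MeDIP", "PacBio+threshold", "PacBio+MeDIP+threshold")

_BASE_BITS = np.zeros(256, dtype=np.uint8)
for _base, _bit in zip(b"ACGT", (1, 2, 4, 8)):
    _BASE_BITS[_base] = _bit

_CODE_MASK = {
    code: int(sum(_BASE_BITS[ord(b)] for b in bases))
    for code, bases in IUPAC_SETS.items()
}


@dataclass(frozen=True)
class MotifOccurrence:
    """One located instance of a motif on a genome strand.

    ``start``/``end`` are 0-based half-open on the forward sequence
    regardless of strand.  ``adenine_positions`` holds the 1-based
    reference coordinates inside the occurrence where a methylated A on
    that strand is possible: positions whose pattern character is
    A-compatible and whose reference base is A (+ strand) or T (- strand).
    """

    motif_name: str
    chrom: str
    start: int
    end: int
    strand: str
    adenine_positions: tuple[int, ...]


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC degenerate pattern (VATB -> VATB)."""
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern))


def _encode(seq: str) -> np.ndarray:
    """Sequence to base bitmasks (A=1, C=2, G=4, T=8, N and others = 0).

    An N in the reference matches no IUPAC code, including N itself.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_BITS[raw]


def _match_starts(bits: np.ndarray, pattern: str) -> np.ndarray:
    """0-based start positions where the pattern matches the encoded sequence."""
    width = bits.size - len(pattern) + 1
    if width <= 0:
        return np.empty(0, dtype=np.intp)
    ok = np.ones(width, dtype=bool)
    for j, code in enumerate(pattern):
        window = bits[j : j + width]
        mask = _CODE_MASK[code]
        ok &= (window != 0) & ((window & mask) == window)
    return np.flatnonzero(ok)


def _adenine_positions(
    seq: str, start: int, strand: str, motif: MotifSpec
) -> tuple[int, ...]:
    length = len(motif.pattern)
    offsets: Iterable[int]
    if motif.methylated_offset == "any":
        offsets = range(length)
    else:
        offsets = (motif.methylated_offset,)
    positions = []
    for j in offsets:
        if motif.pattern[j] not in A_COMPATIBLE:
            continue
        if strand == "+":
            idx = start + j
            if seq[idx] == "A":
                positions.append(idx + 1)
        else:
            # pattern index j reads 3'->5' on the forward sequence
            idx = start + length - 1 - j
            if seq[idx] == "T":
                positions.append(idx + 1)
    return tuple(sorted(positions))


def scan_motifs(
    genome: GenomeSequence, motifs: Sequence[MotifSpec]
) -> list[MotifOccurrence]:
    """Locate every occurrence of each motif on both strands.

    Minus-strand occurrences are found by matching the reverse complement
    of the pattern on the forward sequence; overlapping and
    self-overlapping occurrences are all reported.  A motif longer than a
    chromosome simply yields no occurrences.
    """
    occurrences: list[MotifOccurrence] = []
    for chrom, seq in genome.sequences.items():
        bits = _encode(seq)
        for motif in motifs:
            length = len(motif.pattern)
            for start in _match_starts(bits, motif.pattern):
                occurrences.append(
                    MotifOccurrence(
                        motif_name=motif.name,
                        chrom=chrom,
                        start=int(start),
                        end=int(start) + length,
                        strand="+",
                        adenine_positions=_adenine_positions(
                            seq, int(start), "+", motif
                        ),
                    )
                )
            for start in _match_starts(bits, reverse_complement_pattern(motif.pattern)):
                occurrences.append(
                    MotifOccurrence(
                        motif_name=motif.name,
                        chrom=chrom,
                        start=int(start),
                        end=int(start) + length,
                        strand="-",
                        adenine_positions=_adenine_positions(
                            seq, int(start), "-", motif
                        ),
                    )
                )
    return occurrences


def classify_calls(
    calls: Sequence[ModificationCall], occurrences: Sequence[MotifOccurrence]
) -> list[frozenset[str]]:
    """Label each call with the motifs whose methylatable adenine it hits.

    A call is "on motif" iff its (chromosome, position, strand) coincides
    with an adenine position of an occurrence on the same strand.  A call
    hit by several motifs carries all their names (it still counts once in
    the total-motif count M).  The empty set means non-motif.
    """
    index: dict[tuple[str, str, int], set[str]] = {}
    for occ in occurrences:
        for pos in occ.adenine_positions:
            index.setdefault((occ.chrom, occ.strand, pos), set()).add(occ.motif_name)
    return [
        frozenset(index.get((c.chrom, c.strand, c.position), ())) for c in calls
    ]


@dataclass
class MotifProportionReport:
    """Per-motif and total-motif proportions over the four analysis states.

    ``per_motif`` columns: motif, state, m, N, proportion (NaN when the
    state is empty — an undefined ratio is never coerced to 0).
    ``totals`` columns: state, M, N, proportion.
    """

    per_motif: pd.DataFrame
    totals: pd.DataFrame

    def proportion(self, motif: str, state: str) -> float:
        rows = self.per_motif
        hit = rows[(rows["motif"] == motif) & (rows["state"] == state)]
        if hit.empty:
            raise KeyError(f"no entry for motif {motif!r} in state {state!r}")
        return float(hit["proportion"].iloc[0])

    def total_proportion(self, state: str) -> float:
        hit = self.totals[self.totals["state"] == state]
        if hit.empty:
            raise KeyError(f"no totals entry for state {state!r}")
        return float(hit["proportion"].iloc[0])


def compute_state_proportions(
    state_labels: Mapping[str, Sequence[frozenset[str]]],
    motif_names: Sequence[str] | None = None,
) -> MotifProportionReport:
    """Per-motif (m/N) and total-motif (M/N) proportions for each state.

    ``state_labels`` maps a state name to the per-call label sets of that
    state (as returned by :func:`classify_calls`).  The "PacBio" state
    must be present and non-empty; each other state should be a subset of
    it (the caller guarantees this by construction).  Empty states yield
    NaN proportions.
    """
    if "PacBio" not in state_labels or len(state_labels["PacBio"]) == 0:
        raise ValueError("the 'PacBio' state must be present and non-empty")
    if motif_names is None:
        names: list[str] = []
        for labels in state_labels.values():
            for label in labels:
                for name in sorted(label):
                    if name not in names:
                        names.append(name)
        motif_names = names
    per_motif_rows = []
    totals_rows = []
    for state, labels in state_labels.items():
        n_state = len(labels)
        m_total = sum(1 for label in labels if label)
        for name in motif_names:
            m = sum(1 for label in labels if name in label)
            per_motif_rows.append(
                {
                    "motif": name,
                    "state": state,
                    "m": m,
                    "N": n_state,
                    "proportion": (m / n_state) if n_state else float("nan"),
                }
            )
        totals_rows.append(
            {
                "state": state,
                "M": m_total,
                "N": n_state,
                "proportion": (m_total / n_state) if n_state else float("nan"),
            }
        )
    return MotifProportionReport(
        per_motif=pd.DataFrame(per_motif_rows),
        totals=pd.DataFrame(totals_rows),
    )


def compute_increase_decrease(
    n_total: int, m_total: int, n_thr: int, m_thr: int
) -> tuple[float | None, float]:
    """Increase I and decrease D of the total-motif share under thresholding.

    ``I = m_thr/n_thr - m_total/n_total`` (None when the thresholded state
    is empty) and ``D = (1 - m_total/n_total) - (n_thr - m_thr)/n_total``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= m_total <= n_total:
        raise ValueError("m_total must lie in [0, n_total]")
    if not 0 <= n_thr <= n_total:
        raise ValueError("n_thr must lie in [0, n_total]")
    if not 0 <= m_thr <= min(m_total, n_thr):
        raise ValueError("m_thr must lie in [0, min(m_total, n_thr)]")
    increase = None if n_thr == 0 else m_thr / n_thr - m_total / n_total
    decrease = (1.0 - m_total / n_total) - (n_thr - m_thr) / n_total
    return increase, decrease


def filtered_composition(
    removed_labels: Sequence[frozenset[str]],
) -> tuple[float, float] | None:
    """Motif vs non-motif proportions among threshold-removed calls.

    Returns ``(motif_proportion, non_motif_proportion)`` summing to 1, or
    None for an empty removed set (undefined, not zero).
    """
    n = len(removed_labels)
    if n == 0:
        return None
    on_motif = sum(1 for label in removed_labels if label)
    return on_motif / n, (n - on_motif) / n
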