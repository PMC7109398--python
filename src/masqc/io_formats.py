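"""Readers and writers for the file formats around 6mA quality control.

The pipeline touches four external formats:

* reference genome — multi-record FASTA;
* SMRT base-modification calls — either the GFF3 dialect written by the
  PacBio modification-detection step (score column = modification QV,
  attributes carry ``coverage``, ``IPDRatio`` and optionally ``frac``) or a
  flat CSV with columns ``tpl, strand, score, ipdRatio, coverage[, frac,
  base]``;
* MeDIP-seq peaks — MACS2 narrowPeak (BED6+4, ten tab-separated columns);
* methylation motifs — a small TSV of IUPAC degenerate patterns.

Coordinate conventions are kept bit-faithful to each source format:
modification calls carry 1-based positions (GFF-native), peaks carry
0-based half-open intervals (BED-native).  A 1-based position ``p``
corresponds to the 0-based half-open interval ``[p-1, p)``.

Two Phred-type transforms recur throughout: the modification score is
``QV = -10*log10(p)`` (QV 20 <-> p=0.01, QV 30 <-> p=0.001) and the
narrowPeak ``qValue`` column is ``-log10(q)`` (1.3 <-> q=0.05, 2 <-> q=0.01).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomeSequence",
    "ModificationCall",
    "Peak",
    "MotifSpec",
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "A_COMPATIBLE",
    "read_fasta",
    "write_fasta",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_modifications_gff",
    "read_modifications_csv",
    "read_motifs",
    "write_calls",
    "qv_to_pvalue",
    "pvalue_to_qv",
    "qvalue_to_neglog10",
    "neglog10_to_qvalue",
    "to_zero_based",
    "to_one_based",
]


class FormatError(ValueError):
    """An input file violates its declared format."""


# --------------------------------------------------------------------------
# IUPAC degenerate nucleotide alphabet
# --------------------------------------------------------------------------

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: IUPAC codes whose base set contains adenine.
A_COMPATIBLE: frozenset[str] = frozenset("ARWMDHVN")


# --------------------------------------------------------------------------
# Phred-type score / q-value transforms
# --------------------------------------------------------------------------

def qv_to_pvalue(qv: float) -> float:
    """p-value corresponding to a Phred-type modification QV (QV 30 -> 0.001)."""
    return 10.0 ** (-qv / 10.0)


def pvalue_to_qv(p: float) -> float:
    """Phred-type modification QV for a p-value: ``-10*log10(p)``."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return -10.0 * math.log10(p)


def qvalue_to_neglog10(q: float) -> float:
    """``-log10(q)``, the transform MACS2 applies to the narrowPeak q-value."""
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q-value must be in (0, 1], got {q}")
    return -math.log10(q)


def neglog10_to_qvalue(x: float) -> float:
    """Inverse of :func:`qvalue_to_neglog10`."""
    return 10.0 ** (-x)


def to_zero_based(position: int) -> int:
    """1-based position -> start of its 0-based half-open single-base interval."""
    return position - 1


def to_one_based(start: int) -> int:
    """0-based interval start -> 1-based position of that base."""
    return start + 1


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class GenomeSequence:
    """A reference genome held in memory as uppercase A/C/G/T/N strings."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        allowed = set("ACGTN")
        for name, seq in self.sequences.items():
            if not name:
                raise FormatError("empty chromosome identifier")
            if not set(seq) <= allowed:
                bad = sorted(set(seq) - allowed)
                raise FormatError(
                    f"chromosome {name!r} contains non-A/C/G/T/N characters: {bad}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __iter__(self):
        return iter(self.sequences)


@dataclass
class ModificationCall:
    """One putative 6mA site with its SMRT kinetics features.

    ``position`` is the 1-based reference coordinate of the called adenine;
    ``ipd_ratio`` is the observed/expected inter-pulse duration ratio;
    ``score`` is the Phred-type modification QV; ``fraction`` is the
    estimated methylated fraction of reads (absent in low-coverage calls).
    """

    chrom: str
    position: int
    strand: str
    ipd_ratio: float
    coverage: int
    score: float
    fraction: float | None = None
    mod_type: str = "m6A"
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ipd_ratio > 0:
            raise ValueError(f"ipd_ratio must be > 0, got {self.ipd_ratio}")
        if self.coverage < 0:
            raise ValueError(f"coverage must be >= 0, got {self.coverage}")
        if self.score < 0:
            raise ValueError(f"score must be >= 0, got {self.score}")
        if self.fraction is not None and not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction must lie in [0, 1], got {self.fraction}")


@dataclass
class Peak:
    """One MeDIP-seq enriched interval (narrowPeak record, 0-based half-open).

    ``enrichment`` is the MACS2 fold enrichment (signalValue column) and
    ``neg_log10_q`` the -log10-transformed q-value (qValue column).
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    display_score: int = 0
    strand: str = "."
    enrichment: float = 0.0
    neg_log10_p: float = 0.0
    neg_log10_q: float = 0.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"peak start must be < end, got [{self.start}, {self.end})"
            )
        if self.enrichment < 0:
            raise ValueError(f"enrichment must be >= 0, got {self.enrichment}")
        if self.neg_log10_q < 0:
            raise ValueError(f"neg_log10_q must be >= 0, got {self.neg_log10_q}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_position(self, position: int) -> bool:
        """Whether a 1-based position falls inside this half-open interval."""
        return self.start <= position - 1 < self.end


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC degenerate methylation motif.

    ``methylated_offset`` is the 0-based index of the methylated adenine
    within the pattern, or ``"any"`` to allow every A-compatible pattern
    position (e.g. for motifs like VATB where the methylated position is
    not pinned down).
    """

    name: str
    pattern: str
    methylated_offset: Union[int, str] = "any"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("motif pattern must be non-empty")
        bad = sorted(set(self.pattern) - set(IUPAC_SETS))
        if bad:
            raise ValueError(
                f"motif {self.name!r}: non-IUPAC characters {bad} in pattern "
                f"{self.pattern!r}"
            )
        off = self.methylated_offset
        if off != "any":
            if not isinstance(off, int) or not 0 <= off < len(self.pattern):
                raise ValueError(
                    f"motif {self.name!r}: methylated_offset {off!r} outside "
                    f"pattern of length {len(self.pattern)}"
                )
            if self.pattern[off] not in A_COMPATIBLE:
                raise ValueError(
                    f"motif {self.name!r}: pattern position {off} "
                    f"({self.pattern[off]!r}) is not compatible with adenine"
                )


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

_NON_ACGTN = re.compile(r"[^ACGTN]")


def read_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file, uppercasing and mapping ambiguity codes to N."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate record identifier {rec.id!r}")
        seq = _NON_ACGTN.sub("N", str(rec.seq).upper())
        sequences[rec.id] = seq
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# narrowPeak (BED6+4)
# --------------------------------------------------------------------------

def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Parse a MACS2 narrowPeak file (10 tab-separated columns, no header).

    Parsing is strictly column-position-based: columns 7, 8 and 9 are fold
    enrichment, -log10(p) and -log10(q) in that order.
    """
    path = Path(path)
    peaks: list[Peak] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("track", "browser", "#")):
                continue
            cols = stripped.split("\t")
            if len(cols) != 10:
                raise FormatError(
                    f"{path}: line {lineno}: expected 10 narrowPeak columns, "
                    f"got {len(cols)}"
                )
            try:
                peak = Peak(
                    chrom=cols[0],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    name=cols[3],
                    display_score=int(float(cols[4])),
                    strand=cols[5],
                    enrichment=float(cols[6]),
                    neg_log10_p=float(cols[7]),
                    neg_log10_q=float(cols[8]),
                    summit_offset=int(cols[9]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            peaks.append(peak)
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    (
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(p.display_score),
                        p.strand,
                        _fmt_num(p.enrichment),
                        _fmt_num(p.neg_log10_p),
                        _fmt_num(p.neg_log10_q),
                        str(p.summit_offset),
                    )
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# Modification calls: GFF dialect
# --------------------------------------------------------------------------

_CORE_ATTRS = ("coverage", "IPDRatio", "frac")


def read_modifications_gff(
    path: str | Path, restrict_type: str | None = "m6A"
) -> list[ModificationCall]:
    """Parse the GFF3 dialect written by the PacBio modification caller.

    Column 3 holds the modification type, columns 4 and 5 the 1-based
    position, column 6 the modification QV, column 7 the strand; the
    attribute column carries ``coverage``, ``IPDRatio`` and optionally
    ``frac``.  Records whose type differs from ``restrict_type`` are
    skipped; pass ``restrict_type=None`` to keep every record (including
    generic ``modified_base`` calls).  Unrecognised attributes are kept
    verbatim so a write/read cycle does not destroy upstream metadata.
    """
    path = Path(path)
    calls: list[ModificationCall] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            cols = stripped.split("\t")
            if len(cols) < 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 GFF columns, got {len(cols)}"
                )
            mod_type = cols[2]
            if restrict_type is not None and mod_type != restrict_type:
                continue
            attrs: dict[str, str] = {}
            for item in cols[8].split(";"):
                item = item.strip()
                if not item:
                    continue
                if "=" not in item:
                    raise FormatError(
                        f"{path}: line {lineno}: malformed attribute {item!r}"
                    )
                key, value = item.split("=", 1)
                attrs[key] = value
            for required in ("IPDRatio", "coverage"):
                if required not in attrs:
                    raise FormatError(
                        f"{path}: line {lineno}: missing required attribute "
                        f"{required!r}"
                    )
            try:
                ipd_ratio = float(attrs.pop("IPDRatio"))
                coverage = int(float(attrs.pop("coverage")))
                fraction = float(attrs.pop("frac")) if "frac" in attrs else None
                call = ModificationCall(
                    chrom=cols[0],
                    position=int(cols[3]),
                    strand=cols[6],
                    ipd_ratio=ipd_ratio,
                    coverage=coverage,
                    score=float(cols[5]),
                    fraction=fraction,
                    mod_type=mod_type,
                    attributes=attrs,
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            calls.append(call)
    return calls


# --------------------------------------------------------------------------
# Modification calls: flat CSV dialect
# --------------------------------------------------------------------------

def read_modifications_csv(path: str | Path) -> list[ModificationCall]:
    """Parse the flat CSV dialect of the modification caller output.

    ``tpl`` is the 1-based template position; ``strand`` 0 maps to "+" and
    1 to "-".  When a ``base`` column is present only adenine rows are kept
    (6mA analysis).
    """
    import pandas as pd

    path = Path(path)
    table = pd.read_csv(path)
    required = {"tpl", "strand", "score", "ipdRatio", "coverage"}
    missing = sorted(required - set(table.columns))
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    if "base" in table.columns:
        table = table[table["base"].astype(str).str.upper() == "A"]
    has_frac = "frac" in table.columns
    has_ref = "refName" in table.columns
    strand_map = {0: "+", 1: "-"}
    calls: list[ModificationCall] = []
    for row in table.itertuples(index=False):
        strand_code = int(getattr(row, "strand"))
        if strand_code not in strand_map:
            raise FormatError(
                f"{path}: strand must be 0 (+) or 1 (-), got {strand_code}"
            )
        frac = getattr(row, "frac") if has_frac else None
        if frac is not None and (frac != frac):  # NaN
            frac = None
        calls.append(
            ModificationCall(
                chrom=str(getattr(row, "refName")) if has_ref else "ref000001",
                position=int(getattr(row, "tpl")),
                strand=strand_map[strand_code],
                ipd_ratio=float(getattr(row, "ipdRatio")),
                coverage=int(getattr(row, "coverage")),
                score=float(getattr(row, "score")),
                fraction=None if frac is None else float(frac),
            )
        )
    return calls


# --------------------------------------------------------------------------
# Motif lists
# --------------------------------------------------------------------------

def read_motifs(path: str | Path) -> list[MotifSpec]:
    """Read a motif TSV: ``name<TAB>pattern[<TAB>methylated_offset]``.

    ``methylated_offset`` is a 0-based integer index or the word ``any``
    (the default when the column is absent).
    """
    path = Path(path)
    motifs: list[MotifSpec] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            cols = stripped.split("\t")
            if len(cols) not in (2, 3):
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(cols)}"
                )
            offset: Union[int, str] = "any"
            if len(cols) == 3 and cols[2] != "any":
                try:
                    offset = int(cols[2])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: methylated_offset must be an "
                        f"integer or 'any', got {cols[2]!r}"
                    ) from exc
            try:
                motifs.append(MotifSpec(cols[0], cols[1].upper(), offset))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return motifs


# --------------------------------------------------------------------------
# Output
# --------------------------------------------------------------------------

def _fmt_num(x: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    if isinstance(x, int):
        return str(x)
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_calls(
    calls: Sequence[ModificationCall], path: str | Path, format: str = "gff"
) -> None:
    """Write calls as the modification GFF dialect or as single-base BED6.

    GFF output round-trips losslessly through :func:`read_modifications_gff`
    for every modeled field; BED intervals are 0-based half-open.
    """
    path = Path(path)
    if format == "gff":
        with path.open("w") as fh:
            fh.write("##gff-version 3\n")
            for c in calls:
                attrs = [
                    f"coverage={c.coverage}",
                    f"IPDRatio={_fmt_num(c.ipd_ratio)}",
                ]
                if c.fraction is not None:
                    attrs.append(f"frac={_fmt_num(c.fraction)}")
                attrs.extend(f"{k}={v}" for k, v in c.attributes.items())
                fh.write(
                    "\t".join(
                        (
                            c.chrom,
                            "kinModCall",
                            c.mod_type,
                            str(c.position),
                            str(c.position),
                            _fmt_num(c.score),
                            c.strand,
                            ".",
                            ";".join(attrs),
                        )
                    )
                    + "\n"
                )
    elif format == "bed":
        with path.open("w") as fh:
            for c in calls:
                score = int(round(min(max(c.score, 0.0), 1000.0)))
                fh.write(
                    "\t".join(
                        (
                            c.chrom,
                            str(to_zero_based(c.position)),
                            str(c.position),
                            c.mod_type,
                            str(score),
                            c.strand,
                        )
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown output format {format!r} (use 'gff' or 'bed')")
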