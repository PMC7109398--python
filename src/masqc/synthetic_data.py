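"""Synthetic genomes, 6mA call tables and MeDIP peak tracks with ground truth.

Real inputs to the pipeline are multi-gigabyte sequencing runs; this
module emulates their statistical structure at desk scale so every stage
can be exercised and validated against a known truth.  Two regimes are
provided:

* ``prokaryote-like`` — methylation driven by restriction–modification
  systems: ~95% of true 6mA calls sit on a short motif (default GATC,
  methylated at the A, both strands as for Dam methylase);
* ``eukaryote-like`` — weakly motif driven: ~2% of true calls sit on a
  degenerate motif (default VATB) and false positives dominate the raw
  call table.

True calls draw IPD ratios from a high component (default N(5.0, 0.5^2),
truncated positive), false calls from a low component (N(1.8, 0.4^2)).
Coverage is negative-binomial, methylated fraction Beta-distributed with
most true-call mass above the 0.7 cutoff, and the modification QV is a
monotone function of IPD elevation and coverage so that true calls pass
the strict score cutoff and false calls generally do not.  Peaks of
configurable width are laid over the true sites (plus failing decoy
peaks elsewhere) so that the strict peak filter recovers the truly
methylated regions.

Everything is driven by a single mandatory seed; a given configuration
reproduces its dataset byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import (
    IUPAC_SETS,
    GenomeSequence,
    ModificationCall,
    MotifSpec,
    Peak,
    write_calls,
    write_fasta,
    write_narrowpeak,
)
from .motif_analysis import scan_motifs

__all__ = [
    "SimulationConfig",
    "generate_genome",
    "plant_motifs_and_calls",
    "simulate_peaks",
    "simulate_dataset",
    "read_truth",
]

REGIMES = ("prokaryote-like", "eukaryote-like")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset (seed is mandatory)."""

    seed: int
    genome_length: int = 100_000
    gc_content: float = 0.45
    chrom_name: str = "chrSim"
    regime: str = "prokaryote-like"
    motifs: tuple[MotifSpec, ...] = (MotifSpec("GATC", "GATC", 1),)
    planted_copies: tuple[int, ...] = (250,)
    n_true: int = 1000
    on_motif_fraction: float = 0.95
    n_false: int = 400
    true_ipd_mean: float = 5.0
    true_ipd_sd: float = 0.5
    false_ipd_mean: float = 1.8
    false_ipd_sd: float = 0.4
    coverage_mean: float = 80.0
    coverage_dispersion: float = 10.0
    true_fraction_beta: tuple[float, float] = (8.0, 2.0)
    false_fraction_beta: tuple[float, float] = (2.0, 5.0)
    peak_width: int = 200
    peak_coverage: float = 1.0
    n_decoy_peaks: int = 40
    true_peak_enrichment: tuple[float, float] = (2.0, 8.0)
    true_peak_neglog10q: tuple[float, float] = (5.0, 30.0)
    decoy_enrichment: tuple[float, float] = (0.2, 1.1)
    decoy_neglog10q: tuple[float, float] = (0.0, 2.2)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a simulation seed is mandatory")
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1 kb")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError(f"gc_content must lie in [0, 1], got {self.gc_content}")
        for prob in (self.on_motif_fraction, self.peak_coverage):
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"probability parameter out of [0, 1]: {prob}")
        if self.regime not in REGIMES:
            raise ValueError(
                f"unknown regime {self.regime!r}; valid regimes: {REGIMES}"
            )
        if len(self.planted_copies) != len(self.motifs):
            raise ValueError("planted_copies must align with motifs")
        if self.true_ipd_mean <= self.false_ipd_mean:
            warnings.warn(
                "true IPD mean does not exceed false IPD mean; the threshold "
                "cannot separate the components",
                stacklevel=2,
            )

    @classmethod
    def prokaryote_like(cls, seed: int, **overrides) -> "SimulationConfig":
        """Motif-driven regime: ~95% of true calls on GATC, modest FPR."""
        return cls(seed=seed, **overrides)

    @classmethod
    def eukaryote_like(cls, seed: int, **overrides) -> "SimulationConfig":
        """Weakly motif-driven regime: ~2% of true calls on VATB, high FPR."""
        defaults = dict(
            regime="eukaryote-like",
            motifs=(MotifSpec("VATB", "VATB", 1),),
            planted_copies=(300,),
            n_true=500,
            on_motif_fraction=0.02,
            n_false=1500,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["motifs"] = [
            [m.name, m.pattern, m.methylated_offset] for m in self.motifs
        ]
        data["planted_copies"] = list(self.planted_copies)
        for key in (
            "true_fraction_beta",
            "false_fraction_beta",
            "true_peak_enrichment",
            "true_peak_neglog10q",
            "decoy_enrichment",
            "decoy_neglog10q",
        ):
            data[key] = list(data[key])
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "motifs" in data:
            data["motifs"] = tuple(
                MotifSpec(name, pattern, offset if offset == "any" else int(offset))
                for name, pattern, offset in data["motifs"]
            )
        for key in (
            "planted_copies",
            "true_fraction_beta",
            "false_fraction_beta",
            "true_peak_enrichment",
            "true_peak_neglog10q",
            "decoy_enrichment",
            "decoy_neglog10q",
        ):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with Path(path).open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        "genome": np.random.default_rng(children[0]),
        "calls": np.random.default_rng(children[1]),
        "peaks": np.random.default_rng(children[2]),
    }


def generate_genome(config: SimulationConfig) -> GenomeSequence:
    """I.i.d. random genome at the configured GC content (deterministic per seed)."""
    rng = _stage_rngs(config.seed)["genome"]
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    draws = rng.choice(bases, size=config.genome_length, p=probs)
    return GenomeSequence({config.chrom_name: draws.tobytes().decode("ascii")})


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, low: float = 1e-3
) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = out <= low
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, low)


def _negative_binomial(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _score(
    rng: np.random.Generator, ipd: np.ndarray, coverage: np.ndarray
) -> np.ndarray:
    """Modification QV as a monotone function of IPD elevation and coverage."""
    base = 12.0 * (ipd - 1.0) * np.sqrt(np.maximum(coverage, 1) / 50.0)
    noisy = base + rng.normal(0.0, 3.0, size=ipd.size)
    return np.clip(noisy, 0.0, 1000.0)


def _plant_motif_instances(
    seq: bytearray, config: SimulationConfig, rng: np.random.Generator
) -> None:
    """Overwrite the sequence with concrete motif instances at
    non-overlapping random loci (guaranteeing the configured copy counts)."""
    occupied = np.zeros(len(seq), dtype=bool)
    for motif, copies in zip(config.motifs, config.planted_copies):
        length = len(motif.pattern)
        placed = 0
        attempts = 0
        max_attempts = max(200, 60 * copies)
        while placed < copies and attempts < max_attempts:
            attempts += 1
            start = int(rng.integers(0, len(seq) - length + 1))
            if occupied[start : start + length].any():
                continue
            instance = "".join(
                str(rng.choice(sorted(IUPAC_SETS[c]))) for c in motif.pattern
            )
            seq[start : start + length] = instance.encode("ascii")
            occupied[start : start + length] = True
            placed += 1
        if placed < copies:
            raise ValueError(
                f"could not place {copies} non-overlapping copies of "
                f"{motif.name!r}; placed {placed}"
            )


def plant_motifs_and_calls(
    genome: GenomeSequence, config: SimulationConfig
) -> tuple[GenomeSequence, list[ModificationCall], pd.DataFrame]:
    """Plant motif instances and emit a call table with ground truth.

    Returns the modified genome, the calls (sorted by position then
    strand) and a truth table with one row per call (columns: chrom,
    position, strand, is_true_6mA, on_motif, motif_name).  The genome is
    re-scanned after planting so naturally occurring motif instances are
    part of the ground truth — false calls are never placed on a motif
    adenine, planned or not.
    """
    rng = _stage_rngs(config.seed)["calls"]
    chrom = config.chrom_name
    seq_bytes = bytearray(genome[chrom].encode("ascii"))
    _plant_motif_instances(seq_bytes, config, rng)
    seq = seq_bytes.decode("ascii")
    planted_genome = GenomeSequence({chrom: seq})

    occurrences = scan_motifs(planted_genome, list(config.motifs))
    motif_adenines: dict[tuple[int, str], str] = {}
    for occ in occurrences:
        for pos in occ.adenine_positions:
            motif_adenines.setdefault((pos, occ.strand), occ.motif_name)
    motif_sites = sorted(motif_adenines)

    n_on = int(round(config.n_true * config.on_motif_fraction))
    n_off = config.n_true - n_on
    if n_on > len(motif_sites):
        raise ValueError(
            f"regime requests {n_on} on-motif true calls but only "
            f"{len(motif_sites)} motif adenines exist; plant more copies"
        )
    on_idx = rng.choice(len(motif_sites), size=n_on, replace=False)
    true_on = [motif_sites[i] for i in sorted(on_idx)]

    # off-motif adenine pool: A on + strand, T (i.e. A on -) on forward
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    motif_plus = np.array(
        sorted(p for p, s in motif_adenines if s == "+"), dtype=np.int64
    )
    motif_minus = np.array(
        sorted(p for p, s in motif_adenines if s == "-"), dtype=np.int64
    )
    a_pos = np.flatnonzero(arr == ord("A")) + 1
    t_pos = np.flatnonzero(arr == ord("T")) + 1
    a_pos = a_pos[~np.isin(a_pos, motif_plus)]
    t_pos = t_pos[~np.isin(t_pos, motif_minus)]
    pool = [(int(p), "+") for p in a_pos] + [(int(p), "-") for p in t_pos]
    needed = n_off + config.n_false
    if needed > len(pool):
        raise ValueError(
            f"genome offers {len(pool)} off-motif adenines but the design "
            f"needs {needed}"
        )
    picked = rng.choice(len(pool), size=needed, replace=False)
    true_off = [pool[i] for i in sorted(picked[:n_off])]
    false_sites = [pool[i] for i in sorted(picked[n_off:])]

    sites = true_on + true_off + false_sites
    is_true = [True] * (n_on + n_off) + [False] * config.n_false
    on_motif = [True] * n_on + [False] * (n_off + config.n_false)
    names = [motif_adenines[s] for s in true_on] + [""] * (n_off + config.n_false)

    n_all = len(sites)
    n_true = n_on + n_off
    ipd = np.empty(n_all)
    ipd[:n_true] = _truncated_normal(
        rng, config.true_ipd_mean, config.true_ipd_sd, n_true
    )
    ipd[n_true:] = _truncated_normal(
        rng, config.false_ipd_mean, config.false_ipd_sd, config.n_false
    )
    coverage = _negative_binomial(
        rng, config.coverage_mean, config.coverage_dispersion, n_all
    )
    fraction = np.empty(n_all)
    fraction[:n_true] = rng.beta(*config.true_fraction_beta, size=n_true)
    fraction[n_true:] = rng.beta(*config.false_fraction_beta, size=config.n_false)
    score = _score(rng, ipd, coverage)

    order = sorted(range(n_all), key=lambda i: (sites[i][0], sites[i][1]))
    calls = []
    truth_rows = []
    for i in order:
        pos, strand = sites[i]
        calls.append(
            ModificationCall(
                chrom=chrom,
                position=pos,
                strand=strand,
                ipd_ratio=float(ipd[i]),
                coverage=int(coverage[i]),
                score=float(score[i]),
                fraction=float(np.clip(fraction[i], 0.0, 1.0)),
            )
        )
        truth_rows.append(
            {
                "chrom": chrom,
                "position": pos,
                "strand": strand,
                "is_true_6mA": bool(is_true[i]),
                "on_motif": bool(on_motif[i]),
                "motif_name": names[i],
            }
        )
    truth = pd.DataFrame(truth_rows)
    return planted_genome, calls, truth


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def simulate_peaks(
    truth: pd.DataFrame, genome: GenomeSequence, config: SimulationConfig
) -> list[Peak]:
    """MeDIP-like peak track: enriched intervals over true 6mA sites plus
    decoy peaks that (mostly) fail the strict enrichment/q-value filter."""
    rng = _stage_rngs(config.seed)["peaks"]
    chrom = config.chrom_name
    length = genome.lengths[chrom]
    width = config.peak_width
    half = width // 2

    true_pos = np.sort(truth.loc[truth["is_true_6mA"], "position"].unique())
    covered_mask = rng.random(true_pos.size) < config.peak_coverage
    covered = true_pos[covered_mask]
    intervals = _merge_intervals(
        [
            (max(0, int(p) - 1 - half), min(length, int(p) - 1 + half + 1))
            for p in covered
        ]
    )

    peaks: list[Peak] = []
    for start, end in intervals:
        peaks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=end,
                enrichment=float(rng.uniform(*config.true_peak_enrichment)),
                neg_log10_q=float(rng.uniform(*config.true_peak_neglog10q)),
            )
        )

    placed = 0
    attempts = 0
    while placed < config.n_decoy_peaks and attempts < 50 * max(
        config.n_decoy_peaks, 1
    ):
        attempts += 1
        start = int(rng.integers(0, max(1, length - width)))
        end = start + width
        # reject decoys containing any true site
        lo = np.searchsorted(true_pos, start + 1)
        hi = np.searchsorted(true_pos, end, side="right")
        if hi > lo:
            continue
        peaks.append(
            Peak(
                chrom=chrom,
                start=start,
                end=end,
                enrichment=float(rng.uniform(*config.decoy_enrichment)),
                neg_log10_q=float(rng.uniform(*config.decoy_neglog10q)),
            )
        )
        placed += 1

    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    for i, p in enumerate(peaks):
        p.name = f"sim_peak_{i:04d}"
        p.display_score = int(min(1000, round(100 * p.enrichment)))
        p.neg_log10_p = round(p.neg_log10_q + 0.3, 6)
        p.summit_offset = len(p) // 2
    return peaks


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate a full dataset on disk: FASTA genome, modification GFF,
    narrowPeak track, ground-truth TSV, config YAML and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(config)
    genome, calls, truth = plant_motifs_and_calls(genome, config)
    peaks = simulate_peaks(truth, genome, config)

    paths = {
        "genome": outdir / "genome.fasta",
        "modifications": outdir / "modifications.gff",
        "peaks": outdir / "peaks.narrowPeak",
        "truth": outdir / "truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_fasta(genome, paths["genome"])
    write_calls(calls, paths["modifications"], format="gff")
    write_narrowpeak(peaks, paths["peaks"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    config.to_yaml(paths["config"])

    manifest = {
        "regime": config.regime,
        "seed": config.seed,
        "n_calls": len(calls),
        "n_true": int(truth["is_true_6mA"].sum()),
        "n_peaks": len(peaks),
        "files": {key: path.name for key, path in paths.items()},
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read a ground-truth TSV written by :func:`simulate_dataset`."""
    truth = pd.read_csv(path, sep="\t", dtype={"motif_name": str})
    truth["motif_name"] = truth["motif_name"].fillna("")
    return truth
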