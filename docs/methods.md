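# Methods

## Model and procedure

`masqc` controls the false-positive rate of SMRT-seq 6mA calls without a
whole-genome-amplification control. The statistical core is small and
deliberate:

1. MeDIP-seq peak regions mark genuinely methylated neighbourhoods.
   After strict filtering of peaks (fold enrichment ≥ 1, −log₁₀(q) ≥ 2)
   and calls (coverage ≥ 50, modification QV ≥ 30, methylated
   fraction ≥ 0.7), the calls inside surviving peaks — the
   *conservative set* — are assumed to be (nearly) all true 6mA, and
   their IPD ratios to follow a normal population N(μ, σ²).
2. A simple random sample of n = 30 IPD ratios is drawn without
   replacement from the conservative set. With sample mean X̄ and
   standard deviation S (n−1 denominator), the genome-wide threshold is
   the lower bound of the two-sided confidence interval for μ:
   *thres* = X̄ − t·S/√n.
3. A call anywhere in the (coverage-filtered) genome-wide call table is
   retained iff its IPD ratio ≥ *thres*; the comparison is inclusive.
4. Quality is judged externally through methylation motifs: the share of
   calls on known motifs should rise after filtering (statistic I) and
   the non-motif share should fall (statistic D, with D·N equal to the
   count of removed non-motif calls).

### Assumptions, and what the threshold actually trades

The normality assumption is diagnosed (Shapiro–Wilk on the sample,
advisory warning only, constant samples reported as non-testable) but
never enforced. More important is a structural property users should
understand: the threshold is a confidence bound on the *mean* of the
true-site IPD distribution, so it sits only t/√n ≈ 0.36 sample standard
deviations below X̄ — close to the centre of the true component, not in
the valley between true and false components. Consequently the filter is
**precision-first**: essentially every false call falls far below the
threshold (specificity ≈ 1), while the lower tail of the true
distribution is sacrificed (sensitivity ≈ P(IPD ≥ thres | true), about
0.6–0.7 for a true component with coefficient of variation 0.1). This is
inherent to the formula, not an implementation artefact, and the
evaluation module reports it honestly.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| peak cutoffs | enrichment ≥ 1, −log₁₀(q) ≥ 2 | strict peak filter (q < 0.01) |
| call cutoffs | coverage ≥ 50, QV ≥ 30, fraction ≥ 0.7 | strict call filter (QV 30 ⇔ p = 0.001) |
| basic coverage | 50 | genome-wide pre-filter before thresholding |
| n | 30 | threshold sample size |
| α | 0.05 | confidence level of the interval |
| critical value | 1.96 (fixed) | confidence multiplier; `"auto"` gives the exact Student quantile t₀.₀₂₅(n−1) = 2.045 at n = 30 |
| seed | mandatory in the CLI | reproducibility of the sampling draw |

The fixed 1.96 default reproduces the method's historical behaviour;
note 1.96 is the *normal* quantile, so the fixed-mode interval is
slightly anticonservative relative to the Student interval it
approximates. Both the multiplier and mode are recorded in the threshold
report. Sampling is without replacement (a flag enables replacement);
each threshold comes from a single draw — no multi-draw averaging —
matching the method's design, with `replicate_thresholds` available to
quantify the resulting sampling dispersion (on a large conservative set
with σ ≈ 0.5 the spread of three replicate thresholds is typically
≈ 0.1).

## Numerical and convention choices

* Calls carry 1-based positions (GFF-native); peaks carry 0-based
  half-open intervals (BED-native); every comparison converts a position
  p to [p−1, p). A call at a peak's end coordinate is outside.
* The narrowPeak qValue column is taken as −log₁₀(q) exactly as MACS2
  emits it. Older descriptions of this pipeline write "−10 log
  (q-value)", but the printed anchor points (1.3 ⇔ q = 0.05, 2 ⇔
  q = 0.01) identify the quantity as −log₁₀; the numbers, not the
  notation, are followed. The modification score is the Phred-type
  QV = −10·log₁₀(p) (20 ⇔ 0.01, 30 ⇔ 0.001).
* All cutoff and threshold comparisons are inclusive (≥). Threshold
  statistics are computed on the sorted sample, so they are independent
  of draw order; a constant sample short-circuits to sd exactly 0.
* Duplicate calls (same chromosome, position, strand) are collapsed with
  a warning before filtering; they would double-count in the motif
  proportions. The coverage rule is applied per site; a per-chromosome
  variant (`drop_low_coverage_chromosomes`) is available for users who
  read the rule as a chromosome-level mean.
* A call with absent methylated fraction fails any finite fraction
  cutoff. Undefined ratios (empty states, empty removed sets) are
  reported as missing values, never coerced to 0.
* Motif scanning uses per-base bitmasks under IUPAC semantics; an N in
  the reference matches no code (conservative). Minus-strand occurrences
  come from matching the reverse-complemented pattern on the forward
  sequence with coordinates mapped back; overlapping and
  self-overlapping occurrences are all reported. A call is "on motif"
  iff its position and strand coincide with an A-compatible motif
  position whose reference base is A (+) or T (−); with
  `methylated_offset="any"` every such position counts (permissive
  reading), a fixed offset narrows it. A call on several motifs
  increments each motif's m but counts once in the total M, keeping
  M ≤ N.
* MeDIP peaks are unstranded, so peak–call intersection ignores strand;
  call strand is preserved throughout.

## The synthetic-data generator

The generator emulates the statistical structure of the real inputs at
desk scale; its defaults are the study conditions of the test suite.

* **Genome**: 100 kb i.i.d. sequence at GC 0.45; motif instances are
  planted by overwriting non-overlapping random loci (guaranteeing copy
  counts), and the genome is re-scanned afterwards so naturally arising
  occurrences join the ground truth — false calls are never placed on
  any motif adenine, planned or not.
* **Regimes**: prokaryote-like — GATC (methylated A, both strands, as
  for Dam methylase), 250 planted copies, 1000 true calls of which 95%
  on motif adenines, 400 false calls; eukaryote-like — VATB, 300
  planted copies, 500 true calls of which 2% on motifs, 1500 false
  calls. The regime fractions mirror the >95% (prokaryote) vs <3%
  (eukaryote) motif-driven contrast seen in real methylomes; the
  eukaryote false-call excess reflects the higher false-positive rate
  where 6mA is rare.
* **Kinetics**: true IPD ~ N(5.0, 0.5²) truncated positive, false
  IPD ~ N(1.8, 0.4²) — a well-separated (≈7 pooled-σ) caricature of
  methylated vs background kinetics. Coverage ~ negative binomial
  (mean 80, dispersion 10); methylated fraction ~ Beta(8,2) for true
  calls (mass above the 0.7 cutoff) and Beta(2,5) for false; the QV is a
  monotone function of IPD elevation and coverage
  (12·(IPD−1)·√(cov/50) plus N(0,3) noise, clipped to [0,1000]), chosen
  so true calls clear QV 30 and false calls generally do not — the
  upstream caller's score distribution is not public, only its
  monotonicity in signal strength is emulated.
* **Peaks**: width-200 intervals merged over true sites (coverage
  fraction 1.0 by default) with enrichment ~ U(2,8) and
  −log₁₀(q) ~ U(5,30), passing the strict filter; ~40 decoy peaks avoid
  true sites with enrichment ~ U(0.2,1.1), −log₁₀(q) ~ U(0,2.2), almost
  all failing it.
* **Determinism**: one mandatory seed drives three spawned RNG streams
  (genome, calls, peaks); outputs are byte-identical across runs.

What the generator does **not** emulate: read-level data (no FASTQ/BAM),
kinetic context effects (IPD noise is i.i.d., real IPD depends on
sequence context and neighbouring modifications), correlated
fraction/score/coverage structure, chromosome heterogeneity, and MeDIP
fragment-level enrichment (peaks are drawn directly). Passing tests
therefore demonstrate the correctness of the statistics and plumbing and
the qualitative regime behaviour, not performance on real genomes, where
component overlap is larger and the conservative set can be
contaminated.

## Problem sizes in the validation suite

The test suite and `scripts/acceptance.py` use 100 kb genomes with
1.4 k–2 k calls per regime, 10⁴ calls × 10³ peaks for the intersection
oracle, 50 × 10 kb sequences for the scanner oracle, 100-sample batches
for the closed-form threshold oracle, and 5000-value conservative pools
for the replication analysis — sizes at which the brute-force oracles
remain exact and the full suite runs in seconds.

## Known limitations

* The fixed 1.96 multiplier understates the Student interval width for
  small n (use `"auto"` when exactness matters).
* Sensitivity is bounded by the tail mass of the true IPD distribution
  above the confidence bound (see above); applications needing high
  recall should treat the retained set as a high-precision core, not a
  complete catalogue.
* A single genome-wide threshold is derived; per-chromosome or
  mixture-model thresholds are out of scope.
* The conservative set must hold at least n calls; the sampler fails
  loudly (advising to relax cutoffs or lower n) rather than silently
  degrading.
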