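"""Motif scanning, call classification and the proportion statistics."""

import re
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from masqc import (
    GenomeSequence,
    MotifSpec,
    classify_calls,
    compute_increase_decrease,
    compute_state_proportions,
    filtered_composition,
    scan_motifs,
)
from masqc.motif_analysis import MotifOccurrence, reverse_complement_pattern

from conftest import make_call

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq):
    return seq.translate(COMPLEMENT)[::-1]


def regex_scan(seq, pattern):
    """Brute-force oracle: (start, strand) of every occurrence, both strands.

    Plus strand matches the pattern on the forward sequence; minus strand
    matches the pattern on the reverse complement, with coordinates mapped
    back to forward 0-based starts.  A reference N matches nothing since
    the character classes list concrete bases only.
    """
    expr = re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in pattern) + "))")
    length = len(pattern)
    hits = {(m.start(), "+") for m in expr.finditer(seq)}
    hits |= {
        (len(seq) - m.start() - length, "-") for m in expr.finditer(revcomp(seq))
    }
    return hits


class TestScanMotifs:
    def test_gatc_palindrome_found_on_both_strands(self):
        genome = GenomeSequence({"c": "GGATCC"})
        occs = scan_motifs(genome, [MotifSpec("gatc", "GATC", 1)])
        assert {(o.start, o.end, o.strand) for o in occs} == {(1, 5, "+"), (1, 5, "-")}
        by_strand = {o.strand: o for o in occs}
        # + strand A is position 3 (1-based); - strand A sits on the T at 4
        assert by_strand["+"].adenine_positions == (3,)
        assert by_strand["-"].adenine_positions == (4,)

    def test_vatb_matches_catg(self):
        occs = scan_motifs(
            GenomeSequence({"c": "CATG"}), [MotifSpec("vatb", "VATB", "any")]
        )
        assert any(o.strand == "+" and o.start == 0 for o in occs)

    def test_self_overlapping_occurrences_all_reported(self):
        occs = scan_motifs(GenomeSequence({"c": "AAAAA"}), [MotifSpec("a4", "AAAA")])
        plus = [o for o in occs if o.strand == "+"]
        assert [(o.start, o.end) for o in plus] == [(0, 4), (1, 5)]

    def test_reference_n_matches_no_code(self):
        occs = scan_motifs(GenomeSequence({"c": "GANC"}), [MotifSpec("m", "GANC")])
        assert occs == []

    def test_motif_longer_than_chromosome_yields_nothing(self):
        occs = scan_motifs(GenomeSequence({"c": "ACG"}), [MotifSpec("m", "ACGTACGT")])
        assert occs == []

    def test_fixed_offset_restricts_adenine_positions(self):
        genome = GenomeSequence({"c": "AATT"})
        any_occ = scan_motifs(genome, [MotifSpec("m", "AATT", "any")])
        fixed_occ = scan_motifs(genome, [MotifSpec("m", "AATT", 0)])
        plus_any = next(o for o in any_occ if o.strand == "+")
        plus_fixed = next(o for o in fixed_occ if o.strand == "+")
        assert plus_any.adenine_positions == (1, 2)
        assert plus_fixed.adenine_positions == (1,)

    @pytest.mark.parametrize(
        "pattern", ["GATC", "VATB", "RYSWKM", "BDHVN", "ANNT", "ACGT", "AAA"]
    )
    def test_equivalence_with_regex_oracle(self, rng, pattern):
        bases = np.array(list("ACGTN"))
        seq = "".join(
            rng.choice(bases, p=[0.24, 0.24, 0.24, 0.24, 0.04], size=3000)
        )
        genome = GenomeSequence({"c": seq})
        occs = scan_motifs(genome, [MotifSpec("m", pattern)])
        assert {(o.start, o.strand) for o in occs} == regex_scan(seq, pattern)

    @given(st.integers(min_value=0, max_value=2**16))
    def test_reverse_complement_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        pattern = "VATB"
        minus_here = {
            o.start
            for o in scan_motifs(GenomeSequence({"c": seq}), [MotifSpec("m", pattern)])
            if o.strand == "-"
        }
        plus_on_rc = {
            len(seq) - o.start - len(pattern)
            for o in scan_motifs(
                GenomeSequence({"c": revcomp(seq)}), [MotifSpec("m", pattern)]
            )
            if o.strand == "+"
        }
        assert minus_here == plus_on_rc

    def test_pattern_reverse_complement_helper(self):
        assert reverse_complement_pattern("GATC") == "GATC"
        assert reverse_complement_pattern("VATB") == "VATB"
        assert reverse_complement_pattern("AAC") == "GTT"


class TestClassifyCalls:
    def _occ(self, positions, strand="+", name="GATC"):
        return MotifOccurrence(name, "chr1", 0, 4, strand, tuple(positions))

    def test_call_on_motif_adenine_labeled(self):
        labels = classify_calls([make_call(position=3)], [self._occ([3])])
        assert labels == [frozenset({"GATC"})]

    def test_strand_specificity(self):
        call = make_call(position=3, strand="-")
        assert classify_calls([call], [self._occ([3], "+")]) == [frozenset()]
        assert classify_calls([call], [self._occ([3], "-")]) == [frozenset({"GATC"})]

    def test_call_on_two_motifs_carries_both_names(self):
        occs = [self._occ([3], name="m1"), self._occ([3], name="m2")]
        assert classify_calls([make_call(position=3)], occs) == [
            frozenset({"m1", "m2"})
        ]

    def test_matches_all_pairs_oracle(self, rng):
        occs = [
            MotifOccurrence(
                f"m{rng.integers(3)}",
                "chr1",
                0,
                4,
                str(rng.choice(["+", "-"])),
                tuple(int(p) for p in rng.integers(1, 500, size=2)),
            )
            for _ in range(300)
        ]
        calls = [
            make_call(
                position=int(rng.integers(1, 500)), strand=str(rng.choice(["+", "-"]))
            )
            for _ in range(2000)
        ]
        labels = classify_calls(calls, occs)
        for call, label in zip(calls, labels):
            expected = {
                o.motif_name
                for o in occs
                if o.strand == call.strand and call.position in o.adenine_positions
            }
            assert label == frozenset(expected)


class TestStateProportions:
    def test_simple_ratio(self):
        labels = [frozenset({"m"}), frozenset({"m"}), frozenset(), frozenset()]
        report = compute_state_proportions({"PacBio": labels})
        assert report.proportion("m", "PacBio") == 0.5
        assert report.total_proportion("PacBio") == 0.5

    def test_all_calls_on_motifs_gives_one_everywhere(self):
        labels = [frozenset({"m"})] * 3
        report = compute_state_proportions(
            {"PacBio": labels, "PacBio+threshold": labels[:2]}
        )
        assert report.total_proportion("PacBio") == 1.0
        assert report.total_proportion("PacBio+threshold") == 1.0

    def test_empty_state_reported_as_nan_not_zero(self):
        report = compute_state_proportions(
            {"PacBio": [frozenset({"m"})], "PacBio+MeDIP": []}
        )
        assert np.isnan(report.total_proportion("PacBio+MeDIP"))

    def test_empty_pacbio_state_is_an_error(self):
        with pytest.raises(ValueError):
            compute_state_proportions({"PacBio": []})

    def test_matches_brute_force_counting(self, rng):
        motifs = ["m1", "m2"]
        labels = [
            frozenset(m for m in motifs if rng.random() < 0.3) for _ in range(500)
        ]
        subset = labels[: rng.integers(100, 400)]
        report = compute_state_proportions(
            {"PacBio": labels, "PacBio+threshold": subset}, motif_names=motifs
        )
        for state, pool in (("PacBio", labels), ("PacBio+threshold", subset)):
            for m in motifs:
                assert report.proportion(m, state) == (
                    sum(1 for l in pool if m in l) / len(pool)
                )
            assert report.total_proportion(state) == (
                sum(1 for l in pool if l) / len(pool)
            )
        # conservation: motif + non-motif labels account for the whole state
        m_total = int(
            report.totals.loc[report.totals["state"] == "PacBio", "M"].iloc[0]
        )
        assert m_total + sum(1 for l in labels if not l) == len(labels)


class TestIncreaseDecrease:
    def test_printed_example(self):
        increase, decrease = compute_increase_decrease(10, 6, 5, 4)
        assert increase == pytest.approx(4 / 5 - 6 / 10)
        assert decrease == pytest.approx((1 - 0.6) - (5 - 4) / 10)

    def test_no_removal_is_the_identity(self):
        assert compute_increase_decrease(10, 6, 10, 6) == (0.0, 0.0)

    def test_empty_thresholded_state_undefined_increase(self):
        increase, decrease = compute_increase_decrease(10, 6, 0, 0)
        assert increase is None
        assert decrease == pytest.approx(1 - 0.6)  # all 10 calls removed, 4 non-motif

    def test_removing_only_non_motif_calls(self):
        n, m = 20, 8
        n_thr, m_thr = 14, 8  # six non-motif calls removed
        increase, decrease = compute_increase_decrease(n, m, n_thr, m_thr)
        assert decrease == pytest.approx(6 / n)
        assert increase > 0

    def test_algebraic_identities_on_random_integer_scenarios(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 200))
            on_motif = rng.random(n) < rng.random()
            removed = rng.random(n) < rng.random()
            m = int(on_motif.sum())
            n_thr = int((~removed).sum())
            m_thr = int((on_motif & ~removed).sum())
            increase, decrease = compute_increase_decrease(n, m, n_thr, m_thr)
            exact_decrease = Fraction(1) - Fraction(m, n) - Fraction(n_thr - m_thr, n)
            assert decrease == pytest.approx(float(exact_decrease), abs=1e-12)
            # D*N equals the number of removed non-motif calls
            removed_non_motif = int((removed & ~on_motif).sum())
            assert decrease * n == pytest.approx(removed_non_motif, abs=1e-9)
            if n_thr:
                exact_increase = Fraction(m_thr, n_thr) - Fraction(m, n)
                assert increase == pytest.approx(float(exact_increase), abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_increase_decrease(0, 0, 0, 0)
        with pytest.raises(ValueError):
            compute_increase_decrease(10, 12, 5, 4)
        with pytest.raises(ValueError):
            compute_increase_decrease(10, 4, 5, 5)


class TestFilteredComposition:
    def test_simple_proportions(self):
        labels = [frozenset()] * 3 + [frozenset({"m"})]
        assert filtered_composition(labels) == (0.25, 0.75)

    def test_all_non_motif(self):
        assert filtered_composition([frozenset()] * 5) == (0.0, 1.0)

    def test_empty_removed_set_undefined(self):
        assert filtered_composition([]) is None
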