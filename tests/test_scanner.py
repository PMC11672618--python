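"""Perfect-repeat scanning and compound merging."""

import numpy as np
import pytest

from oracle import brute_force_ssrs
from ssrmine.io_formats import GenomeSequence
from ssrmine.ssr_detect import (
    ContractViolation,
    SSRLocus,
    canonical_class,
    merge_compound,
    scan_perfect_ssrs,
)


def _seq(s: str, seq_id: str = "t") -> GenomeSequence:
    return GenomeSequence(seq_id, s, len(s))


def _locus(start: int, unit: str, n: int, seq_id: str = "t") -> SSRLocus:
    return SSRLocus(
        seq_id=seq_id,
        start=start,
        end=start + len(unit) * n - 1,
        unit=unit,
        motif=canonical_class(unit),
        n_repeats=n,
        length_bp=len(unit) * n,
    )


class TestScanExamples:
    def test_embedded_dinucleotide_run(self):
        (locus,) = scan_perfect_ssrs(_seq("TTT" + "AC" * 6 + "GGT"))
        assert (locus.start, locus.end, locus.motif.canonical, locus.n_repeats) == (4, 15, "AC", 6)

    def test_below_threshold_dinucleotide_not_reported(self):
        assert scan_perfect_ssrs(_seq("AC" * 5)) == []

    def test_trinucleotide_at_threshold(self):
        (locus,) = scan_perfect_ssrs(_seq("GAT" * 5))
        assert (locus.motif.canonical, locus.n_repeats, locus.length_bp) == ("ATC", 5, 15)

    def test_empty_sequence(self):
        assert scan_perfect_ssrs(_seq("")) == []

    def test_run_abutting_both_ends_reported(self):
        (locus,) = scan_perfect_ssrs(_seq("AC" * 7))
        assert (locus.start, locus.end, locus.n_repeats) == (1, 14, 7)

    def test_n_breaks_run_keeping_passing_prefix(self):
        # (AC)7, an N, then (AC)4: only the prefix passes
        (locus,) = scan_perfect_ssrs(_seq("AC" * 7 + "N" + "AC" * 4))
        assert (locus.start, locus.end, locus.n_repeats) == (1, 14, 7)

    def test_mononucleotide_runs_never_reported(self):
        assert scan_perfect_ssrs(_seq("A" * 50)) == []

    def test_tetranucleotide_of_dinucleotide_reported_under_minimal_period(self):
        # (ATAT)8 is (AT)16
        (locus,) = scan_perfect_ssrs(_seq("G" + "ATAT" * 8 + "G"))
        assert (locus.motif.canonical, locus.period, locus.n_repeats) == ("AT", 2, 16)

    def test_partial_trailing_unit_excluded(self):
        (locus,) = scan_perfect_ssrs(_seq("AC" * 6 + "A" + "GGG"))
        assert (locus.end, locus.n_repeats) == (12, 6)

    def test_locus_invariants(self):
        rng = np.random.default_rng(0)
        s = "".join(rng.choice(list("ACGT"), size=3000))
        s = s[:100] + "AGAT" * 7 + s[150:2000] + "AAC" * 9 + s[2050:]
        for locus in scan_perfect_ssrs(_seq(s)):
            assert locus.length_bp == locus.period * locus.n_repeats
            assert locus.end - locus.start + 1 == locus.length_bp
            spanned = s[locus.start - 1 : locus.end]
            assert spanned == locus.unit * locus.n_repeats


class TestOracleEquivalence:
    """The production scanner must agree with the brute-force oracle that
    enumerates every (start, period) pair by direct string comparison."""

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        units = ["AC", "AT", "AG", "AAG", "ATC", "ACT", "AAAT", "AGAT", "AACCT", "AACCGT"]
        for i in range(60):
            chars = list("".join(rng.choice(list("ACGT"), size=1500)))
            for _ in range(int(rng.integers(0, 5))):  # enrich with real tracts
                u = units[rng.integers(len(units))]
                n = int(rng.integers(4, 12))
                pos = int(rng.integers(0, len(chars) - len(u) * n))
                chars[pos : pos + len(u) * n] = list(u * n)
            s = "".join(chars)
            got = [(l.start, l.period, l.n_repeats) for l in scan_perfect_ssrs(_seq(s))]
            assert got == brute_force_ssrs(s)

    def test_sequences_with_n(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            s = "".join(rng.choice(list("ACGTN"), size=800, p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            got = [(l.start, l.period, l.n_repeats) for l in scan_perfect_ssrs(_seq(s))]
            assert got == brute_force_ssrs(s)

    def test_output_sorted_and_non_overlapping(self):
        rng = np.random.default_rng(5)
        s = "".join(rng.choice(list("ACGT"), size=5000))
        loci = scan_perfect_ssrs(_seq(s))
        for a, b in zip(loci, loci[1:]):
            assert a.end < b.start


class TestMergeCompound:
    def test_gap_49_merges(self):
        a = _locus(89, "AC", 6)  # ends at 100
        b = _locus(150, "AG", 7)
        compounds, standalone = merge_compound([a, b])
        assert len(compounds) == 1 and not standalone
        assert compounds[0].gaps == (49,)
        assert (compounds[0].start, compounds[0].end) == (89, 163)

    def test_gap_100_boundary_excluded_under_strict_less(self):
        a = _locus(89, "AC", 6)
        b = _locus(201, "AG", 7)  # gap = 201 - 100 - 1 = 100
        compounds, standalone = merge_compound([a, b])
        assert not compounds and len(standalone) == 2

    def test_gap_99_merges(self):
        a = _locus(89, "AC", 6)
        b = _locus(200, "AG", 7)  # gap 99
        compounds, _ = merge_compound([a, b])
        assert len(compounds) == 1

    def test_single_locus_stays_standalone(self):
        compounds, standalone = merge_compound([_locus(10, "AAG", 5)])
        assert not compounds and len(standalone) == 1

    def test_chain_of_three(self):
        a, b, c = _locus(1, "AC", 6), _locus(20, "AAG", 5), _locus(50, "AT", 7)
        (comp,), standalone = merge_compound([a, b, c])
        assert len(comp.members) == 3 and not standalone

    def test_unsorted_input_rejected(self):
        with pytest.raises(ContractViolation):
            merge_compound([_locus(100, "AC", 6), _locus(1, "AG", 6)])

    def test_conservation_of_loci(self):
        rng = np.random.default_rng(3)
        s = "".join(rng.choice(list("ACGT"), size=4000))
        chars = list(s)
        for pos in (100, 160, 700, 2000, 2180):
            chars[pos : pos + 12] = list("AC" * 6)
        loci = scan_perfect_ssrs(_seq("".join(chars)))
        compounds, standalone = merge_compound(loci)
        members = [m for c in compounds for m in c.members]
        assert sorted(members + standalone, key=lambda l: l.start) == loci
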