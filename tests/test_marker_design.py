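"""Flank extraction and primer constraint screening."""

import numpy as np
import pytest

from ssrmine.io_formats import GenomeSequence
from ssrmine.marker_design import (
    PrimerConstraints,
    extract_flanks,
    gc_content,
    markers_per_chromosome,
    melting_temperature,
    screen_pair,
)
from ssrmine.ssr_detect import SSRLocus, canonical_class, revcomp


def _locus(start, unit, n, seq_id="chr1"):
    return SSRLocus(seq_id, start, start + len(unit) * n - 1, unit,
                    canonical_class(unit), n, len(unit) * n)


def _genome(s, seq_id="chr1"):
    return GenomeSequence(seq_id, s, len(s))


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("ACGT", 50.0), ("AAAA", 0.0), ("GCGCAA", 4 / 6 * 100)])
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            gc_content("")


class TestMeltingTemperature:
    def test_gc_formula_20mer(self):
        seq = "GC" * 5 + "AT" * 5  # 10 G/C in 20
        assert melting_temperature(seq) == pytest.approx(64.9 + 41 * (10 - 16.4) / 20)

    def test_homopolymer_g_20mer(self):
        assert melting_temperature("G" * 20) == pytest.approx(64.9 + 41 * (20 - 16.4) / 20)

    def test_wallace_rule_below_14(self):
        with pytest.warns(UserWarning, match="Wallace"):
            assert melting_temperature("AAAATTTTAAAA") == 24.0


class TestExtractFlanks:
    def test_full_flanks(self):
        rng = np.random.default_rng(1)
        s = "".join(rng.choice(list("ACGT"), size=2000))
        locus = _locus(500, "AC", 12)  # 500..523
        cand = extract_flanks(locus, _genome(s), flank_len=100)
        assert len(cand.left_flank) == 100 and len(cand.right_flank) == 100
        assert cand.left_flank == s[399:499] and cand.right_flank == s[523:623]
        assert cand.designable

    def test_short_left_flank_not_designable(self):
        s = "ACGT" + "AC" * 8 + "T" * 300
        cand = extract_flanks(_locus(5, "AC", 8), _genome(s), flank_len=100)
        assert not cand.designable and "left flank too short" in cand.reject_reason
        assert len(cand.left_flank) == 4

    def test_n_run_blocks_design(self):
        s = "T" * 100 + "N" * 12 + "T" * 100 + "AC" * 8 + "G" * 250
        cand = extract_flanks(_locus(213, "AC", 8), _genome(s), flank_len=250)
        assert not cand.designable and "N run" in cand.reject_reason

    def test_flanks_never_overlap_repeat(self):
        s = "T" * 60 + "AC" * 10 + "G" * 60
        locus = _locus(61, "AC", 10)
        cand = extract_flanks(locus, _genome(s), flank_len=50)
        assert "AC" * 3 not in cand.left_flank + cand.right_flank

    def test_locus_outside_sequence_errors(self):
        with pytest.raises(ValueError):
            extract_flanks(_locus(95, "AC", 8), _genome("A" * 100))


def _template(rng, fwd_gc=0.5, product=150):
    """Build a template where a constructed primer pair yields `product` bp."""
    fwd = "".join(rng.permutation(list("ACGT" * 5)))  # 20-mer, 50% GC
    rev_site = "".join(rng.permutation(list("ACGT" * 5)))
    middle = "".join(rng.choice(list("AT"), size=product - 40))
    return fwd, revcomp(rev_site), fwd + middle + rev_site


class TestScreenPair:
    def test_constructed_pair_passes(self):
        rng = np.random.default_rng(2)
        fwd, rev, template = _template(rng, product=150)
        ok, failures = screen_pair(fwd, rev, template)
        assert ok, failures

    def test_short_primer_fails_on_length(self):
        rng = np.random.default_rng(3)
        fwd, rev, template = _template(rng)
        ok, failures = screen_pair(fwd[:16], rev, fwd[:16] + template)
        assert not ok and any("length 16" in f for f in failures)

    def test_product_outside_range_fails(self):
        rng = np.random.default_rng(4)
        fwd, rev, template = _template(rng, product=350)
        ok, failures = screen_pair(fwd, rev, template)
        assert not ok and any("product 350" in f for f in failures)

    def test_no_binding_site_reported(self):
        rng = np.random.default_rng(5)
        fwd, rev, template = _template(rng)
        ok, failures = screen_pair("ACGT" * 5, rev, template[40:])
        assert not ok and any("no binding site" in f for f in failures)

    def test_all_failures_listed_not_just_first(self):
        ok, failures = screen_pair("GC" * 8, "AT" * 20, "X")
        assert not ok and len(failures) >= 3

    def test_product_size_matches_string_search_oracle(self):
        rng = np.random.default_rng(6)
        fwd, rev, template = _template(rng, product=200)
        ok, failures = screen_pair(fwd, rev, template)
        assert ok
        # oracle: product = rev-binding end - fwd-binding start + 1
        f0 = template.index(fwd)
        r0 = template.index(revcomp(rev))
        assert (r0 + len(rev) - 1) - f0 + 1 == 200

    def test_relaxing_constraints_is_monotone(self):
        rng = np.random.default_rng(7)
        fwd, rev, template = _template(rng, product=350)
        tight = PrimerConstraints()
        loose = PrimerConstraints(product_range=(100, 500))
        ok_tight, _ = screen_pair(fwd, rev, template, tight)
        ok_loose, _ = screen_pair(fwd, rev, template, loose)
        assert not ok_tight and ok_loose


class TestMarkersPerChromosome:
    def test_frequency_per_mb(self, small_planted_genome):
        _, res = small_planted_genome
        from ssrmine.ssr_detect import scan_genome

        lengths = {s.seq_id: s.length_bp for s in res.genome}
        by_id = {s.seq_id: s for s in res.genome}
        loci = scan_genome(res.genome)
        cands = [extract_flanks(l, by_id[l.seq_id]) for l in loci]
        df = markers_per_chromosome(cands, lengths).set_index("seq_id")
        # planted genome is clean, spacious, N-free: every locus designable
        assert int(df["n_designable"].sum()) == len(loci)
        for seq_id, L in lengths.items():
            expected = df.loc[seq_id, "n_designable"] / (L / 1e6)
            assert df.loc[seq_id, "frequency"] == pytest.approx(expected)
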