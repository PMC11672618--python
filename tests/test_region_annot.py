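"""Exon / intron / intergenic partitioning and record classification."""

import pytest

from ssrmine.io_formats import AnnotationRecord, AnnotationSet
from ssrmine.region_annot import (
    build_region_index,
    classify_record,
    classify_records,
    region_distribution,
)
from ssrmine.ssr_detect import CompoundSSR, SSRLocus, canonical_class


def _ann(records):
    return AnnotationSet([AnnotationRecord(*r) for r in records])


def _locus(start, unit, n, seq_id="chr1"):
    return SSRLocus(seq_id, start, start + len(unit) * n - 1, unit,
                    canonical_class(unit), n, len(unit) * n)


SIMPLE = _ann([
    ("chr1", "gene", 101, 400, "+", "g1", None),
    ("chr1", "mRNA", 101, 400, "+", "m1", "g1"),
    ("chr1", "exon", 101, 200, "+", "e1", "m1"),
    ("chr1", "exon", 301, 400, "+", "e2", "m1"),
])


class TestBuildRegionIndex:
    def test_arithmetic_partition(self):
        index = build_region_index(SIMPLE, {"chr1": 1000})
        bp = index.category_bp("chr1")
        assert bp == {"exon": 200, "intron": 100, "intergenic": 700}

    def test_no_genes_all_intergenic(self):
        index = build_region_index(_ann([]), {"chr1": 500})
        assert index.category_bp("chr1") == {"exon": 0, "intron": 0, "intergenic": 500}

    def test_isoform_exon_union_takes_precedence(self):
        # isoform 2's exon covers isoform 1's intron: union is exonic
        ann = _ann([
            ("chr1", "gene", 101, 400, "+", "g1", None),
            ("chr1", "mRNA", 101, 400, "+", "m1", "g1"),
            ("chr1", "mRNA", 101, 400, "+", "m2", "g1"),
            ("chr1", "exon", 101, 200, "+", "e1", "m1"),
            ("chr1", "exon", 301, 400, "+", "e2", "m1"),
            ("chr1", "exon", 181, 320, "+", "e3", "m2"),
        ])
        index = build_region_index(ann, {"chr1": 1000})
        arr = index.base_category["chr1"]
        # brute-force per-base check against the exon union
        exon_bases = set(range(101, 201)) | set(range(301, 401)) | set(range(181, 321))
        for pos in range(1, 1001):
            expected = 2 if pos in exon_bases else (1 if 101 <= pos <= 400 else 0)
            assert arr[pos - 1] == expected

    def test_per_base_partition_covers_sequence_exactly(self, small_planted_genome):
        _, res = small_planted_genome
        lengths = {s.seq_id: s.length_bp for s in res.genome}
        index = build_region_index(res.annotation, lengths)
        for seq_id, L in lengths.items():
            assert sum(index.category_bp(seq_id).values()) == L

    def test_feature_beyond_end_clipped_with_warning(self):
        ann = _ann([
            ("chr1", "gene", 901, 1200, "+", "g1", None),
            ("chr1", "mRNA", 901, 1200, "+", "m1", "g1"),
            ("chr1", "exon", 901, 1200, "+", "e1", "m1"),
        ])
        with pytest.warns(UserWarning, match="clipped"):
            index = build_region_index(ann, {"chr1": 1000})
        assert index.category_bp("chr1")["exon"] == 100


class TestClassifyRecord:
    @pytest.fixture()
    def index(self):
        return build_region_index(SIMPLE, {"chr1": 1000})

    def test_wholly_exonic(self, index):
        a = classify_record(_locus(110, "AC", 6), index)
        assert a.category == "exon" and a.overlapping_gene_id == "g1"

    def test_wholly_intergenic(self, index):
        a = classify_record(_locus(500, "AC", 6), index)
        assert a.category == "intergenic" and a.overlapping_gene_id is None

    def test_straddler_takes_start_category(self, index):
        # starts in the intron (295), ends in the exon (306)
        a = classify_record(_locus(295, "AC", 6), index)
        assert a.category == "intron"

    def test_majority_overlap_rule(self, index):
        # 6 bp in intron, 6 bp in exon under majority; start rule says intron
        locus = _locus(293, "AC", 6)  # 293..304: intron 293..300 (8bp), exon 301..304
        assert classify_record(locus, index, "majority-overlap").category == "intron"
        locus2 = _locus(299, "AC", 6)  # 299..310: intron 2bp, exon 10bp
        assert classify_record(locus2, index, "majority-overlap").category == "exon"

    def test_unknown_seq_id_errors(self, index):
        with pytest.raises(KeyError):
            classify_record(_locus(1, "AC", 6, seq_id="chrX"), index)

    def test_compound_classified_once_by_start(self, index):
        m1, m2 = _locus(150, "AC", 6), _locus(210, "AAG", 5)
        comp = CompoundSSR("chr1", m1.start, m2.end, (m1, m2), (47,))
        assert classify_record(comp, index).category == "exon"


class TestRegionDistribution:
    def test_survey_shaped_counts(self):
        # the published region-by-period matrix reproduces its printed shares
        from ssrmine.reference import region_counts

        df = region_counts()
        total = int(df.values.sum())
        assert total == 226_573
        assert 100 * df["intron"].sum() / total == pytest.approx(56.91, abs=0.005)
        assert 100 * df["exon"].sum() / total == pytest.approx(8.55, abs=0.005)
        assert 100 * df["intergenic"].sum() / total == pytest.approx(34.54, abs=0.005)

    def test_all_intergenic(self):
        records = [_locus(1 + 100 * i, "AC", 6, seq_id="c") for i in range(5)]
        index = build_region_index(_ann([]), {"c": 1000})
        assignments = classify_records(records, index)
        dist = region_distribution(assignments, records)
        assert dist.loc["percentage", "intergenic"] == pytest.approx(100.0)
        assert dist.loc["all", "all"] == 5

    def test_compound_counts_once_and_margins_consistent(self):
        m1, m2 = _locus(500, "AC", 6), _locus(550, "AAG", 5)
        comp = CompoundSSR("chr1", m1.start, m2.end, (m1, m2), (37,))
        records = [comp, _locus(120, "AC", 6), _locus(320, "AAT", 5)]
        index = build_region_index(SIMPLE, {"chr1": 1000})
        assignments = classify_records(records, index)
        dist = region_distribution(assignments, records)
        assert dist.loc["all", "all"] == 3  # grand total = standalone + compound
        assert dist.loc["compound", "all"] == 1
        row_tot = dist.drop(index=["all", "percentage"])["all"].sum()
        assert row_tot == 3

    def test_planted_region_labels_recovered(self, tiny_planted_genome):
        _, res = tiny_planted_genome
        from ssrmine.ssr_detect import scan_genome

        lengths = {s.seq_id: s.length_bp for s in res.genome}
        index = build_region_index(res.annotation, lengths)
        loci = scan_genome(res.genome)
        truth = {(r.seq_id, int(r.start)): r.region for r in res.truth.itertuples()}
        for locus in loci:
            a = classify_record(locus, index)
            assert a.category == truth[(locus.seq_id, locus.start)]
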