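"""Assign every SSR record to exon / intron / intergenic space and compare
the recovered distribution with the planted region labels."""

from common import results_path, study_data

from ssrmine.io_formats import write_table
from ssrmine.region_annot import build_region_index, classify_records, region_distribution
from ssrmine.ssr_detect import merge_compound_genome, scan_genome


def main() -> None:
    _, res = study_data()
    loci = scan_genome(res.genome)
    lengths = {s.seq_id: s.length_bp for s in res.genome}
    index = build_region_index(res.annotation, lengths)

    bp = {k: 0 for k in ("exon", "intron", "intergenic")}
    for seq_id in lengths:
        for k, v in index.category_bp(seq_id).items():
            bp[k] += v
    total_bp = sum(bp.values())
    print("genome partition:",
          {k: f"{100 * v / total_bp:.2f}%" for k, v in bp.items()})

    compounds, standalone = merge_compound_genome(loci)
    records = sorted(standalone + compounds, key=lambda r: (r.seq_id, r.start))
    assignments = classify_records(records, index)
    dist = region_distribution(assignments, records)
    write_table(dist.reset_index(names="repeat"), results_path("04_region_distribution.tsv"),
                {"repeat": "s", "exon": "2f", "intergenic": "2f", "intron": "2f", "all": "2f"})
    print("region distribution (records):")
    print(dist.to_string())

    truth_by_key = {(r.seq_id, int(r.start)): r.region for r in res.truth.itertuples()}
    n_match = sum(
        a.category == truth_by_key[(r.seq_id, r.start)]
        for a, r in zip(assignments, records)
    )
    print(f"planted region labels recovered: {n_match}/{len(records)}")


if __name__ == "__main__":
    main()
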