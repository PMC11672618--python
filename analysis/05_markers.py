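"""Extract SSR flanks, screen marker candidates, and count designable
markers per chromosome."""

from common import results_path, study_data

from ssrmine.io_formats import write_table
from ssrmine.marker_design import extract_flanks, markers_per_chromosome
from ssrmine.ssr_detect import scan_genome


def main() -> None:
    _, res = study_data()
    loci = scan_genome(res.genome)
    by_id = {s.seq_id: s for s in res.genome}
    lengths = {s.seq_id: s.length_bp for s in res.genome}

    candidates = [extract_flanks(l, by_id[l.seq_id]) for l in loci]
    n_ok = sum(c.designable for c in candidates)
    print(f"{n_ok}/{len(candidates)} loci designable "
          f"(clean N-free background: all interior loci should pass)")
    reasons = {}
    for c in candidates:
        if not c.designable:
            reasons[c.reject_reason] = reasons.get(c.reject_reason, 0) + 1
    if reasons:
        print("rejections:", reasons)

    df = markers_per_chromosome(candidates, lengths)
    write_table(df, results_path("05_markers_per_chromosome.tsv"),
                {"seq_id": "s", "n_designable": "d", "frequency": "2f"})
    print(f"mean designable markers per chromosome: {df['n_designable'].mean():.1f} "
          f"({df['frequency'].mean():.2f} per Mb)")


if __name__ == "__main__":
    main()
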