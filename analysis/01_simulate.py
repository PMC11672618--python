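"""Generate the study genome and genotype panel, and verify the ground truth.

Writes the full FASTA/GFF3/truth to scratch/study_genome/ (large, run-time
only) and a per-chromosome truth summary to results/.
"""

from common import STUDY_SEED, results_path, scratch_path, study_data

from ssrmine.io_formats import write_table
from ssrmine.popgen import write_genotype_table
from ssrmine.synthetic_data import (
    generate_genotypes,
    study_genotype_spec,
    write_genome_outputs,
)


def main() -> None:
    spec, res = study_data()
    paths = write_genome_outputs(res, scratch_path("study_genome"))
    print(f"study genome: {spec.n_chromosomes} chromosomes x "
          f"{spec.chromosome_lengths[0]:,} bp, {len(res.truth)} planted SSRs (seed {STUDY_SEED})")
    print(f"  wrote {paths['fasta']}")

    summary = (
        res.truth.groupby("seq_id")
        .agg(n_planted=("start", "size"), total_bp=("length_bp", "sum"))
        .reset_index()
    )
    region_mix = res.truth["region"].value_counts(normalize=True).round(4)
    period_mix = res.truth["motif"].str.len().value_counts(normalize=True).sort_index().round(4)
    print(f"  region mix: {region_mix.to_dict()}")
    print(f"  period mix: {period_mix.to_dict()}")
    write_table(summary, results_path("01_truth_per_chromosome.tsv"),
                {"seq_id": "s", "n_planted": "d", "total_bp": "d"})

    gspec = study_genotype_spec(seed=STUDY_SEED)
    tables = generate_genotypes(gspec)
    gpath = scratch_path("study_genome/genotypes.tsv")
    write_genotype_table(tables, gpath)
    print(f"genotype panel: {len(tables)} loci x {gspec.n_individuals} individuals -> {gpath}")


if __name__ == "__main__":
    main()
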