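"""Marker polymorphism statistics on the simulated wild panel, plus the
published nine-marker reference panel for comparison."""

from common import STUDY_SEED, results_path

from ssrmine.io_formats import write_table
from ssrmine.popgen import (
    classify_informativeness,
    marker_stats,
    panel_dataframe,
    summarize_panel,
    transferability,
)
from ssrmine.reference import PRIMER_SCREEN, TRANSFER_SCHLEGELII, marker_panel
from ssrmine.synthetic_data import generate_genotypes, study_genotype_spec

PANEL_SCHEMA = {"locus": "s", "na": "4f", "ne": "4f", "ho": "4f", "he": "4f",
                "shannon_i": "4f", "pic": "4f"}


def main() -> None:
    spec = study_genotype_spec(seed=STUDY_SEED)
    tables = generate_genotypes(spec)
    stats = [marker_stats(t) for t in tables]
    df = panel_dataframe(stats)
    write_table(df, results_path("06_simulated_panel.tsv"), PANEL_SCHEMA)
    means, _, total_na = summarize_panel(stats)
    print(f"simulated panel ({len(stats)} loci, N = {spec.n_individuals}): "
          f"{total_na} alleles, mean Ne {means['ne']:.4f}, mean He {means['he']:.4f}, "
          f"mean PIC {means['pic']:.4f}; {classify_informativeness(stats)} loci with PIC > 0.5")

    ref = marker_panel()
    write_table(panel_dataframe(ref), results_path("06_reference_panel.tsv"), PANEL_SCHEMA)
    rmeans, _, rtotal = summarize_panel(ref)
    print(f"reference panel: {rtotal} alleles, mean Ne {rmeans['ne']:.4f}, "
          f"mean PIC {rmeans['pic']:.4f}; {classify_informativeness(ref)} with PIC > 0.5")

    amp, tot = TRANSFER_SCHLEGELII
    print(f"cross-species transferability (A. schlegelii): "
          f"{amp}/{tot} = {transferability([(str(i), i < amp) for i in range(tot)]):.2f}%")
    amp, tot = PRIMER_SCREEN
    print(f"primer screen success: {amp}/{tot} = "
          f"{transferability([(str(i), i < amp) for i in range(tot)]):.2f}%")


if __name__ == "__main__":
    main()
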