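"""Published reference numbers for the yellowfin seabream genome survey.

Small tables from the chromosome-level *Acanthopagrus latus* assembly
(GCA_904848185.1) SSR characterization: per-period genome tallies, the
exon/intron/intergenic distribution, and the nine-marker wild-panel
polymorphism statistics (N = 29 individuals). They serve as fixed inputs
for consistency checks (e.g. the Ne <-> He relation under Levene's
correction) and for proportion arithmetic, not as quantities this
package re-derives from sequence at desk scale.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .popgen import MarkerStats

#: Genotyped individuals behind the marker panel table.
PANEL_N = 29

#: Genome-wide totals: loci, SSR bp, and assembly size in Mb.
GENOME_N_SSRS = 318_862
GENOME_SSR_BP = 9_069_670
GENOME_SIZE_MB = 680.74

#: Compound records reported alongside the member-level tallies.
N_COMPOUND = 92_089

#: Most abundant motif class and its count.
TOP_MOTIF, TOP_MOTIF_N = "AC", 168_390

#: Cross-species amplification tallies: (amplified, tested).
TRANSFER_SCHLEGELII = (33, 37)
PRIMER_SCREEN = (38, 47)


def _read(name: str) -> pd.DataFrame:
    with resources.files("ssrmine.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def period_counts() -> pd.DataFrame:
    """Per-period locus and bp tallies for the reference genome."""
    return _read("alatus_period_counts.tsv")


def region_counts() -> pd.DataFrame:
    """Exon/intergenic/intron counts by repeat category (compound = one record)."""
    return _read("alatus_region_counts.tsv").set_index("repeat")


def marker_panel() -> list[MarkerStats]:
    """The nine-marker wild-panel statistics as MarkerStats records."""
    df = _read("alatus_marker_panel.tsv")
    return [
        MarkerStats(
            locus_id=r.locus,
            n=PANEL_N,
            na=int(r.na),
            ne=float(r.ne),
            ho=float(r.ho),
            he=float(r.he),
            shannon_i=float(r.shannon_i),
            pic=float(r.pic),
        )
        for r in df.itertuples()
    ]
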