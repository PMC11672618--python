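# Methods

## Repeat model and detection

A microsatellite locus is a maximal perfect tandem array of a primitive
(non-self-repeating) unit of 2–6 bp. Detection thresholds follow the MISA
parameterization used in fish genome surveys: a dinucleotide array must
contain ≥ 6 full units, tri- through hexanucleotide arrays ≥ 5. Only full
units count; a trailing partial unit neither extends the reported locus nor
its repeat number. Mononucleotide runs are never reported and never seed
loci of a larger period (a period-p window whose unit is non-primitive is
owned by the shorter period).

The scanner works per period p by marking positions where
`s[i] == s[i+p]` (both bases in {A,C,G,T}; N breaks the match, truncating a
run while keeping any threshold-passing prefix). Maximal match blocks
delimit perfectly periodic regions; every start inside a region whose
remaining full-unit count meets the threshold is a candidate run. Candidates
from all periods are then resolved greedily **leftmost-longest** (ties by
shorter period), which makes the output deterministic, coordinate-sorted,
and non-overlapping. Phase-shifted candidates matter: when the head of a
periodic region is claimed by another locus, the surviving suffix of the
region can still pass the threshold and must be reported — dropping them is
the one subtle way a fast scanner silently diverges from exhaustive search.
The test suite holds the scanner to *exact* agreement with a brute-force
oracle that enumerates every (start, period) pair by direct string
comparison, on repeat-enriched random sequences including N-containing ones.

Coordinates are 1-based inclusive everywhere (the shared convention of GFF3
and MISA tables). Soft-masked lowercase is uppercased and scanned; IUPAC
ambiguity codes other than N are degraded to N with a warning.

## Motif canonicalization

Two units describe the same motif when one is a cyclic rotation of the
other or of its reverse complement; the class is named by the
lexicographically smallest member (A<C<G<T) after reduction to the
primitive unit, so (ATAT)₈ ≡ (AT)₁₆ and (TCTC)₁₀ → class AG × 20. Under
this convention the reverse strand of an (ACT)ₙ array reads (AGT)ₙ, so
AGT/GTA/TAG join ACT/CTA/TAC in class ACT, while TGA/GAT/ATG — the
base-wise complements, sometimes loosely called the "complementary strand"
motifs — belong to class ATC. We follow the reverse-complement convention
because it reflects which arrays are physically the same locus read from
the other strand, and because it yields the canonical class names (e.g.
ATC) that genome surveys tabulate. Exhaustive enumeration gives class
universes of 4, 10, 33, 102, and 350 for periods 2–6; observed classes in
any scan are subsets.

## Compound merging

Consecutive loci on one sequence whose intervening gap
(`next.start − prev.end − 1`) is **strictly less than** 100 nt chain into
one compound record. The strict inequality follows the survey wording
("interval < 100 nt") even though MISA's own semantics are often stated as
≤; the window is exposed (`--max-gap`) for replication under either
reading. Landscape statistics count compound members individually (so
period and motif tallies conserve the scanner total); region tables count
a compound record once, as its own category.

## Landscape statistics

Frequency = loci / Mb and density = SSR bp / Mb with Mb = 10⁶ bp exactly.
The genome denominator defaults to the sum of scanned sequence lengths and
can be overridden (`--genome-size`): published genome-level frequency and
density for the reference assembly imply slightly different denominators
(680.74 Mb vs ≈ 685 Mb), an internal inconsistency of the source tables
that we document rather than resolve — both statistics are computed from
whichever denominator the user supplies. Pearson correlations of
chromosome size against SSR count/length/density use `scipy.stats.pearsonr`
and refuse zero-variance inputs.

## Region assignment

Each sequence is partitioned per base: the union of exon features (UTRs
included; isoform disagreements resolved in favour of exon) is exonic;
remaining bases within a gene span (gene record extended by its
transcripts) are intronic; the rest is intergenic. A record straddling a
boundary takes the category of its **start base** — a single-point rule
that is deterministic and order-independent; a `majority-overlap`
alternative is available. Features extending past the sequence end are
clipped with a warning.

## Marker screening

Flanks of 250 bp (default; the 100–300 bp product window fits inside) are
extracted abutting the repeat, never overlapping it. A candidate is
non-designable when either flank is shorter than the minimum primer length
(18 nt) or contains an N run ≥ 10. Primer pairs are screened against
length 18–30, Tm 50–60 °C, GC 40–60 %, product 100–300 bp; every violated
constraint is listed, not just the first. Tm uses the GC-fraction formula
`64.9 + 41(n_GC − 16.4)/L` for oligos ≥ 14 nt and the Wallace rule
`2(A+T) + 4(G+C)` below; both are deterministic and stated rather than
thermodynamically sophisticated — screening feasibility, not design
optimization, is the deliverable, and product size comes from exact string
match of the forward primer and the reverse complement of the reverse
primer (first binding site, with a multiple-binding warning).

## Polymorphism statistics

With p̂ᵢ the allele relative frequencies over the 2N gene copies of the N
fully genotyped individuals at a locus (missing or half-called individuals
are dropped from that locus; alleles are integer fragment lengths, no
binning or stutter correction):

* Na = number of distinct alleles; Ne = 1/Σp̂ᵢ²
* Ho = fraction of heterozygous individuals
* He = (2N/(2N−1)) (1 − Σp̂ᵢ²) — Levene's unbiased estimator, the Popgene
  convention. The published nine-marker table is mutually consistent
  between its Ne and He columns only under this correction (max deviation
  5 × 10⁻⁵ across rows at N = 29), which is how the convention was pinned.
  The uncorrected gene diversity is available by flag. Note the corrected
  estimator is unbiased **for** the population quantity 1 − Σp²: the
  (2N)/(2N−1) factor exactly cancels the downward sampling bias of Σp̂².
* I = −Σ p̂ᵢ ln p̂ᵢ; PIC = 1 − Σp̂ᵢ² − ΣᵢΣⱼ>ᵢ 2p̂ᵢ²p̂ⱼ² (Botstein), with
  PIC > 0.5 (strict) counting as highly informative.

A monomorphic locus yields (Na, Ne, Ho, He, I, PIC) = (1, 1, 0, 0, 0, 0).
Panel summaries report arithmetic means, n−1 standard deviations, and ΣNa;
single-marker panels report a standard deviation of 0. Transferability is
100 × amplified/tested, rounded to 2 dp.

## Synthetic data generator

The generator emulates the study conditions of a chromosome-level marine
fish assembly at desk scale. Defaults: 24 chromosomes × 200 kb carrying
~2,000 planted SSRs whose period mix (76.9 / 15.8 / 5.7 / 1.2 / 0.4 % for
periods 2–6), dinucleotide motif weights (AC 69 %, AG 21 %, AT 10 %, CG
rare), repeat numbers (threshold + geometric(0.30), capped at 40 — mainly
5–12), and region mix (intron 56.9 %, intergenic 34.5 %, exon 8.6 %) echo
the published survey; background GC fraction 0.41; seed 42.

Background is drawn i.i.d. per base and *screened*: any chance run the
scanner would report is re-randomized until the background is repeat-free,
so precision/recall against the truth table are exact by construction, not
approximations. Planted tracts are written into region-appropriate
intervals of a deterministic gene tiling (3 kb intergenic block + three
400 bp exons separated by 1.2 kb introns), spaced ≥ 200 nt apart (beyond
the compound window) and flanked by bases chosen to break periodic
extension on either side, preventing coordinate drift from phase shifts.
A final scan-and-scrub loop guarantees the scanner output equals the truth
table exactly. Genotypes are Hardy–Weinberg draws from specified
allele-frequency vectors (two independent draws per individual), with
per-individual missingness; the default panel is nine loci with 3–10
alleles at N = 29.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: imperfect/interrupted repeats, indel
polymorphism and stutter, N/gap tracts, isoform complexity, GC structure
beyond a flat fraction, and linkage between loci. On a real assembly the
scanner's thresholds and merge rule still apply, but precision/recall
cannot be 1 by construction and compound records are common.

## Numerical and design choices

* All statistics are kept at full precision internally; fixed-point
  rendering (2 dp for frequencies/densities, 4 dp for popgen statistics)
  happens only when tables are written.
* Motif ranking breaks count ties lexicographically; overlap resolution
  breaks length ties by shorter period — both purely for determinism.
* The single CLI seed drives all randomness through one `numpy` generator;
  identical spec + seed gives byte-identical FASTA/GFF3/TSV outputs.
* Problem sizes in the analysis drivers and acceptance script (24 × 200 kb
  genome, 1,000 × 2 kb oracle sequences, 200 Hardy–Weinberg replicates)
  are the package's desk-scale study conditions; the full-assembly scan is
  the same code path via `ssrmine scan --fasta <assembly>`.

## Known limitations

* No imperfect-repeat model; a single mismatch splits an array.
* Region assignment is strandless and has no promoter/UTR-specific
  categories.
* Tm is a composition formula, not a nearest-neighbour model; real primer
  design should re-check candidates with a thermodynamic engine.
* He/PIC assume autosomal codominant markers in a single random-mating
  sample; no null-allele or F-statistics machinery is included.
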