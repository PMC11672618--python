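"""Seeded synthetic genomes with planted SSRs, annotations, and genotypes.

The generator stands in for a real chromosome-level fish assembly so
every pipeline stage can be verified against exact ground truth on a
desk-scale problem. Background sequence is drawn per-base i.i.d. at a
chosen GC fraction and then *screened*: any run that would register as an
SSR by chance is re-randomized until the background is repeat-free, so
precision and recall against the truth table are exactly measurable.
Planted repeats are written into the clean background inside the
requested genomic region (exon, intron, or intergenic), with flanking
bases adjusted so the perfect run neither extends nor phase-shifts.

Gene models are laid out as a deterministic tiling (intergenic block,
then a three-exon gene) so exon/intron/intergenic space is abundant and
its per-base partition is known by construction.

What this emulates: chromosome count and scale, the heavy skew toward
dinucleotide (especially AC) repeats, repeat numbers mainly in the 5-12
range, and the region mix observed in fish genomes. What it does not:
imperfect/interrupted repeats, flanking indel polymorphism, sequencing
gaps (N tracts), isoform complexity, and base composition structure
beyond a flat GC fraction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AnnotationRecord,
    AnnotationSet,
    GenomeSequence,
    write_fasta,
    write_gff3,
)
from .ssr_detect import (
    DEFAULT_THRESHOLDS,
    canonical_class,
    minimal_period,
    revcomp,
    scan_perfect_ssrs,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class PlacementError(RuntimeError):
    """Raised when planted loci cannot be placed under the spacing
    constraints; try longer chromosomes or fewer loci."""


@dataclass(frozen=True)
class PlantedSSR:
    motif: str  # canonical class representative
    n_repeats: int
    region: str  # exon | intron | intergenic

    def __post_init__(self) -> None:
        unit = self.motif
        if minimal_period(unit) != unit:
            raise ValueError(f"planted motif {unit!r} is not primitive")
        period = len(unit)
        need = DEFAULT_THRESHOLDS.get(period)
        if need is None:
            raise ValueError(f"planted motif period {period} outside 2-6")
        if self.n_repeats < need:
            raise ValueError(
                f"planted ({unit}){self.n_repeats} below detection threshold {need}"
            )
        if self.region not in {"exon", "intron", "intergenic"}:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class SyntheticGenomeSpec:
    chromosome_lengths: list[int]
    planted: list[PlantedSSR]
    gc_fraction: float = 0.41
    min_spacing: int = 200  # > compound window so planted loci stay standalone
    seed: int = 42

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)


@dataclass
class GenotypeSimSpec:
    loci: list[tuple[str, list[int], list[float]]]  # (locus_id, alleles, freqs)
    n_individuals: int = 29
    missing_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need N >= 2 individuals")
        for locus_id, alleles, freqs in self.loci:
            if len(alleles) != len(freqs):
                raise ValueError(f"{locus_id}: alleles and freqs differ in length")
            if any(f < 0 for f in freqs):
                raise ValueError(f"{locus_id}: negative allele frequency")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError(f"{locus_id}: frequencies sum to {sum(freqs)}, not 1")


@dataclass
class SyntheticGenome:
    genome: list[GenomeSequence]
    annotation: AnnotationSet
    truth: pd.DataFrame  # seq_id, start, end, motif, unit, n_repeats, length_bp, region


# ---------------------------------------------------------------- gene layout

_INTERGENIC_BLOCK = 3000
_EXON_LEN = 400
_INTRON_LEN = 1200
_GENE_PARTS = [("exon", _EXON_LEN), ("intron", _INTRON_LEN), ("exon", _EXON_LEN), ("intron", _INTRON_LEN), ("exon", _EXON_LEN)]
_GENE_LEN = sum(L for _, L in _GENE_PARTS)


def _layout_chromosome(seq_id: str, length: int) -> tuple[list[AnnotationRecord], dict[str, list[tuple[int, int]]]]:
    """Deterministic gene tiling; returns records and per-category intervals."""
    records: list[AnnotationRecord] = []
    intervals: dict[str, list[tuple[int, int]]] = {"exon": [], "intron": [], "intergenic": []}
    pos = 1
    gene_i = 0
    while pos + _INTERGENIC_BLOCK + _GENE_LEN - 1 <= length:
        intervals["intergenic"].append((pos, pos + _INTERGENIC_BLOCK - 1))
        gstart = pos + _INTERGENIC_BLOCK
        gene_i += 1
        gid = f"{seq_id}.g{gene_i}"
        mid = f"{gid}.t1"
        records.append(AnnotationRecord(seq_id, "gene", gstart, gstart + _GENE_LEN - 1, "+", gid, None))
        records.append(AnnotationRecord(seq_id, "mRNA", gstart, gstart + _GENE_LEN - 1, "+", mid, gid))
        part_pos = gstart
        exon_i = 0
        for kind, plen in _GENE_PARTS:
            iv = (part_pos, part_pos + plen - 1)
            intervals[kind].append(iv)
            if kind == "exon":
                exon_i += 1
                records.append(AnnotationRecord(seq_id, "exon", iv[0], iv[1], "+", f"{mid}.e{exon_i}", mid))
            part_pos += plen
        pos = gstart + _GENE_LEN
    if pos <= length:
        intervals["intergenic"].append((pos, length))
    return records, intervals


# ------------------------------------------------------------- background gen


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _scrub_chance_ssrs(
    arr: np.ndarray,
    rng: np.random.Generator,
    gc: float,
    seq_id: str,
    protected: np.ndarray | None = None,
    max_iter: int = 60,
) -> None:
    """Re-randomize unprotected spans until the scanner finds nothing
    outside the protected (planted) positions. Mutates `arr`."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for _ in range(max_iter):
        seq = GenomeSequence(seq_id, _decode(arr), arr.size)
        dirty = False
        for locus in scan_perfect_ssrs(seq):
            i0, i1 = locus.start - 1, locus.end  # 0-based half-open
            span = np.arange(i0, i1)
            if protected is not None:
                span = span[~protected[span]]
            if span.size == 0:
                continue  # wholly protected: a planted locus, leave it
            arr[span] = rng.choice(_BASES, size=span.size, p=p)
            dirty = True
        if not dirty:
            return
    raise RuntimeError(f"{seq_id}: background scrubbing did not converge")


# ----------------------------------------------------------------- generation


def _unit_variants(canonical: str) -> list[str]:
    rc = revcomp(canonical)
    var = {canonical[i:] + canonical[:i] for i in range(len(canonical))}
    var |= {rc[i:] + rc[:i] for i in range(len(rc))}
    return sorted(var)


def _place_loci(
    rng: np.random.Generator,
    planted: Sequence[PlantedSSR],
    intervals: dict[str, list[tuple[int, int]]],
    min_spacing: int,
    max_attempts: int = 400,
) -> list[tuple[int, int, PlantedSSR]]:
    """Choose non-overlapping start positions honoring region and spacing."""
    placed: list[tuple[int, int, PlantedSSR]] = []
    edge_pad = 2  # room for the boundary-break bases
    for spec in planted:
        length = len(spec.motif) * spec.n_repeats
        cands = [
            (s, e)
            for s, e in intervals[spec.region]
            if (e - s + 1) >= length + 2 * edge_pad
        ]
        if not cands:
            raise PlacementError(
                f"no {spec.region} interval can hold a {length} bp repeat; use longer chromosomes"
            )
        weights = np.array([e - s + 1 - length - 2 * edge_pad + 1 for s, e in cands], dtype=float)
        weights /= weights.sum()
        ok = False
        for _ in range(max_attempts):
            s, e = cands[rng.choice(len(cands), p=weights)]
            start = int(rng.integers(s + edge_pad, e - edge_pad - length + 2))
            end = start + length - 1
            if all(
                start > pe + min_spacing or end < ps - min_spacing
                for ps, pe, _ in placed
            ):
                placed.append((start, end, spec))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place ({spec.motif}){spec.n_repeats} in {spec.region} "
                f"after {max_attempts} attempts; use longer chromosomes or fewer loci"
            )
    return sorted(placed)


def generate_genome(spec: SyntheticGenomeSpec) -> SyntheticGenome:
    """Generate (genome, annotation, truth table) for a planted-SSR genome.

    Deterministic for a fixed spec and seed. The scanner is guaranteed to
    recover exactly the truth table: after planting, each chromosome is
    re-scanned and any discrepancy outside the planted spans is scrubbed.
    """
    rng = np.random.default_rng(spec.seed)
    # round-robin assignment of planted loci to chromosomes
    per_chrom: list[list[PlantedSSR]] = [[] for _ in spec.chromosome_lengths]
    for i, p in enumerate(spec.planted):
        per_chrom[i % spec.n_chromosomes].append(p)

    genome: list[GenomeSequence] = []
    ann_records: list[AnnotationRecord] = []
    truth_rows: list[dict] = []
    for ci, length in enumerate(spec.chromosome_lengths):
        seq_id = f"chr{ci + 1}"
        records, intervals = _layout_chromosome(seq_id, length)
        ann_records.extend(records)
        arr = _random_background(rng, length, spec.gc_fraction)
        placements = _place_loci(rng, per_chrom[ci], intervals, spec.min_spacing)

        protected = np.zeros(length, dtype=bool)
        for start, end, pspec in placements:
            unit = _unit_variants(pspec.motif)[rng.integers(len(_unit_variants(pspec.motif)))]
            period = len(unit)
            tract = np.frombuffer((unit * pspec.n_repeats).encode("ascii"), dtype=np.uint8)
            arr[start - 1 : end] = tract
            # break periodic extension on both sides:
            # left neighbour must differ from unit's last base, right from its first
            left_forbidden = ord(unit[-1])
            right_forbidden = ord(unit[0])
            if start >= 2 and arr[start - 2] == left_forbidden:
                arr[start - 2] = rng.choice(_BASES[_BASES != left_forbidden])
            if end < length and arr[end] == right_forbidden:
                arr[end] = rng.choice(_BASES[_BASES != right_forbidden])
            protected[start - 1 : end] = True
            if start >= 2:
                protected[start - 2] = True
            if end < length:
                protected[end] = True
            truth_rows.append(
                {
                    "seq_id": seq_id,
                    "start": start,
                    "end": end,
                    "motif": pspec.motif,
                    "unit": unit,
                    "n_repeats": pspec.n_repeats,
                    "length_bp": period * pspec.n_repeats,
                    "region": pspec.region,
                }
            )
        _scrub_chance_ssrs(arr, rng, spec.gc_fraction, seq_id, protected)
        genome.append(GenomeSequence(seq_id, _decode(arr), length))

    truth = pd.DataFrame(
        truth_rows,
        columns=["seq_id", "start", "end", "motif", "unit", "n_repeats", "length_bp", "region"],
    ).sort_values(["seq_id", "start"], kind="stable").reset_index(drop=True)
    return SyntheticGenome(genome, AnnotationSet(ann_records), truth)


def write_genome_outputs(result: SyntheticGenome, outdir: str | os.PathLike) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fasta"),
        "gff3": os.path.join(outdir, "annotation.gff3"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_fasta(result.genome, paths["fasta"])
    write_gff3(result.annotation, paths["gff3"])
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ----------------------------------------------------------------- genotypes


def generate_genotypes(spec: GenotypeSimSpec):
    """Hardy-Weinberg genotype tables: each individual's two alleles are
    drawn independently from the locus frequency vector; missingness is
    applied per individual x locus."""
    from .popgen import GenotypeTable

    rng = np.random.default_rng(spec.seed)
    samples = [f"ind{i + 1}" for i in range(spec.n_individuals)]
    tables: list[GenotypeTable] = []
    for locus_id, alleles, freqs in spec.loci:
        a = rng.choice(alleles, size=spec.n_individuals, p=freqs)
        b = rng.choice(alleles, size=spec.n_individuals, p=freqs)
        miss = rng.random(spec.n_individuals) < spec.missing_rate
        genos = tuple(
            (s, None, None) if m else (s, int(x), int(y))
            for s, x, y, m in zip(samples, a, b, miss)
        )
        tables.append(GenotypeTable(locus_id=locus_id, individuals=genos))
    return tables


# ------------------------------------------------------------ fixtures/specs


def generate_compound_fixture(gap: int, seed: int = 42) -> tuple[GenomeSequence, pd.DataFrame]:
    """Two threshold-passing SSRs separated by exactly `gap` repeat-free nt.

    (AC)8 then (AAG)6, with 150 nt clean pads on both sides; the truth
    table carries both loci so the compound-merging boundary (< 100 nt)
    can be probed exactly.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    pad = 150
    unit1, n1 = "AC", 8
    unit2, n2 = "AAG", 6
    len1, len2 = len(unit1) * n1, len(unit2) * n2
    total = pad + len1 + gap + len2 + pad
    arr = _random_background(rng, total, 0.41)
    s1 = pad + 1
    e1 = s1 + len1 - 1
    s2 = e1 + gap + 1
    e2 = s2 + len2 - 1
    arr[s1 - 1 : e1] = np.frombuffer((unit1 * n1).encode(), dtype=np.uint8)
    arr[s2 - 1 : e2] = np.frombuffer((unit2 * n2).encode(), dtype=np.uint8)
    protected = np.zeros(total, dtype=bool)
    protected[s1 - 1 : e1] = True
    protected[s2 - 1 : e2] = True
    # break periodic extension, but never by touching the other tract
    for (s, e, unit) in ((s1, e1, unit1), (s2, e2, unit2)):
        if not protected[s - 2]:
            if arr[s - 2] == ord(unit[-1]):
                arr[s - 2] = rng.choice(_BASES[_BASES != ord(unit[-1])])
            protected[s - 2] = True
        if e < total and not protected[e]:
            if arr[e] == ord(unit[0]):
                arr[e] = rng.choice(_BASES[_BASES != ord(unit[0])])
            protected[e] = True
    _scrub_chance_ssrs(arr, rng, 0.41, "fixture", protected)
    seq = GenomeSequence("fixture", _decode(arr), total)
    truth = pd.DataFrame(
        [
            {"seq_id": "fixture", "start": s1, "end": e1, "motif": canonical_class(unit1).canonical,
             "unit": unit1, "n_repeats": n1, "length_bp": len1, "region": "intergenic"},
            {"seq_id": "fixture", "start": s2, "end": e2, "motif": canonical_class(unit2).canonical,
             "unit": unit2, "n_repeats": n2, "length_bp": len2, "region": "intergenic"},
        ]
    )
    return seq, truth


# Study-scale defaults: 24 chromosomes x 200 kb with ~2,000 planted SSRs whose
# period, motif, repeat-number and region mixes echo a chromosome-level marine
# fish assembly (dinucleotide-heavy, AC dominant, repeat numbers mainly 5-12,
# intron > intergenic > exon).
_PERIOD_MIX = {2: 0.769, 3: 0.158, 4: 0.057, 5: 0.012, 6: 0.004}
_DI_WEIGHTS = {"AC": 0.687, "AG": 0.213, "AT": 0.098, "CG": 0.002}
_REGION_MIX = {"intron": 0.569, "intergenic": 0.345, "exon": 0.086}


def study_genome_spec(
    seed: int = 42,
    n_chromosomes: int = 24,
    chromosome_length: int = 200_000,
    n_loci: int = 2000,
) -> SyntheticGenomeSpec:
    """The default desk-scale study genome (see module docstring)."""
    from .ssr_detect import enumerate_motif_classes

    rng = np.random.default_rng(seed)
    periods = list(_PERIOD_MIX)
    pprob = np.array([_PERIOD_MIX[p] for p in periods])
    pprob /= pprob.sum()
    class_pool = {p: sorted(m.canonical for m in enumerate_motif_classes(p)) for p in periods}
    di = list(_DI_WEIGHTS)
    dprob = np.array([_DI_WEIGHTS[m] for m in di])
    dprob /= dprob.sum()
    regions = list(_REGION_MIX)
    rprob = np.array([_REGION_MIX[r] for r in regions])
    rprob /= rprob.sum()
    planted = []
    for _ in range(n_loci):
        p = periods[rng.choice(len(periods), p=pprob)]
        if p == 2:
            motif = di[rng.choice(len(di), p=dprob)]
        else:
            motif = class_pool[p][rng.integers(len(class_pool[p]))]
        floor = DEFAULT_THRESHOLDS[p]
        n_rep = int(min(floor + rng.geometric(0.30) - 1, 40))
        region = regions[rng.choice(len(regions), p=rprob)]
        planted.append(PlantedSSR(motif, n_rep, region))
    return SyntheticGenomeSpec(
        chromosome_lengths=[chromosome_length] * n_chromosomes,
        planted=planted,
        seed=seed,
    )


def study_genotype_spec(seed: int = 42, n_individuals: int = 29) -> GenotypeSimSpec:
    """A nine-locus marker panel emulating a wild marine fish sample:
    3-10 alleles per locus with skewed frequency vectors."""
    rng = np.random.default_rng(seed)
    loci = []
    na_per_locus = [8, 10, 9, 6, 4, 3, 8, 7, 7]
    for i, na in enumerate(na_per_locus):
        alleles = [150 + 10 * i + 2 * k for k in range(na)]
        raw = rng.dirichlet(np.ones(na) * 1.2)
        freqs = (raw / raw.sum()).tolist()
        freqs[-1] = 1.0 - sum(freqs[:-1])  # exact unit sum
        loci.append((f"sim{i + 1}", alleles, freqs))
    return GenotypeSimSpec(loci=loci, n_individuals=n_individuals, seed=seed)


# ----------------------------------------------------------------- JSON specs


def genome_spec_from_json(path: str | os.PathLike) -> SyntheticGenomeSpec:
    with open(path) as fh:
        d = json.load(fh)
    planted = [PlantedSSR(p["motif"], p["n_repeats"], p["region"]) for p in d["planted"]]
    return SyntheticGenomeSpec(
        chromosome_lengths=list(d["chromosome_lengths"]),
        planted=planted,
        gc_fraction=d.get("gc_fraction", 0.41),
        min_spacing=d.get("min_spacing", 200),
        seed=d.get("seed", 42),
    )


def genotype_spec_from_json(path: str | os.PathLike) -> GenotypeSimSpec:
    with open(path) as fh:
        d = json.load(fh)
    loci = [(l["locus_id"], list(l["alleles"]), list(l["freqs"])) for l in d["loci"]]
    return GenotypeSimSpec(
        loci=loci,
        n_individuals=d.get("n_individuals", 29),
        missing_rate=d.get("missing_rate", 0.0),
        seed=d.get("seed", 42),
    )
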