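"""Per-marker polymorphism statistics from microsatellite genotype tables.

Statistics follow the conventions of the classic marker-evaluation tools:

* Na — observed number of alleles.
* Ne — effective number of alleles, ``1 / sum(p_i^2)``.
* Ho — observed heterozygosity, fraction of heterozygous individuals.
* He — unbiased expected heterozygosity with Levene's small-sample
  correction, ``(2N / (2N - 1)) * (1 - sum(p_i^2))`` (the Popgene
  convention; the uncorrected gene diversity is available via a flag).
* I  — Shannon's information index, ``-sum(p_i * ln p_i)``.
* PIC — polymorphism information content (Botstein),
  ``1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``.

Alleles are integer fragment lengths as called from capillary
electrophoresis traces; no binning or stutter correction is applied.
Missing genotypes drop the individual from that locus's N.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = None

Genotype = tuple[str, object, object]  # (sample_id, allele_a, allele_b)


@dataclass(frozen=True)
class GenotypeTable:
    locus_id: str
    individuals: tuple[Genotype, ...]

    def called(self) -> list[tuple[str, int, int]]:
        """Individuals with both alleles present; partial calls are missing."""
        out = []
        for sample, a, b in self.individuals:
            if a is None or b is None:
                continue
            out.append((sample, int(a), int(b)))
        return out


@dataclass(frozen=True)
class MarkerStats:
    locus_id: str
    n: int
    na: int
    ne: float
    ho: float
    he: float
    shannon_i: float
    pic: float


class AllMissingError(ValueError):
    pass


def allele_frequencies(table: GenotypeTable) -> dict[int, float]:
    """Allele relative frequencies over the 2N observed allele copies."""
    called = table.called()
    if not called:
        raise AllMissingError(f"{table.locus_id}: no called individuals")
    counts: dict[int, int] = {}
    for _, a, b in called:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    total = 2 * len(called)
    return {allele: c / total for allele, c in sorted(counts.items())}


def _pic(freqs: Sequence[float]) -> float:
    p = np.asarray(freqs, dtype=float)
    sum_p2 = float(np.sum(p**2))
    cross = 0.0
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            cross += 2.0 * p[i] ** 2 * p[j] ** 2
    return 1.0 - sum_p2 - cross


def marker_stats(table: GenotypeTable, unbiased_he: bool = True) -> MarkerStats:
    """All Table-style statistics for one locus.

    Requires N >= 2 when the unbiased (Levene-corrected) He is requested.
    A monomorphic locus yields Ne = 1 and Ho = He = I = PIC = 0.
    """
    called = table.called()
    if not called:
        raise AllMissingError(f"{table.locus_id}: no called individuals")
    n = len(called)
    if unbiased_he and n < 2:
        raise ValueError(f"{table.locus_id}: unbiased He undefined for N < 2")
    freqs = allele_frequencies(table)
    p = np.array(list(freqs.values()))
    sum_p2 = float(np.sum(p**2))
    ne = 1.0 / sum_p2
    ho = sum(1 for _, a, b in called if a != b) / n
    he = 1.0 - sum_p2
    if unbiased_he:
        he *= (2 * n) / (2 * n - 1)
    shannon = float(-np.sum(p * np.log(p)))
    return MarkerStats(
        locus_id=table.locus_id,
        n=n,
        na=len(freqs),
        ne=ne,
        ho=ho,
        he=he,
        shannon_i=shannon,
        pic=_pic(list(freqs.values())),
    )


_STAT_COLS = ["na", "ne", "ho", "he", "shannon_i", "pic"]


def summarize_panel(
    stats: Sequence[MarkerStats],
) -> tuple[dict[str, float], dict[str, float], int]:
    """Panel means, sample (n-1) standard deviations, and total alleles.

    With a single marker the standard deviations are reported as 0.0
    (flagged by nan-free output with n=1 visible to the caller).
    """
    if not stats:
        raise ValueError("empty marker panel")
    df = pd.DataFrame([s.__dict__ for s in stats])
    means = {c: float(df[c].mean()) for c in _STAT_COLS}
    if len(stats) > 1:
        sds = {c: float(df[c].std(ddof=1)) for c in _STAT_COLS}
    else:
        sds = {c: 0.0 for c in _STAT_COLS}
    return means, sds, int(df["na"].sum())


def classify_informativeness(stats: Sequence[MarkerStats], threshold: float = 0.5) -> int:
    """Number of markers with PIC strictly above the threshold
    (PIC > 0.5 is the conventional 'highly informative' cut)."""
    return sum(1 for s in stats if s.pic > threshold)


def transferability(results: Sequence[tuple[str, bool]]) -> float:
    """Percentage of loci that amplified, to 2 decimal places."""
    if not results:
        raise ValueError("no loci")
    pct = 100.0 * sum(1 for _, ok in results if ok) / len(results)
    return round(pct, 2)


def read_genotype_table(path: str | os.PathLike) -> list[GenotypeTable]:
    """Read a wide genotype TSV: sample_id, then one column per locus.

    Cells are "a/b" with integer fragment lengths, "." (or empty) for
    missing; a partial call like "171/." is treated as missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    tables = []
    for locus in df.columns[1:]:
        genos: list[Genotype] = []
        for sample, cell in zip(df["sample_id"], df[locus]):
            a = b = None
            if isinstance(cell, str) and cell.strip() not in {"", "."}:
                parts = cell.strip().split("/")
                if len(parts) == 2 and all(p.strip().isdigit() for p in parts):
                    a, b = int(parts[0]), int(parts[1])
            genos.append((sample, a, b))
        tables.append(GenotypeTable(locus_id=locus, individuals=tuple(genos)))
    return tables


def write_genotype_table(tables: Iterable[GenotypeTable], path: str | os.PathLike) -> None:
    tables = list(tables)
    samples = [g[0] for g in tables[0].individuals]
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(t.locus_id for t in tables) + "\n")
        for i, sample in enumerate(samples):
            cells = []
            for t in tables:
                _, a, b = t.individuals[i]
                cells.append("." if a is None or b is None else f"{a}/{b}")
            fh.write(sample + "\t" + "\t".join(cells) + "\n")


def panel_dataframe(stats: Sequence[MarkerStats]) -> pd.DataFrame:
    """Marker rows plus mean and st.dev summary rows, Table-style."""
    means, sds, total_na = summarize_panel(stats)
    df = pd.DataFrame(
        [
            {
                "locus": s.locus_id,
                "na": s.na,
                "ne": s.ne,
                "ho": s.ho,
                "he": s.he,
                "shannon_i": s.shannon_i,
                "pic": s.pic,
            }
            for s in stats
        ]
    )
    df.loc[len(df)] = {"locus": "mean", "na": means["na"], **{k: means[k] for k in _STAT_COLS if k != "na"}}
    df.loc[len(df)] = {"locus": "st_dev", "na": sds["na"], **{k: sds[k] for k in _STAT_COLS if k != "na"}}
    return df
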