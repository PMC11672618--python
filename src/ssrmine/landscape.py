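"""Genome- and chromosome-level SSR landscape statistics.

Frequency is reported as loci/Mb and density as bp/Mb (Mb = 1e6 bp
exactly), the units used throughout fish genome SSR surveys. Compound
members are counted individually in all landscape statistics; compound
records are tallied separately where requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ssr_detect import SSRLocus

MB = 1_000_000


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested on a zero-variance vector."""


@dataclass(frozen=True)
class ChromosomeStats:
    seq_id: str
    size_mb: float
    n_ssrs: int
    total_ssr_bp: int
    frequency: float  # loci/Mb
    density: float  # bp/Mb


def ssr_length(period: int, n_repeats: int) -> int:
    """Length of a perfect SSR in bp: unit length x repeat count.

    (AC)12 -> 2 x 12 = 24 bp.
    """
    if period not in range(2, 7):
        raise ValueError(f"period {period} outside 2-6")
    if n_repeats < 1:
        raise ValueError(f"n_repeats {n_repeats} < 1")
    return period * n_repeats


def summarize_sequence(
    loci: Sequence[SSRLocus], size_bp: int, seq_id: str = "genome"
) -> ChromosomeStats:
    """Aggregate count, total bp, frequency and density for one sequence.

    Values are kept at full precision; rounding to 2 dp happens only when
    tables are written.
    """
    if size_bp <= 0:
        raise ValueError(f"size_bp must be positive, got {size_bp}")
    n = len(loci)
    total_bp = sum(l.length_bp for l in loci)
    size_mb = size_bp / MB
    return ChromosomeStats(
        seq_id=seq_id,
        size_mb=size_mb,
        n_ssrs=n,
        total_ssr_bp=total_bp,
        frequency=n / size_mb,
        density=total_bp / size_mb,
    )


def summarize_genome(
    loci_by_seq: Mapping[str, Sequence[SSRLocus]],
    seq_lengths: Mapping[str, int],
    genome_size_bp: int | None = None,
) -> tuple[list[ChromosomeStats], ChromosomeStats]:
    """Per-sequence stats plus a genome-level aggregate.

    `genome_size_bp` overrides the genome denominator (default: sum of the
    scanned sequence lengths).
    """
    per_seq = [
        summarize_sequence(loci_by_seq.get(s, []), seq_lengths[s], s) for s in seq_lengths
    ]
    all_loci = [l for s in seq_lengths for l in loci_by_seq.get(s, [])]
    denom = genome_size_bp if genome_size_bp is not None else sum(seq_lengths.values())
    return per_seq, summarize_sequence(all_loci, denom, "genome")


def period_breakdown_from_counts(
    counts: Mapping[int, int],
    total_bp: Mapping[int, int] | None = None,
    size_bp: int | None = None,
) -> pd.DataFrame:
    """Per-period summary table from precomputed per-period tallies."""
    periods = sorted(counts)
    total = sum(counts.values())
    rows = []
    for p in periods:
        row: dict = {
            "period": p,
            "n": counts[p],
            "proportion_pct": 100.0 * counts[p] / total if total else 0.0,
        }
        if total_bp is not None:
            row["total_bp"] = total_bp.get(p, 0)
        if size_bp is not None:
            row["frequency"] = counts[p] / (size_bp / MB)
            if total_bp is not None:
                row["density"] = total_bp.get(p, 0) / (size_bp / MB)
        rows.append(row)
    return pd.DataFrame(rows)


def period_breakdown(
    loci: Sequence[SSRLocus], size_bp: int | None = None
) -> pd.DataFrame:
    """Count, proportion, total bp (and frequency/density given a size)
    for each unit length 2-6 present in the scan."""
    counts: dict[int, int] = {}
    bp: dict[int, int] = {}
    for l in loci:
        counts[l.period] = counts.get(l.period, 0) + 1
        bp[l.period] = bp.get(l.period, 0) + l.length_bp
    return period_breakdown_from_counts(counts, bp, size_bp)


def motif_ranking(
    loci: Sequence[SSRLocus], top_n: int, size_bp: int | None = None
) -> pd.DataFrame:
    """Most abundant canonical motif classes, count-descending.

    Ties are broken lexicographically by canonical motif so the ranking is
    deterministic.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    counts: dict[str, int] = {}
    bp: dict[str, int] = {}
    for l in loci:
        m = l.motif.canonical
        counts[m] = counts.get(m, 0) + 1
        bp[m] = bp.get(m, 0) + l.length_bp
    ranked = sorted(counts, key=lambda m: (-counts[m], m))[:top_n]
    rows = []
    for m in ranked:
        row: dict = {"motif": m, "n": counts[m], "total_bp": bp[m]}
        if size_bp is not None:
            row["frequency"] = counts[m] / (size_bp / MB)
            row["density"] = bp[m] / (size_bp / MB)
        rows.append(row)
    return pd.DataFrame(rows)


def repeat_number_histogram(loci: Sequence[SSRLocus]) -> dict[int, int]:
    """Counts of loci by repeat number; sums to len(loci)."""
    hist: dict[int, int] = {}
    for l in loci:
        hist[l.n_repeats] = hist.get(l.n_repeats, 0) + 1
    return dict(sorted(hist.items()))


_METRICS = {"n_ssrs", "total_ssr_bp", "density", "frequency"}


def size_correlation(
    chrom_stats: Sequence[ChromosomeStats], metric: str
) -> tuple[float, float]:
    """Pearson correlation of chromosome size against an SSR metric.

    Returns (r, two-sided p). Raises UndefinedCorrelationError when either
    vector has zero variance.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if len(chrom_stats) < 3:
        raise ValueError("need at least 3 chromosomes for a correlation")
    x = np.array([c.size_mb for c in chrom_stats], dtype=float)
    y = np.array([getattr(c, metric) for c in chrom_stats], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in size or metric vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
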