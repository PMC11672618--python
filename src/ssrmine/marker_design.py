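"""SSR flanking-sequence extraction and primer constraint screening.

Screening, not design: candidate primers are checked against the marker
development constraints (length 18-30 nt, Tm 50-60 degC, GC 40-60%,
product 100-300 bp). Tm uses the basic GC fraction formula
``64.9 + 41 * (n_GC - 16.4) / L`` for oligos of >= 14 nt and the Wallace
rule ``2(A+T) + 4(G+C)`` below that; both are deterministic and
documented, deliberately simpler than a nearest-neighbour thermodynamic
model.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import GenomeSequence
from .landscape import MB
from .ssr_detect import SSRLocus, revcomp

MIN_PRIMER_LEN = 18


@dataclass(frozen=True)
class PrimerConstraints:
    len_range: tuple[int, int] = (18, 30)
    tm_range: tuple[float, float] = (50.0, 60.0)
    gc_range: tuple[float, float] = (40.0, 60.0)
    product_range: tuple[int, int] = (100, 300)

    def __post_init__(self) -> None:
        for lo, hi in (self.len_range, self.tm_range, self.gc_range, self.product_range):
            if lo > hi:
                raise ValueError(f"invalid range {lo}..{hi}")


@dataclass(frozen=True)
class MarkerCandidate:
    locus: SSRLocus
    left_flank: str
    right_flank: str
    designable: bool
    reject_reason: str | None


def gc_content(seq: str) -> float:
    """GC percentage of an ACGT string."""
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str) -> float:
    """Approximate oligo Tm in degC.

    GC-fraction formula for >= 14 nt; Wallace rule (2(A+T) + 4(G+C)) for
    shorter oligos, with a warning noting the method switch.
    """
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    if len(seq) >= 14:
        return 64.9 + 41.0 * (gc - 16.4) / len(seq)
    warnings.warn(
        f"oligo of {len(seq)} nt < 14: using Wallace rule instead of GC formula",
        stacklevel=2,
    )
    at = seq.count("A") + seq.count("T")
    return float(2 * at + 4 * gc)


def extract_flanks(
    locus: SSRLocus,
    genome: GenomeSequence,
    flank_len: int = 250,
    max_n_run: int = 10,
) -> MarkerCandidate:
    """Flanking sequences abutting (never overlapping) the repeat tract.

    Marked non-designable when either flank is shorter than the minimum
    primer length or contains a run of >= `max_n_run` Ns.
    """
    if locus.seq_id != genome.seq_id:
        raise ValueError(f"locus on {locus.seq_id}, genome is {genome.seq_id}")
    if locus.start < 1 or locus.end > genome.length_bp:
        raise ValueError(
            f"locus {locus.start}..{locus.end} outside {genome.seq_id} (1..{genome.length_bp})"
        )
    left = genome.residues[max(locus.start - 1 - flank_len, 0) : locus.start - 1]
    right = genome.residues[locus.end : locus.end + flank_len]
    reason = None
    n_run = "N" * max_n_run
    if len(left) < MIN_PRIMER_LEN:
        reason = "left flank too short"
    elif len(right) < MIN_PRIMER_LEN:
        reason = "right flank too short"
    elif n_run in left:
        reason = f"left flank contains an N run >= {max_n_run}"
    elif n_run in right:
        reason = f"right flank contains an N run >= {max_n_run}"
    return MarkerCandidate(locus, left, right, reason is None, reason)


def screen_pair(
    fwd: str,
    rev: str,
    template: str,
    constraints: PrimerConstraints = PrimerConstraints(),
) -> tuple[bool, list[str]]:
    """Check one primer pair against all constraints; list every failure.

    The product is delimited by the first (lowest-coordinate) exact match
    of the forward primer and of the reverse complement of the reverse
    primer on the template.
    """
    failures: list[str] = []
    for name, primer in (("forward", fwd), ("reverse", rev)):
        lo, hi = constraints.len_range
        if not lo <= len(primer) <= hi:
            failures.append(f"{name} length {len(primer)} outside {lo}-{hi}")
        gc = gc_content(primer)
        lo, hi = constraints.gc_range
        if not lo <= gc <= hi:
            failures.append(f"{name} GC {gc:.1f}% outside {lo}-{hi}%")
        tm = melting_temperature(primer)
        lo, hi = constraints.tm_range
        if not lo <= tm <= hi:
            failures.append(f"{name} Tm {tm:.1f} outside {lo}-{hi}")

    fwd_hits = [m.start() for m in re.finditer(re.escape(fwd), template)]
    rev_site = revcomp(rev)
    rev_hits = [m.start() for m in re.finditer(re.escape(rev_site), template)]
    if not fwd_hits:
        failures.append("no binding site for forward primer")
    if not rev_hits:
        failures.append("no binding site for reverse primer")
    if fwd_hits and rev_hits:
        if len(fwd_hits) > 1 or len(rev_hits) > 1:
            warnings.warn("primer binds the template more than once", stacklevel=2)
        product = rev_hits[0] + len(rev_site) - fwd_hits[0]
        lo, hi = constraints.product_range
        if not lo <= product <= hi:
            failures.append(f"product {product} outside {lo}-{hi}")
    return (not failures), failures


def markers_per_chromosome(
    candidates: Sequence[MarkerCandidate], seq_lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Designable-marker counts and per-Mb frequency per sequence."""
    counts: dict[str, int] = {s: 0 for s in seq_lengths}
    for c in candidates:
        if c.designable:
            counts[c.locus.seq_id] = counts.get(c.locus.seq_id, 0) + 1
    rows = [
        {
            "seq_id": s,
            "n_designable": counts.get(s, 0),
            "frequency": counts.get(s, 0) / (seq_lengths[s] / MB),
        }
        for s in seq_lengths
    ]
    return pd.DataFrame(rows)
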