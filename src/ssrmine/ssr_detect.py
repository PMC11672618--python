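"""Perfect microsatellite detection, motif canonicalization, compound merging.

A microsatellite (SSR) is a perfect tandem repeat of a 2-6 bp unit. Detection
thresholds follow the MISA convention used for fish genome surveys:
dinucleotide units need >= 6 repeats, tri- through hexanucleotide units
>= 5. Two repeat units describe the same motif when one is a circular
permutation of the other or of its reverse complement (an (AC)n tract read
on the opposite strand is (GT)n); each equivalence class is named by its
lexicographically smallest member, and a unit that is itself a whole-number
repetition of a shorter unit is first reduced to that shortest unit, so
(ATAT)8 is recorded as (AT)16. SSRs separated by fewer than 100 intervening
nucleotides are merged into compound records.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GenomeSequence

#: MISA-style detection thresholds: minimum repeat count per unit length.
DEFAULT_THRESHOLDS: dict[int, int] = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

#: Maximum intervening gap (exclusive) for compound merging, in nt.
DEFAULT_MAX_GAP = 100

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MotifDomainError(ValueError):
    """Raised for units outside the 2-6 bp ACGT motif domain."""


@dataclass(frozen=True, order=True)
class MotifClass:
    """Canonical representative of a repeat-unit equivalence class.

    `canonical` is the lexicographic minimum (A<C<G<T) over all rotations
    of the primitive unit and all rotations of its reverse complement.
    """

    canonical: str

    @property
    def period(self) -> int:
        return len(self.canonical)


@dataclass(frozen=True)
class SSRLocus:
    seq_id: str
    start: int  # 1-based inclusive
    end: int
    unit: str  # as it occurs on the forward strand
    motif: MotifClass
    n_repeats: int
    length_bp: int

    @property
    def period(self) -> int:
        return len(self.unit)


@dataclass(frozen=True)
class CompoundSSR:
    seq_id: str
    start: int
    end: int
    members: tuple[SSRLocus, ...]
    gaps: tuple[int, ...]  # intervening nt between consecutive members


def _check_unit(unit: str) -> None:
    if not unit or set(unit) - set("ACGT"):
        raise MotifDomainError(f"unit {unit!r} contains non-ACGT characters or is empty")
    if len(unit) > 6:
        raise MotifDomainError(f"unit {unit!r} longer than 6 bp")


def minimal_period(unit: str) -> str:
    """Shortest u with unit == u * k; the unit itself if primitive."""
    _check_unit(unit)
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return unit[:d]
    return unit


@lru_cache(maxsize=65536)
def canonical_class(unit: str) -> MotifClass:
    """Canonical motif class of a primitive 2-6 bp unit.

    Minimum over all rotations of the unit and of its reverse complement,
    under A<C<G<T. Idempotent: the canonical string maps to itself.
    """
    _check_unit(unit)
    if minimal_period(unit) != unit:
        raise MotifDomainError(f"unit {unit!r} is not primitive; reduce with minimal_period first")
    if len(unit) == 1:
        raise MotifDomainError("mononucleotide units are out of scope (motifs are 2-6 bp)")
    rc = revcomp(unit)
    candidates = [unit[i:] + unit[:i] for i in range(len(unit))]
    candidates += [rc[i:] + rc[:i] for i in range(len(rc))]
    return MotifClass(min(candidates))


def normalize_repeat(unit: str, n: int) -> tuple[MotifClass, int]:
    """Reduce to minimal period, scale the repeat count, canonicalize.

    ("TCTC", 10) -> (class AG, 20); ("ATAT", 8) -> (class AT, 16).
    """
    if n < 1:
        raise MotifDomainError(f"repeat count {n} < 1")
    base = minimal_period(unit)
    factor = len(unit) // len(base)
    return canonical_class(base), n * factor


def enumerate_motif_classes(period: int) -> set[MotifClass]:
    """All canonical classes of exactly `period` (primitive units only).

    Sizes for periods 2..6 are 4, 10, 33, 102, 350.
    """
    if period not in range(2, 7):
        raise MotifDomainError(f"period {period} outside 2-6")
    out: set[MotifClass] = set()
    for tup in itertools.product("ACGT", repeat=period):
        unit = "".join(tup)
        if minimal_period(unit) == unit:
            out.add(canonical_class(unit))
    return out


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    code = np.full(256, 4, dtype=np.uint8)
    for b, v in _BASE_CODE.items():
        code[ord(b)] = v
    return code[arr]


def _candidate_runs(
    residues: str, thresholds: Mapping[int, int]
) -> list[tuple[int, int, int]]:
    """Threshold-passing perfect runs as (start0, period, n_repeats).

    For each period p, positions where s[i] == s[i+p] (both in ACGT) form
    matching blocks; a maximal block of m matches starting at i spans a
    periodic region of m + p bases. Every start inside the region whose
    remaining full-unit count meets the threshold is a candidate (phase
    shifts included, so overlap resolution can fall back to a suffix run
    when the region's head is claimed by another locus). Regions whose
    p-mer is non-primitive are owned by the shorter period and skipped.
    """
    arr = _encode(residues)
    n = arr.size
    valid = arr < 4
    cands: list[tuple[int, int, int]] = []
    for p, min_rep in thresholds.items():
        if n < p * min_rep:
            continue
        eq = (arr[p:] == arr[:-p]) & valid[p:] & valid[:-p]
        if not eq.any():
            continue
        # run-length encode the boolean match vector
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]  # [start, end) in eq-index space
        lengths = ends - starts
        keep = (lengths + p) // p >= min_rep
        for i0, m in zip(starts[keep], lengths[keep]):
            unit = residues[i0 : i0 + p]
            if minimal_period(unit) != unit:
                continue  # rotations of a non-primitive unit are non-primitive
            region_end = int(i0) + int(m) + p - 1  # 0-based inclusive
            last_start = region_end + 1 - p * min_rep
            for s0 in range(int(i0), last_start + 1):
                cands.append((s0, p, (region_end - s0 + 1) // p))
    return cands


def _resolve_overlaps(cands: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Greedy leftmost-longest (then shortest-period) selection."""
    cands.sort(key=lambda c: (c[0], -(c[1] * c[2]), c[1]))
    chosen: list[tuple[int, int, int]] = []
    max_end = -1  # 0-based inclusive end of accepted runs
    for i0, p, n_rep in cands:
        if i0 > max_end:
            chosen.append((i0, p, n_rep))
            max_end = max(max_end, i0 + p * n_rep - 1)
    return chosen


def scan_perfect_ssrs(
    seq: GenomeSequence,
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
) -> list[SSRLocus]:
    """All maximal perfect 2-6 bp tandem repeats meeting the thresholds.

    Runs are reported under their minimal period; overlaps between
    candidate runs of different phase or period are resolved
    leftmost-longest, so the output is coordinate-sorted and
    non-overlapping. N breaks a run (the threshold-passing prefix is kept).
    """
    bad = set(thresholds) - set(range(2, 7))
    if bad:
        raise MotifDomainError(f"threshold periods outside 2-6: {sorted(bad)}")
    out: list[SSRLocus] = []
    for i0, p, n_rep in _resolve_overlaps(_candidate_runs(seq.residues, thresholds)):
        unit = seq.residues[i0 : i0 + p]
        out.append(
            SSRLocus(
                seq_id=seq.seq_id,
                start=i0 + 1,
                end=i0 + p * n_rep,
                unit=unit,
                motif=canonical_class(unit),
                n_repeats=n_rep,
                length_bp=p * n_rep,
            )
        )
    return out


def scan_genome(
    genome: Iterable[GenomeSequence],
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
) -> list[SSRLocus]:
    loci: list[SSRLocus] = []
    for seq in genome:
        loci.extend(scan_perfect_ssrs(seq, thresholds))
    return loci


class ContractViolation(ValueError):
    pass


def merge_compound(
    loci: Sequence[SSRLocus], max_gap: int = DEFAULT_MAX_GAP
) -> tuple[list[CompoundSSR], list[SSRLocus]]:
    """Chain loci whose intervening gap is strictly below `max_gap` nt.

    Input must be coordinate-sorted, non-overlapping, single-sequence.
    Every input locus appears in exactly one output record: either as a
    member of one CompoundSSR (chains of >= 2) or standalone.
    """
    loci = list(loci)
    for prev, nxt in zip(loci, loci[1:]):
        if prev.seq_id != nxt.seq_id:
            raise ContractViolation("merge_compound requires a single seq_id")
        if nxt.start <= prev.end:
            raise ContractViolation("loci must be coordinate-sorted and non-overlapping")

    compounds: list[CompoundSSR] = []
    standalone: list[SSRLocus] = []
    chain: list[SSRLocus] = []
    gaps: list[int] = []

    def flush() -> None:
        if len(chain) >= 2:
            compounds.append(
                CompoundSSR(
                    seq_id=chain[0].seq_id,
                    start=chain[0].start,
                    end=chain[-1].end,
                    members=tuple(chain),
                    gaps=tuple(gaps),
                )
            )
        elif chain:
            standalone.append(chain[0])

    for locus in loci:
        if chain:
            gap = locus.start - chain[-1].end - 1
            if gap < max_gap:
                chain.append(locus)
                gaps.append(gap)
                continue
            flush()
        chain, gaps = [locus], []
    flush()
    return compounds, standalone


def merge_compound_genome(
    loci: Sequence[SSRLocus], max_gap: int = DEFAULT_MAX_GAP
) -> tuple[list[CompoundSSR], list[SSRLocus]]:
    """merge_compound applied per seq_id over a genome-wide locus list."""
    compounds: list[CompoundSSR] = []
    standalone: list[SSRLocus] = []
    by_seq: dict[str, list[SSRLocus]] = {}
    for locus in loci:
        by_seq.setdefault(locus.seq_id, []).append(locus)
    for seq_id in by_seq:
        c, s = merge_compound(by_seq[seq_id], max_gap)
        compounds.extend(c)
        standalone.extend(s)
    return compounds, standalone
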