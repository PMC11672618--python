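"""Assignment of SSR records to exonic, intronic, or intergenic space.

Each sequence is partitioned per base: bases covered by any exon (union
over isoforms) are exonic; remaining bases inside a gene span are
intronic; everything else is intergenic. A record straddling a boundary
is classified by the category at its start base by default ("start"
rule), or by the category covering the most of its span ("majority-overlap").
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import AnnotationSet
from .ssr_detect import CompoundSSR, SSRLocus

INTERGENIC, INTRON, EXON = 0, 1, 2
_NAMES = {INTERGENIC: "intergenic", INTRON: "intron", EXON: "exon"}

Record = Union[SSRLocus, CompoundSSR]


@dataclass(frozen=True)
class RegionAssignment:
    record_id: str
    category: str  # exon | intron | intergenic
    overlapping_gene_id: str | None


@dataclass
class RegionIndex:
    """Per-base category arrays plus sorted gene spans per sequence."""

    base_category: dict[str, np.ndarray]  # uint8, 0-based position -> code
    gene_spans: dict[str, list[tuple[int, int, str]]]  # (start, end, gene_id), sorted

    def category_bp(self, seq_id: str) -> dict[str, int]:
        arr = self.base_category[seq_id]
        return {name: int((arr == code).sum()) for code, name in _NAMES.items()}


def _gene_spans(annotation: AnnotationSet) -> dict[str, list[tuple[int, int, str]]]:
    """Gene span = union of the gene record and all its transcripts."""
    spans: dict[str, tuple[str, int, int]] = {}  # gene_id -> (seq, start, end)
    mrna_gene: dict[str, str] = {}
    for r in annotation.records:
        if r.feature_type == "gene" and r.feature_id:
            spans[r.feature_id] = (r.seq_id, r.start, r.end)
    for r in annotation.records:
        if r.feature_type == "mRNA" and r.feature_id:
            gid = r.parent_id or r.feature_id
            mrna_gene[r.feature_id] = gid
            if gid in spans:
                seq, s, e = spans[gid]
                spans[gid] = (seq, min(s, r.start), max(e, r.end))
            else:
                spans[gid] = (r.seq_id, r.start, r.end)
    by_seq: dict[str, list[tuple[int, int, str]]] = {}
    for gid, (seq, s, e) in spans.items():
        by_seq.setdefault(seq, []).append((s, e, gid))
    for seq in by_seq:
        by_seq[seq].sort()
    return by_seq


def build_region_index(
    annotation: AnnotationSet, seq_lengths: Mapping[str, int]
) -> RegionIndex:
    """Partition every sequence into exon / intron / intergenic bases.

    Exon takes precedence over intron where isoforms disagree. Features
    extending beyond the sequence end are clipped with a warning.
    """
    cat = {s: np.zeros(L, dtype=np.uint8) for s, L in seq_lengths.items()}
    spans = _gene_spans(annotation)

    def clip(seq_id: str, start: int, end: int, what: str) -> tuple[int, int]:
        L = seq_lengths[seq_id]
        if end > L or start < 1:
            warnings.warn(
                f"{what} {start}..{end} outside {seq_id} (1..{L}); clipped", stacklevel=3
            )
        return max(start, 1), min(end, L)

    for seq_id, gene_list in spans.items():
        if seq_id not in cat:
            continue
        for s, e, gid in gene_list:
            s, e = clip(seq_id, s, e, f"gene {gid}")
            cat[seq_id][s - 1 : e] = INTRON
    for r in annotation.records:
        if r.feature_type != "exon" or r.seq_id not in cat:
            continue
        s, e = clip(r.seq_id, r.start, r.end, f"exon {r.feature_id}")
        cat[r.seq_id][s - 1 : e] = EXON
    return RegionIndex(base_category=cat, gene_spans=spans)


def _record_id(record: Record) -> str:
    kind = "c" if isinstance(record, CompoundSSR) else "p"
    return f"{record.seq_id}:{record.start}-{record.end}:{kind}"


def _gene_at(index: RegionIndex, seq_id: str, pos: int) -> str | None:
    spans = index.gene_spans.get(seq_id, [])
    i = bisect_right(spans, (pos, float("inf"), ""))
    # walk left: spans are sorted by start but may nest/overlap
    for s, e, gid in reversed(spans[:i]):
        if s <= pos <= e:
            return gid
    return None


def classify_record(
    record: Record, index: RegionIndex, boundary_rule: str = "start"
) -> RegionAssignment:
    """Assign one SSR record (standalone or compound) to a region category."""
    if record.seq_id not in index.base_category:
        raise KeyError(f"seq_id {record.seq_id!r} absent from region index")
    arr = index.base_category[record.seq_id]
    if boundary_rule == "start":
        code = int(arr[record.start - 1])
        anchor = record.start
    elif boundary_rule == "majority-overlap":
        span = arr[record.start - 1 : record.end]
        counts = np.bincount(span, minlength=3)
        code = int(np.argmax(counts))  # ties: intergenic < intron < exon index order
        anchor = record.start
    else:
        raise ValueError(f"unknown boundary rule {boundary_rule!r}")
    gene = _gene_at(index, record.seq_id, anchor) if code != INTERGENIC else None
    return RegionAssignment(_record_id(record), _NAMES[code], gene)


def classify_records(
    records: Sequence[Record], index: RegionIndex, boundary_rule: str = "start"
) -> list[RegionAssignment]:
    return [classify_record(r, index, boundary_rule) for r in records]


def _row_label(record: Record) -> str:
    if isinstance(record, CompoundSSR):
        return "compound"
    return f"p{record.period}"


_ROW_ORDER = ["p2", "p3", "p4", "p5", "p6", "compound"]
_COL_ORDER = ["exon", "intergenic", "intron"]


def region_distribution(
    assignments: Sequence[RegionAssignment], records: Sequence[Record]
) -> pd.DataFrame:
    """Period-x-region count matrix with an All row and overall percentages.

    Records and assignments are parallel. Compound records count once
    (their members are not re-counted), so the grand total is
    n_standalone + n_compound.
    """
    if len(assignments) != len(records):
        raise ValueError("assignments and records must be parallel")
    counts: dict[str, dict[str, int]] = {r: {c: 0 for c in _COL_ORDER} for r in _ROW_ORDER}
    for a, rec in zip(assignments, records):
        counts[_row_label(rec)][a.category] += 1
    rows = [r for r in _ROW_ORDER if sum(counts[r].values()) > 0]
    df = pd.DataFrame(
        [[counts[r][c] for c in _COL_ORDER] for r in rows],
        index=rows,
        columns=_COL_ORDER,
    )
    df["all"] = df.sum(axis=1)
    total = int(df["all"].sum())
    all_row = df.sum(axis=0)
    df.loc["all"] = all_row
    pct = {c: (100.0 * all_row[c] / total if total else 0.0) for c in _COL_ORDER}
    pct["all"] = 100.0 if total else 0.0
    df.loc["percentage"] = pd.Series(pct)
    return df
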