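"""Reading genomes and annotations; writing tab-separated reports.

All coordinates are 1-based inclusive throughout the package (the shared
convention of GFF3 and MISA-style repeat tables); nothing converts to
0-based half-open except transiently inside array code.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO


class FastaFormatError(ValueError):
    """Raised when a FASTA file is empty or structurally malformed."""


class GFF3FormatError(ValueError):
    """Raised when a GFF3 file cannot be parsed at all."""


# Soft-masked (lowercase) residues are uppercased and scanned like any other
# base; IUPAC ambiguity codes other than N are degraded to N with a warning.
_VALID = set("ACGTN")
_AMBIG = set("RYSWKMBDHV")


@dataclass(frozen=True)
class GenomeSequence:
    """One normalized DNA sequence: uppercase over {A,C,G,T,N}."""

    seq_id: str
    residues: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp != len(self.residues):
            raise ValueError(
                f"{self.seq_id}: length_bp {self.length_bp} != {len(self.residues)} residues"
            )


@dataclass(frozen=True)
class AnnotationRecord:
    seq_id: str
    feature_type: str  # gene | mRNA | exon
    start: int  # 1-based inclusive
    end: int
    strand: str
    feature_id: str | None
    parent_id: str | None


@dataclass
class AnnotationSet:
    records: list[AnnotationRecord] = field(default_factory=list)

    def by_type(self, feature_type: str) -> list[AnnotationRecord]:
        return [r for r in self.records if r.feature_type == feature_type]

    def __len__(self) -> int:
        return len(self.records)


def normalize_residues(raw: str, seq_id: str = "?") -> str:
    """Uppercase, U->T, non-N ambiguity codes -> N (with one warning)."""
    s = raw.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        ambig = bad & _AMBIG
        hard = bad - _AMBIG
        if hard:
            raise FastaFormatError(
                f"{seq_id}: non-nucleotide characters {sorted(hard)} in sequence"
            )
        warnings.warn(
            f"{seq_id}: IUPAC ambiguity codes {sorted(ambig)} mapped to N",
            stacklevel=2,
        )
        s = re.sub("[" + "".join(sorted(ambig)) + "]", "N", s)
    return s


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a multi-record FASTA into normalized GenomeSequence objects.

    Record order is preserved. Raises FastaFormatError on an empty file or
    when the first non-blank line is not a header.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected FASTA header '>', got {line[:30]!r}"
                    )
                break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file (line 1)")
    out: list[GenomeSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq), rec.id)
        out.append(GenomeSequence(rec.id, residues, len(residues)))
    if not out:
        raise FastaFormatError(f"{path}: no FASTA records (line 1)")
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.seq_id}\n")
            for i in range(0, s.length_bp, width):
                fh.write(s.residues[i : i + width] + "\n")


_KEPT_TYPES = {"gene", "mRNA", "exon"}


def read_gff3(path: str | os.PathLike) -> AnnotationSet:
    """Parse gene/mRNA/exon features from a GFF3 file.

    Other feature types are ignored. Records with start > end are dropped
    with a warning; exons whose Parent cannot be resolved are kept with a
    null parent and a warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # comment-only / featureless file
        with open(path) as fh:
            if all(not ln.strip() or ln.startswith("#") for ln in fh):
                return AnnotationSet([])
        raise GFF3FormatError(f"{path}: could not parse GFF3: {exc}") from exc

    known_ids = {f.id for f in db.all_features()}
    records: list[AnnotationRecord] = []
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in _KEPT_TYPES:
            continue
        if feat.start > feat.end:
            warnings.warn(
                f"{path}: {feat.featuretype} {feat.id}: start {feat.start} > end {feat.end}; record dropped",
                stacklevel=2,
            )
            continue
        parents = feat.attributes.get("Parent", [])
        parent_id = parents[0] if parents else None
        if parent_id is not None and parent_id not in known_ids:
            warnings.warn(
                f"{path}: {feat.featuretype} {feat.id}: Parent={parent_id} not found; kept with null parent",
                stacklevel=2,
            )
            parent_id = None
        records.append(
            AnnotationRecord(
                seq_id=feat.seqid,
                feature_type=feat.featuretype,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
                feature_id=feat.id,
                parent_id=parent_id,
            )
        )
    return AnnotationSet(records)


def write_gff3(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in annotation.records:
            attrs = []
            if r.feature_id:
                attrs.append(f"ID={r.feature_id}")
            if r.parent_id:
                attrs.append(f"Parent={r.parent_id}")
            fh.write(
                "\t".join(
                    [
                        r.seq_id,
                        "ssrmine",
                        r.feature_type,
                        str(r.start),
                        str(r.end),
                        ".",
                        r.strand,
                        ".",
                        ";".join(attrs) or ".",
                    ]
                )
                + "\n"
            )


# Column format codes for write_table: "2f" fixed 2 decimals (frequencies,
# densities), "4f" fixed 4 decimals (popgen statistics), "d" integer, "s" raw.
Schema = Mapping[str, str]


def _fmt(value, code: str) -> str:
    if pd.isna(value):
        return ""
    if code == "2f":
        return f"{float(value):.2f}"
    if code == "4f":
        return f"{float(value):.4f}"
    if code == "d":
        return str(int(value))
    return str(value)


def write_table(
    rows: pd.DataFrame | Sequence[Mapping],
    path: str | os.PathLike,
    schema: Schema,
) -> None:
    """Write rows as a TSV with a header and fixed-point float rendering.

    `schema` maps column name -> format code and fixes the column order.
    A density of 13237.9312 under code "2f" renders as "13237.93".
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    cols = list(schema)
    missing = [c for c in cols if c not in df.columns and len(df)]
    if missing:
        raise ValueError(f"rows missing schema columns: {missing}")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(row[c], schema[c]) for c in cols) + "\n")
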