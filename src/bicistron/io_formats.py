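"""Readers and writers for the formats the pipeline touches.

All genomic coordinates are 0-based half-open internally.  GFF3 and the
transcript-isoform TSV are 1-based inclusive at the file boundary; the
conversion happens exactly once, in these readers/writers, so that interval
containment logic elsewhere never has to think about conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneAnnotation:
    """A named, stranded genomic interval for one coding gene."""

    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptIsoform:
    """A stranded transcript boundary pair with a supporting-read count."""

    chrom: str
    strand: str
    start: int  # 0-based
    end: int  # exclusive
    read_count: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(f"isoform start {self.start} >= end {self.end}")
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.read_count < 1:
            raise ValidationError(f"read_count {self.read_count} < 1")


@dataclass(frozen=True)
class AlignmentRecord:
    """One BLAST outfmt-6 style hit of a CDS query against a long read."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_length: int
    query_coverage: float  # percent, 100 * aln_len / qlen if not given
    strand: str  # orientation of the hit on the subject
    subject_start: int  # normalized so start < end
    subject_end: int
    subject_length: int | None = None

    def __post_init__(self):
        if not 0 <= self.percent_identity <= 100:
            raise ValidationError(f"identity {self.percent_identity} out of [0,100]")
        if not 0 <= self.query_coverage <= 100 + 1e-9:
            raise ValidationError(f"coverage {self.query_coverage} out of [0,100]")
        if self.subject_start >= self.subject_end:
            raise ValidationError("subject_start >= subject_end after normalization")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    mrna_rpkm: float
    footprint_rpkm: float

    def __post_init__(self):
        for name in ("mrna_rpkm", "footprint_rpkm"):
            v = getattr(self, name)
            if not (v >= 0 and v == v and v != float("inf")):
                raise ValidationError(f"{self.gene_id}: {name}={v} must be finite >= 0")


# ---------------------------------------------------------------------------
# gene annotation


def _parse_gff3_attributes(attrs: str) -> dict:
    out = {}
    for chunk in attrs.strip().rstrip(";").split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_annotation(path, fmt: str | None = None) -> list[GeneAnnotation]:
    """Read gene intervals from GFF3 or BED6.

    GFF3 rows of type ``gene`` (1-based inclusive) are converted to the
    internal 0-based half-open convention; BED is already half-open and
    passes through.  Duplicate gene ids are rejected.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    if fmt not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gff3":
                    if len(fields) < 9:
                        raise ParseError("GFF3 row has fewer than 9 columns", lineno)
                    if fields[2] not in ("gene", "CDS"):
                        continue
                    attrs = _parse_gff3_attributes(fields[8])
                    gene_id = attrs.get("ID") or attrs.get("Name")
                    if not gene_id:
                        raise ParseError("GFF3 row lacks an ID attribute", lineno)
                    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based
                    end = int(fields[4])
                    strand = fields[6]
                    chrom = fields[0]
                else:
                    if len(fields) < 6:
                        raise ParseError("BED row has fewer than 6 columns", lineno)
                    chrom, start, end, gene_id, _, strand = fields[:6]
                    start, end = int(start), int(end)
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
            if gene_id in seen:
                raise ValidationError(f"duplicate gene_id {gene_id!r} (line {lineno})")
            seen.add(gene_id)
            genes.append(GeneAnnotation(gene_id, chrom, start, end, strand))
    return genes


def write_gene_annotation_gff3(genes: Iterable[GeneAnnotation], path) -> None:
    genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tbicistron\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# transcript isoform table

_ISOFORM_HEADER = ["chrom", "strand", "start", "end", "count"]


def read_isoform_table(path) -> list[TranscriptIsoform]:
    """Read a TIF-style isoform table (TSV, 1-based inclusive coordinates)."""
    isoforms = []
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if not lines:
        logger.warning("isoform table %s is empty", path)
        return []
    header = lines[0].split("\t")
    if header != _ISOFORM_HEADER:
        raise ParseError(f"expected header {_ISOFORM_HEADER}, got {header}", 1)
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 5:
            raise ParseError("expected 5 columns", lineno)
        chrom, strand, start, end, count = fields
        try:
            start, end, count = int(start), int(end), int(count)
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
        if count < 1:
            raise ValidationError(f"line {lineno}: read count {count} < 1")
        isoforms.append(TranscriptIsoform(chrom, strand, start - 1, end, count))
    return isoforms


def write_isoform_table(isoforms: Iterable[TranscriptIsoform], path) -> None:
    rows = sorted(isoforms, key=lambda t: (t.chrom, t.start, t.end, t.strand))
    with open(path, "w") as fh:
        fh.write("\t".join(_ISOFORM_HEADER) + "\n")
        for t in rows:
            fh.write(f"{t.chrom}\t{t.strand}\t{t.start + 1}\t{t.end}\t{t.read_count}\n")


# ---------------------------------------------------------------------------
# BLAST tabular


def read_alignment_table(
    path, query_lengths: Mapping[str, int] | None = None
) -> list[AlignmentRecord]:
    """Read BLAST outfmt-6 rows.

    Accepted dialects: the standard 12 columns (requires a ``query_lengths``
    sidecar mapping), 13 columns with a trailing ``qlen``, or 14 columns with
    trailing ``qlen`` and ``slen``.  Subject coordinates are normalized so
    start < end, recording hit orientation in ``strand``.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) not in (12, 13, 14):
                raise ParseError(f"expected 12-14 columns, got {len(f)}", lineno)
            try:
                qid, sid = f[0], f[1]
                pident = float(f[2])
                aln_len = int(f[3])
                sstart, send = int(f[8]), int(f[9])
                qlen = int(f[12]) if len(f) >= 13 else None
                slen = int(f[13]) if len(f) == 14 else None
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from exc
            if qlen is None:
                if query_lengths is None or qid not in query_lengths:
                    raise ParseError(
                        f"no query length available for query {qid!r}", lineno
                    )
                qlen = query_lengths[qid]
            if qlen <= 0:
                raise ValidationError(f"line {lineno}: qlen {qlen} <= 0 for {qid!r}")
            strand = "+" if sstart < send else "-"
            lo, hi = min(sstart, send), max(sstart, send)
            records.append(
                AlignmentRecord(
                    query_id=qid,
                    subject_id=sid,
                    percent_identity=pident,
                    alignment_length=aln_len,
                    query_length=qlen,
                    query_coverage=100.0 * aln_len / qlen,
                    strand=strand,
                    subject_start=lo,
                    subject_end=hi,
                    subject_length=slen,
                )
            )
    return records


def write_alignment_table(records: Iterable[AlignmentRecord], path) -> None:
    """Write records as 14-column outfmt 6 (+qlen +slen); filler values are
    used for the columns the pipeline does not consume."""
    with open(path, "w") as fh:
        for r in records:
            sstart, send = (
                (r.subject_start, r.subject_end)
                if r.strand == "+"
                else (r.subject_end, r.subject_start)
            )
            slen = r.subject_length if r.subject_length is not None else 0
            fh.write(
                f"{r.query_id}\t{r.subject_id}\t{r.percent_identity:g}\t"
                f"{r.alignment_length}\t0\t0\t1\t{r.query_length}\t"
                f"{sstart}\t{send}\t0.0\t0\t{r.query_length}\t{slen}\n"
            )


# ---------------------------------------------------------------------------
# expression / ages / FASTA


def read_expression_table(path) -> list[ExpressionRecord]:
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if not lines:
        logger.warning("expression table %s is empty", path)
        return []
    expected = ["gene", "mrna_rpkm", "footprint_rpkm"]
    if lines[0].split("\t") != expected:
        raise ParseError(f"expected header {expected}", 1)
    for lineno, line in enumerate(lines[1:], start=2):
        gene, mrna, fp = line.split("\t")
        try:
            mrna, fp = float(mrna), float(fp)
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
        records.append(ExpressionRecord(gene, mrna, fp))
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tmrna_rpkm\tfootprint_rpkm\n")
        for r in sorted(records, key=lambda r: r.gene_id):
            fh.write(f"{r.gene_id}\t{r.mrna_rpkm:g}\t{r.footprint_rpkm:g}\n")


def read_age_table(path) -> dict[str, int]:
    """Gene-age table: TSV with header ``gene<TAB>age``, ages in 1..10."""
    ages: dict[str, int] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if not lines or lines[0].split("\t") != ["gene", "age"]:
        raise ParseError("expected header gene\tage", 1)
    for lineno, line in enumerate(lines[1:], start=2):
        gene, age = line.split("\t")
        age = int(age)
        if not 1 <= age <= 10:
            raise ValidationError(f"line {lineno}: age {age} outside 1..10")
        ages[gene] = age
    return ages


def write_age_table(ages: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tage\n")
        for gene in sorted(ages):
            fh.write(f"{gene}\t{ages[gene]}\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# result tables (operon calls, classifications)


def write_results(rows: Sequence[Mapping], path, columns: Sequence[str]) -> None:
    """Write a generic deterministic TSV: fixed column order, rows sorted by
    the given columns' values (stringified)."""
    rows = sorted(rows, key=lambda r: tuple(str(r[c]) for c in columns))
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in columns) + "\n")
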