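"""Calling operon-like (bi-/tri-/multicistronic) transcripts.

Two routes are supported, mirroring how such transcripts are found in
practice: (1) from transcript-isoform boundary data, where a transcript that
fully contains two or more same-strand genes is an operon-like candidate,
and (2) from long-read alignment tables, where a single mRNA read covering
two CDS queries at high identity and near-complete coverage is the evidence.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass

from .io_formats import AlignmentRecord, GeneAnnotation, TranscriptIsoform

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OperonCall:
    """One called operon-like transcript: ordered contained genes plus the
    total read support pooled over isoforms with the same gene content."""

    chrom: str
    strand: str
    gene_ids: tuple[str, ...]  # 5'->3' along the transcript strand
    read_support: int
    source: str  # "isoform" or "longread"

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def is_bicistronic(self) -> bool:
        return self.n_genes == 2

    @property
    def is_tricistronic(self) -> bool:
        return self.n_genes == 3


@dataclass(frozen=True)
class MonoSummary:
    gene_id: str
    mono_reads: int  # reads of isoforms fully containing exactly this gene


class GeneIndex:
    """Genes bucketed per chromosome, sorted by start, for containment
    queries against transcript intervals."""

    def __init__(self, genes: list[GeneAnnotation]):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[GeneAnnotation]] = defaultdict(list)
        for g in genes:
            self._by_chrom[g.chrom].append(g)
        self._starts: dict[str, list[int]] = {}
        for chrom, gl in self._by_chrom.items():
            gl.sort(key=lambda g: (g.start, g.end, g.gene_id))
            self._starts[chrom] = [g.start for g in gl]

    def contained(self, isoform: TranscriptIsoform) -> list[GeneAnnotation]:
        """Genes 100% contained in the isoform on the isoform's strand,
        ordered 5'->3' along the transcript."""
        gl = self._by_chrom.get(isoform.chrom, [])
        if not gl:
            return []
        starts = self._starts[isoform.chrom]
        lo = bisect_left(starts, isoform.start)
        hi = bisect_right(starts, isoform.end)
        hits = [
            g
            for g in gl[lo:hi]
            if g.strand == isoform.strand and g.end <= isoform.end
        ]
        hits.sort(key=lambda g: g.start, reverse=(isoform.strand == "-"))
        return hits


def contained_genes(
    isoform: TranscriptIsoform, genes: GeneIndex | list[GeneAnnotation]
) -> list[GeneAnnotation]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return index.contained(isoform)


def _spans_overlap(genes: list[GeneAnnotation]) -> bool:
    spans = sorted((g.start, g.end) for g in genes)
    return any(spans[i][1] > spans[i + 1][0] for i in range(len(spans) - 1))


def call_operons(
    isoforms: list[TranscriptIsoform],
    genes: GeneIndex | list[GeneAnnotation],
    min_reads: int = 2,
) -> list[OperonCall]:
    """Group isoforms containing >=2 genes by their ordered gene tuple and
    keep groups supported by at least ``min_reads`` reads.

    Isoforms whose contained genes have overlapping genomic spans are
    skipped: intergenic features are undefined for overlapping pairs.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    support: dict[tuple[str, str, tuple[str, ...]], int] = defaultdict(int)
    for iso in isoforms:
        hits = index.contained(iso)
        if len(hits) < 2:
            continue
        if _spans_overlap(hits):
            logger.debug("skipping isoform with overlapping contained genes")
            continue
        key = (iso.chrom, iso.strand, tuple(g.gene_id for g in hits))
        support[key] += iso.read_count
    calls = [
        OperonCall(chrom, strand, gids, reads, "isoform")
        for (chrom, strand, gids), reads in support.items()
        if reads >= min_reads
    ]
    calls.sort(key=lambda c: (c.chrom, c.strand, c.gene_ids))
    return calls


def mono_summaries(
    isoforms: list[TranscriptIsoform],
    genes: GeneIndex | list[GeneAnnotation],
) -> list[MonoSummary]:
    """Per gene, the read support of isoforms containing exactly that gene."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    counts: dict[str, int] = {g.gene_id: 0 for g in index.genes}
    for iso in isoforms:
        hits = index.contained(iso)
        if len(hits) == 1:
            counts[hits[0].gene_id] += iso.read_count
    return [MonoSummary(gid, n) for gid, n in counts.items()]


def coexistence_with_bicistronic(
    tri_calls: list[OperonCall], bi_calls: list[OperonCall]
) -> int:
    """Count tricistronic calls that coexist with a bicistronic variant,
    i.e. some bicistronic call's gene pair is an adjacent sub-pair of the
    tricistronic call's ordered gene triple."""
    bi_pairs = {c.gene_ids for c in bi_calls if c.is_bicistronic}
    n = 0
    for tri in tri_calls:
        if not tri.is_tricistronic:
            continue
        g = tri.gene_ids
        if (g[0], g[1]) in bi_pairs or (g[1], g[2]) in bi_pairs:
            n += 1
    return n


def call_bt_from_alignments(
    records: list[AlignmentRecord],
    min_identity: float = 90.0,
    min_coverage: float = 99.0,
    min_read_length: int = 1000,
    min_reads: int = 2,
) -> list[OperonCall]:
    """Call operon-like transcripts from a long-read alignment table.

    Filters are strict inequalities: a hit survives only with identity
    strictly above ``min_identity`` and coverage strictly above
    ``min_coverage``, on a read strictly longer than ``min_read_length``.
    A read hit by >=2 distinct genes, all in the same orientation, yields a
    candidate gene tuple ordered by position along the read; tuples seen in
    at least ``min_reads`` reads become calls.
    """
    kept = [
        r
        for r in records
        if r.percent_identity > min_identity
        and r.query_coverage > min_coverage
        and r.subject_length is not None
        and r.subject_length > min_read_length
    ]
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for r in kept:
        by_read[r.subject_id].append(r)

    # grouping unit is the 5'->3' gene tuple; a read's alignment orientation
    # only serves to order the genes, so +/- reads of one pair pool together
    support: dict[tuple[str, ...], int] = defaultdict(int)
    orientations: dict[tuple[str, ...], dict[str, int]] = defaultdict(
        lambda: {"+": 0, "-": 0}
    )
    for read_id, hits in by_read.items():
        # best hit per gene on this read
        best: dict[str, AlignmentRecord] = {}
        for r in hits:
            cur = best.get(r.query_id)
            if cur is None or r.percent_identity > cur.percent_identity:
                best[r.query_id] = r
        if len(best) < 2:
            continue
        strands = {r.strand for r in best.values()}
        if len(strands) > 1:
            logger.debug("read %s discarded: mixed hit orientations", read_id)
            continue
        strand = strands.pop()
        ordered = sorted(best.values(), key=lambda r: r.subject_start)
        if strand == "-":
            ordered.reverse()  # 5'->3' on the transcript
        gids = tuple(r.query_id for r in ordered)
        support[gids] += 1
        orientations[gids][strand] += 1

    calls = []
    for gids, n in support.items():
        if n < min_reads:
            continue
        counts = orientations[gids]
        strand = "+" if counts["+"] >= counts["-"] else "-"
        calls.append(OperonCall("*", strand, gids, n, "longread"))
    calls.sort(key=lambda c: (c.strand, c.gene_ids))
    return calls


# ---------------------------------------------------------------------------
# call table round trip

CALL_COLUMNS = ["chrom", "strand", "genes", "n_genes", "read_support", "source"]


def write_calls(calls: list[OperonCall], path) -> None:
    rows = sorted(calls, key=lambda c: (c.chrom, c.strand, c.gene_ids))
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in rows:
            fh.write(
                f"{c.chrom}\t{c.strand}\t{','.join(c.gene_ids)}\t"
                f"{c.n_genes}\t{c.read_support}\t{c.source}\n"
            )


def read_calls(path) -> list[OperonCall]:
    calls = []
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    for line in lines[1:]:
        chrom, strand, genes, _, reads, source = line.split("\t")
        calls.append(OperonCall(chrom, strand, tuple(genes.split(",")), int(reads), source))
    return calls
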