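"""Operon-like transcript calling: containment, pooling, filters."""

import numpy as np
import pytest

from bicistron.bt_caller import (
    GeneIndex,
    OperonCall,
    call_bt_from_alignments,
    call_operons,
    coexistence_with_bicistronic,
    contained_genes,
    mono_summaries,
)
from bicistron.io_formats import AlignmentRecord, GeneAnnotation, TranscriptIsoform

from conftest import make_isoform


class TestContainedGenes:
    def test_strand_and_containment(self, toy_genes):
        hits = contained_genes(make_isoform(100, 500), toy_genes)
        assert [g.gene_id for g in hits] == ["A", "B"]  # C excluded by strand

    def test_partial_overlap_is_not_containment(self, toy_genes):
        hits = contained_genes(make_isoform(100, 500), toy_genes)
        assert "D" not in [g.gene_id for g in hits]  # starts at 90 < 100

    def test_minus_strand_orders_five_prime_first(self):
        genes = [
            GeneAnnotation("A", "chrI", 120, 200, "-"),
            GeneAnnotation("B", "chrI", 250, 480, "-"),
        ]
        hits = contained_genes(make_isoform(100, 500, strand="-"), genes)
        assert [g.gene_id for g in hits] == ["B", "A"]

    def test_other_chromosome_excluded(self, toy_genes):
        hits = contained_genes(make_isoform(100, 500, chrom="chrII"), toy_genes)
        assert [g.gene_id for g in hits] == ["E"]


def _pair_genes():
    return [
        GeneAnnotation("A", "chrI", 100, 200, "+"),
        GeneAnnotation("B", "chrI", 250, 400, "+"),
    ]


class TestCallOperons:
    def test_two_single_read_isoforms_pool_to_threshold(self):
        isoforms = [make_isoform(90, 410), make_isoform(95, 405)]
        (call,) = call_operons(isoforms, _pair_genes(), min_reads=2)
        assert call.gene_ids == ("A", "B")
        assert call.read_support == 2

    def test_single_read_dropped_at_threshold(self):
        assert call_operons([make_isoform(90, 410)], _pair_genes(), min_reads=2) == []

    def test_overlapping_gene_pairs_excluded(self):
        genes = [
            GeneAnnotation("A", "chrI", 100, 300, "+"),
            GeneAnnotation("B", "chrI", 250, 400, "+"),
        ]
        assert call_operons([make_isoform(90, 410, count=5)], genes) == []

    def test_raising_min_reads_never_adds_calls(self, default_dataset):
        isoforms = default_dataset.isoforms[:400]
        index = GeneIndex(default_dataset.genes)
        previous = None
        for mr in (1, 2, 5, 20):
            calls = {c.gene_ids for c in call_operons(isoforms, index, min_reads=mr)}
            if previous is not None:
                assert calls <= previous
            previous = calls

    def test_row_order_invariance(self, default_dataset):
        isoforms = list(default_dataset.isoforms[:300])
        index = GeneIndex(default_dataset.genes)
        forward = call_operons(isoforms, index)
        backward = call_operons(isoforms[::-1], index)
        assert forward == backward


def _brute_force_calls(isoforms, genes, min_reads=2):
    """Independent O(n*m) containment scan used as the oracle."""
    support = {}
    for iso in isoforms:
        hits = [
            g
            for g in genes
            if g.chrom == iso.chrom
            and g.strand == iso.strand
            and iso.start <= g.start
            and g.end <= iso.end
        ]
        if len(hits) < 2:
            continue
        spans = sorted((g.start, g.end) for g in hits)
        if any(spans[i][1] > spans[i + 1][0] for i in range(len(spans) - 1)):
            continue
        hits.sort(key=lambda g: g.start, reverse=(iso.strand == "-"))
        key = (iso.chrom, iso.strand, tuple(g.gene_id for g in hits))
        support[key] = support.get(key, 0) + iso.read_count
    return {k: v for k, v in support.items() if v >= min_reads}


def random_toy_genome(rng, n_genes=30, n_isoforms=100):
    genes, cursor = [], 0
    for i in range(n_genes):
        cursor += int(rng.integers(10, 120))
        length = int(rng.integers(30, 200))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{int(rng.integers(1, 4))}"
        genes.append(GeneAnnotation(f"g{i}", chrom, cursor, cursor + length, strand))
        cursor += length
    isoforms = []
    for _ in range(n_isoforms):
        start = int(rng.integers(0, cursor))
        end = start + int(rng.integers(50, 900))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{int(rng.integers(1, 4))}"
        isoforms.append(
            TranscriptIsoform(chrom, strand, start, end, int(rng.integers(1, 5)))
        )
    return genes, isoforms


def test_call_operons_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    for _ in range(30):
        genes, isoforms = random_toy_genome(rng)
        calls = call_operons(isoforms, genes)
        observed = {(c.chrom, c.strand, c.gene_ids): c.read_support for c in calls}
        assert observed == _brute_force_calls(isoforms, genes)


class TestMonoSummaries:
    def test_sums_counts_of_solo_isoforms(self, toy_genes):
        isoforms = [
            make_isoform(110, 210, count=3),
            make_isoform(115, 205, count=4),
            make_isoform(100, 500, count=9),  # contains A and B: not mono
        ]
        mono = {m.gene_id: m.mono_reads for m in mono_summaries(isoforms, toy_genes)}
        assert mono["A"] == 7
        assert mono["B"] == 0

    def test_random_sets_match_recount(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            genes, isoforms = random_toy_genome(rng, n_genes=15, n_isoforms=60)
            mono = {m.gene_id: m.mono_reads for m in mono_summaries(isoforms, genes)}
            for g in genes:
                expected = sum(
                    iso.read_count
                    for iso in isoforms
                    if [
                        x.gene_id
                        for x in contained_genes(iso, genes)
                    ] == [g.gene_id]
                )
                assert mono[g.gene_id] == expected


class TestCoexistence:
    def test_adjacent_subpair_coexists(self):
        tri = [OperonCall("c", "+", ("A", "B", "C"), 2, "isoform")]
        bi = [OperonCall("c", "+", ("A", "B"), 2, "isoform")]
        assert coexistence_with_bicistronic(tri, bi) == 1

    def test_non_adjacent_pair_does_not_coexist(self):
        tri = [OperonCall("c", "+", ("A", "B", "C"), 2, "isoform")]
        bi = [OperonCall("c", "+", ("A", "C"), 2, "isoform")]
        assert coexistence_with_bicistronic(tri, bi) == 0

    def test_empty_bicistronic_set(self):
        tri = [OperonCall("c", "+", ("A", "B", "C"), 2, "isoform")]
        assert coexistence_with_bicistronic(tri, []) == 0


def _aln(gene, read, ident, aln_len, qlen, slen, sstart=1, send=None, strand="+"):
    send = send if send is not None else sstart + qlen
    return AlignmentRecord(
        query_id=gene,
        subject_id=read,
        percent_identity=ident,
        alignment_length=aln_len,
        query_length=qlen,
        query_coverage=100.0 * aln_len / qlen,
        strand=strand,
        subject_start=min(sstart, send),
        subject_end=max(sstart, send),
        subject_length=slen,
    )


class TestLongReadCalling:
    def test_two_clean_reads_give_one_call(self):
        rows = []
        for read in ("r1", "r2"):
            rows.append(_aln("geneA", read, 95.0, 996, 1000, 2500, sstart=10))
            rows.append(_aln("geneB", read, 92.0, 800, 800, 2500, sstart=1200))
        (call,) = call_bt_from_alignments(rows)
        assert call.gene_ids == ("geneA", "geneB")
        assert call.read_support == 2

    @pytest.mark.parametrize(
        "ident,aln_len,qlen,slen",
        [
            (90.0, 1000, 1000, 2500),  # identity exactly at the threshold
            (95.0, 990, 1000, 2500),  # coverage exactly 99.0
            (95.0, 1000, 1000, 1000),  # read length exactly 1 kb
        ],
    )
    def test_threshold_equal_rows_excluded(self, ident, aln_len, qlen, slen):
        rows = []
        for read in ("r1", "r2"):
            rows.append(_aln("geneA", read, ident, aln_len, qlen, slen, sstart=10))
            rows.append(_aln("geneB", read, 95.0, 800, 800, slen, sstart=1200))
        assert call_bt_from_alignments(rows) == []

    def test_mixed_orientation_read_discarded(self):
        rows = []
        for read in ("r1", "r2"):
            rows.append(_aln("geneA", read, 95.0, 1000, 1000, 2500, sstart=10))
            rows.append(
                _aln("geneB", read, 95.0, 800, 800, 2500, sstart=2000, send=1200,
                     strand="-")
            )
        assert call_bt_from_alignments(rows) == []

    def test_minus_reads_pool_with_plus_reads(self):
        rows = [
            _aln("geneA", "r1", 95.0, 1000, 1000, 2500, sstart=10),
            _aln("geneB", "r1", 95.0, 800, 800, 2500, sstart=1200),
            _aln("geneA", "r2", 95.0, 1000, 1000, 2500, sstart=2490, send=1490,
                 strand="-"),
            _aln("geneB", "r2", 95.0, 800, 800, 2500, sstart=1300, send=500,
                 strand="-"),
        ]
        (call,) = call_bt_from_alignments(rows)
        assert call.gene_ids == ("geneA", "geneB")
        assert call.read_support == 2

    def test_twenty_row_table_matches_hand_filter(self):
        """Row-by-row manual filter over a fixed 20-row table."""
        rows = []
        # pair (gA, gB): 2 clean reads -> called
        for read in ("r1", "r2"):
            rows.append(_aln("gA", read, 96.0, 500, 500, 1800, sstart=10))
            rows.append(_aln("gB", read, 97.0, 600, 600, 1800, sstart=700))
        # pair (gC, gD): one clean read, plus one read where gD fails the
        # identity filter -> only one supporting read, dropped by min_reads
        rows.append(_aln("gC", "r3", 96.0, 500, 500, 1800, sstart=10))
        rows.append(_aln("gD", "r3", 97.0, 600, 600, 1800, sstart=700))
        rows.append(_aln("gC", "r10", 96.0, 500, 500, 1800, sstart=10))
        rows.append(_aln("gD", "r10", 89.9, 600, 600, 1800, sstart=700))
        # pair (gE, gF): 2 reads but gF always at identity 90.0 -> no pair
        for read in ("r4", "r5"):
            rows.append(_aln("gE", read, 96.0, 500, 500, 1800, sstart=10))
            rows.append(_aln("gF", read, 90.0, 600, 600, 1800, sstart=700))
        # pair (gG, gH): 2 reads on short reads (length 1000) -> excluded
        for read in ("r6", "r7"):
            rows.append(_aln("gG", read, 96.0, 500, 500, 1000, sstart=10))
            rows.append(_aln("gH", read, 97.0, 600, 600, 1000, sstart=700))
        # pair (gI, gJ): 2 reads, coverage 98 for gJ -> no pair
        for read in ("r8", "r9"):
            rows.append(_aln("gI", read, 96.0, 500, 500, 1800, sstart=10))
            rows.append(_aln("gJ", read, 97.0, 588, 600, 1800, sstart=700))
        assert len(rows) == 20
        calls = call_bt_from_alignments(rows)
        assert [(c.gene_ids, c.read_support) for c in calls] == [(("gA", "gB"), 2)]
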