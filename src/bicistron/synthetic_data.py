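"""Seeded synthetic datasets with the statistical structure of yeast
operon-like transcription.

The generator lays out tandem same-strand gene pairs on one chromosome and
emits every input the pipeline consumes: annotation, genome sequence,
transcript-isoform counts, expression profiles, a long-read alignment table,
ortholog alignments and gene ages.  Its defaults encode the study
conditions the analysis assumes:

* class proportions bh/sh/bl of 0.10/0.25/0.65 (about 35% highly expressed),
* a monotone-decreasing link between monocistronic expression and the
  bicistronic rate statistic,
* two-fold translational repression of the 3' gene in bh/sh pairs,
* class-ordered intergenic spacers (bh shortest/most GC-rich/least
  structured, bl the opposite, non-BT controls beyond bl),
* class-dependent sharing across conditions and strains (0.8/0.7/0.3),
* class-dependent young-gene fractions.

Classes are assigned generatively and read counts drawn conditional on
class, so classification is evaluated as a recovery problem with known
ground truth.  All randomness flows from one integer seed through named
per-component streams.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import ValidationError
from .io_formats import (
    AlignmentRecord,
    ExpressionRecord,
    GeneAnnotation,
    TranscriptIsoform,
    write_age_table,
    write_alignment_table,
    write_expression_table,
    write_fasta,
    write_gene_annotation_gff3,
    write_isoform_table,
)

logger = logging.getLogger(__name__)

_CLASSES = ("bh", "sh", "bl")
_NUC = np.array(list("GCAT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    n_gene_pairs: int = 300
    n_control_pairs: int = 150
    class_proportions: tuple[float, float, float] = (0.10, 0.25, 0.65)  # bh, sh, bl
    mean_depth: float = 100.0
    depth_sigma: float = 0.6
    rate_expression_slope: float = -0.8
    rate_expression_intercept: float = 2.0
    te_repression_gene2: float = 0.5
    intergenic_length_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"bh": 60.0, "sh": 80.0, "bl": 200.0}
    )
    control_intergenic_length: float = 300.0
    gc_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"bh": 0.50, "sh": 0.46, "bl": 0.38}
    )
    control_gc: float = 0.35
    stem_length_by_class: Mapping[str, int] = field(
        default_factory=lambda: {"bh": 4, "sh": 6, "bl": 22}
    )
    control_stem_length: int = 26
    sharing_prob_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"bh": 0.8, "sh": 0.7, "bl": 0.3}
    )
    young_prob_by_class: Mapping[str, float] = field(
        default_factory=lambda: {"bh": 0.55, "sh": 0.50, "bl": 0.25, "nonBT": 0.20}
    )
    gene_length_mean: float = 500.0
    gene_length_sd: float = 80.0
    junction_gap_mean: float = 350.0
    minus_strand_prob: float = 0.3
    ortholog_transition_prob: float = 0.10
    ortholog_transversion_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_gene_pairs < 1:
            raise ValidationError("n_gene_pairs must be >= 1")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValidationError("class_proportions must sum to 1")
        probs = list(self.class_proportions)
        probs += list(self.sharing_prob_by_class.values())
        probs += list(self.young_prob_by_class.values())
        probs += [self.minus_strand_prob, self.ortholog_transition_prob,
                  self.ortholog_transversion_prob]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if not 0 < self.te_repression_gene2 <= 1:
            raise ValidationError("te_repression_gene2 must be in (0, 1]")
        lengths = list(self.intergenic_length_by_class.values())
        lengths += [self.control_intergenic_length, self.gene_length_mean,
                    self.junction_gap_mean]
        if any(v <= 0 for v in lengths):
            raise ValidationError("lengths must be positive")
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = json.load(fh)
        data.pop("_comment", None)
        if "class_proportions" in data:
            data["class_proportions"] = tuple(data["class_proportions"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)
            fh.write("\n")


@dataclass
class PairTruth:
    """Ground truth for one generated gene pair (BT or non-BT control)."""

    pair_id: int
    gene1_id: str  # 5' gene on the transcript
    gene2_id: str
    chrom: str
    strand: str
    class_label: str | None  # None for control pairs
    spacer_start: int
    spacer_end: int
    mono1: int | None = None
    mono2: int | None = None
    bt: int | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene1_id, self.gene2_id)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genes: list[GeneAnnotation]
    genome: dict[str, str]
    pairs: list[PairTruth]  # BT pairs
    control_pairs: list[PairTruth]
    isoforms: list[TranscriptIsoform]
    expressions: list[ExpressionRecord]
    ages: dict[str, int]
    second_condition: set[tuple[str, str]]
    longread_alignments: list[AlignmentRecord]
    ortholog_pairs: dict[str, tuple[str, str]]

    @property
    def control_gene_ids(self) -> set[str]:
        return {g for p in self.control_pairs for g in (p.gene1_id, p.gene2_id)}

    def spacer_sequence(self, pair: PairTruth) -> str:
        return self.genome[pair.chrom][pair.spacer_start : pair.spacer_end]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _allocate_classes(n: int, proportions, rng) -> list[str]:
    """Deterministic largest-remainder allocation, then a seeded shuffle."""
    raw = [p * n for p in proportions]
    counts = [int(math.floor(x)) for x in raw]
    rest = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in rest[: n - sum(counts)]:
        counts[i] += 1
    labels = [lab for lab, c in zip(_CLASSES, counts) for _ in range(c)]
    return [labels[i] for i in rng.permutation(n)]


def _random_seq(n: int, gc: float, rng) -> str:
    p = np.array([gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2])
    return "".join(_NUC[rng.choice(4, size=n, p=p)])


def _spacer_seq(length: int, gc: float, stem: int, rng) -> str:
    """Spacer with target GC and a planted hairpin stem of the given length
    (folds to roughly -2.3 per stem base under the default energy model)."""
    base = _random_seq(length, gc, rng)
    k = min(stem, (length - 5) // 2)
    if k < 2:
        return base
    head = base[:k]
    return head + base[k : length - k] + _revcomp(head)


# ---------------------------------------------------------------------------
# genome


def generate_genome(config: SimulationConfig) -> SyntheticDataset:
    """Lay out BT units and control units on one chromosome.

    Each unit is two same-strand genes separated by a class-dependent (or
    control) spacer; units are separated by long low-GC junction gaps.
    Returns a dataset skeleton with genes, genome and pair truths; counts,
    expression and the rest are filled in by the other generators.
    """
    config.validate()
    rng = _rng(config.seed, 0)
    class_labels = _allocate_classes(
        config.n_gene_pairs, config.class_proportions, rng
    )
    chrom = "chrS"
    parts: list[str] = []
    genes: list[GeneAnnotation] = []
    pairs: list[PairTruth] = []
    control_pairs: list[PairTruth] = []
    cursor = 0

    def emit(n: int, gc: float) -> None:
        nonlocal cursor
        parts.append(_random_seq(n, gc, rng))
        cursor += n

    n_units = config.n_gene_pairs + config.n_control_pairs
    emit(150, config.control_gc)
    for u in range(n_units):
        is_control = u >= config.n_gene_pairs
        label = None if is_control else class_labels[u]
        if is_control:
            sp_mean = config.control_intergenic_length
            gc = config.control_gc
            stem = config.control_stem_length
        else:
            sp_mean = config.intergenic_length_by_class[label]
            gc = config.gc_by_class[label]
            stem = config.stem_length_by_class[label]
        strand = "-" if rng.random() < config.minus_strand_prob else "+"
        len_a = max(300, round(rng.normal(config.gene_length_mean, config.gene_length_sd)))
        len_b = max(300, round(rng.normal(config.gene_length_mean, config.gene_length_sd)))
        sp_len = max(25, round(rng.normal(sp_mean, 0.25 * sp_mean)))
        gap = max(120, round(rng.normal(config.junction_gap_mean, 50)))

        prefix = "C" if is_control else "P"
        name_left = f"{prefix}{u:04d}{'B' if strand == '-' else 'A'}"
        name_right = f"{prefix}{u:04d}{'A' if strand == '-' else 'B'}"
        left = GeneAnnotation(name_left, chrom, cursor, cursor + len_a, strand)
        emit(len_a, 0.40)
        sp_start = cursor
        parts.append(_spacer_seq(sp_len, gc, stem, rng))
        cursor += sp_len
        right = GeneAnnotation(name_right, chrom, cursor, cursor + len_b, strand)
        emit(len_b, 0.40)
        emit(gap, config.control_gc)
        genes.extend([left, right])
        # gene1 is the 5' gene of the transcript: left on '+', right on '-'
        g1, g2 = (left, right) if strand == "+" else (right, left)
        truth = PairTruth(
            pair_id=u,
            gene1_id=g1.gene_id,
            gene2_id=g2.gene_id,
            chrom=chrom,
            strand=strand,
            class_label=label,
            spacer_start=sp_start,
            spacer_end=sp_start + sp_len,
        )
        (control_pairs if is_control else pairs).append(truth)

    return SyntheticDataset(
        config=config,
        genes=genes,
        genome={chrom: "".join(parts)},
        pairs=pairs,
        control_pairs=control_pairs,
        isoforms=[],
        expressions=[],
        ages={},
        second_condition=set(),
        longread_alignments=[],
        ortholog_pairs={},
    )


# ---------------------------------------------------------------------------
# isoform counts


def _draw_counts(label: str, config: SimulationConfig, rng) -> tuple[int, int, int]:
    """(mono1, mono2, bt) consistent with the pair's class by construction:
    bh forces bt above both monos, sh between them, bl at or below both,
    with the bl rate following the configured decreasing link."""
    mu = math.log(config.mean_depth)
    m1 = max(3, round(float(rng.lognormal(mu, config.depth_sigma))))
    m2 = max(3, round(float(rng.lognormal(mu, config.depth_sigma))))
    if label == "bh":
        mx = max(m1, m2)
        bt = mx + 1 + int(rng.poisson(0.05 * mx))
    elif label == "sh":
        if m1 == m2:
            m2 += 1
        lo, hi = min(m1, m2), max(m1, m2)
        bt = int(rng.integers(lo + 1, hi + 1))
    else:
        mbar = math.sqrt(m1 * m2)
        z = config.rate_expression_intercept + config.rate_expression_slope * math.log(mbar)
        rate = 0.5 / (1.0 + math.exp(-z))
        bt = round(rate / (1.0 - rate) * mbar)
        bt = int(min(max(bt, 2), min(m1, m2)))
    return m1, m2, bt


def generate_isoforms(dataset: SyntheticDataset) -> list[TranscriptIsoform]:
    """Draw per-pair counts and emit jittered isoforms: one monocistronic
    isoform per gene (covering exactly that gene) and bicistronic isoforms
    covering both genes, split over two boundary variants when the support
    allows, so that callers pooling by gene content are exercised."""
    config = dataset.config
    rng = _rng(config.seed, 1)
    gene_by_id = {g.gene_id: g for g in dataset.genes}
    isoforms: list[TranscriptIsoform] = []

    def mono_iso(gene: GeneAnnotation, spacer: tuple[int, int], count: int) -> TranscriptIsoform:
        out5 = int(rng.integers(1, 41))
        out3 = int(rng.integers(1, 41))
        sp_len = spacer[1] - spacer[0]
        inward = int(rng.integers(0, max(1, min(sp_len, 30))))
        if gene.start >= spacer[1]:  # spacer on the left of this gene
            start = gene.start - inward
            end = gene.end + out3
        else:  # spacer on the right
            start = gene.start - out5
            end = gene.end + inward
        return TranscriptIsoform(gene.chrom, gene.strand, max(0, start), end, count)

    for pair in dataset.pairs:
        pair.mono1, pair.mono2, pair.bt = _draw_counts(pair.class_label, config, rng)
        g1 = gene_by_id[pair.gene1_id]
        g2 = gene_by_id[pair.gene2_id]
        spacer = (pair.spacer_start, pair.spacer_end)
        isoforms.append(mono_iso(g1, spacer, pair.mono1))
        isoforms.append(mono_iso(g2, spacer, pair.mono2))
        lo = min(g1.start, g2.start)
        hi = max(g1.end, g2.end)
        bt_counts = [pair.bt] if pair.bt < 4 else [pair.bt // 2, pair.bt - pair.bt // 2]
        for c in bt_counts:
            ext5 = int(rng.integers(1, 41))
            ext3 = int(rng.integers(1, 41))
            isoforms.append(
                TranscriptIsoform(pair.chrom, pair.strand, max(0, lo - ext5), hi + ext3, c)
            )

    mu = math.log(config.mean_depth)
    for pair in dataset.control_pairs:
        m1 = max(2, round(float(rng.lognormal(mu, config.depth_sigma))))
        m2 = max(2, round(float(rng.lognormal(mu, config.depth_sigma))))
        pair.mono1, pair.mono2 = m1, m2
        spacer = (pair.spacer_start, pair.spacer_end)
        isoforms.append(mono_iso(gene_by_id[pair.gene1_id], spacer, m1))
        isoforms.append(mono_iso(gene_by_id[pair.gene2_id], spacer, m2))

    dataset.isoforms = isoforms
    return isoforms


# ---------------------------------------------------------------------------
# expression / ages / sharing / long reads / orthologs


def generate_expression_profiles(dataset: SyntheticDataset) -> list[ExpressionRecord]:
    """Log-normal baseline TE for every gene; the 3' gene of bh/sh pairs has
    its TE multiplied by ``te_repression_gene2``; control genes stay at
    baseline."""
    config = dataset.config
    rng = _rng(config.seed, 2)
    records = []

    def emit(gene_id: str, repressed: bool) -> None:
        mrna = float(rng.lognormal(3.0, 0.8))
        te = float(rng.lognormal(0.0, 0.4))
        if repressed:
            te *= config.te_repression_gene2
        records.append(ExpressionRecord(gene_id, mrna, te * mrna))

    for pair in dataset.pairs:
        emit(pair.gene1_id, False)
        emit(pair.gene2_id, pair.class_label in ("bh", "sh"))
    for pair in dataset.control_pairs:
        emit(pair.gene1_id, False)
        emit(pair.gene2_id, False)
    dataset.expressions = records
    return records


def generate_ages(dataset: SyntheticDataset) -> dict[str, int]:
    """Gene ages 1..10: young (levels 1-4) with the class's probability,
    otherwise old (levels 5-10)."""
    config = dataset.config
    rng = _rng(config.seed, 3)
    ages: dict[str, int] = {}

    def emit(gene_id: str, p_young: float) -> None:
        if rng.random() < p_young:
            ages[gene_id] = int(rng.integers(1, 5))
        else:
            ages[gene_id] = int(rng.integers(5, 11))

    for pair in dataset.pairs:
        p = config.young_prob_by_class[pair.class_label]
        emit(pair.gene1_id, p)
        emit(pair.gene2_id, p)
    p = config.young_prob_by_class["nonBT"]
    for pair in dataset.control_pairs:
        emit(pair.gene1_id, p)
        emit(pair.gene2_id, p)
    dataset.ages = ages
    return ages


def generate_second_condition(dataset: SyntheticDataset) -> set[tuple[str, str]]:
    """Each BT pair is retained in the second growth condition with its
    class's sharing probability."""
    config = dataset.config
    rng = _rng(config.seed, 4)
    kept = {
        pair.key
        for pair in dataset.pairs
        if rng.random() < config.sharing_prob_by_class[pair.class_label]
    }
    dataset.second_condition = kept
    return kept


def generate_longread_alignments(dataset: SyntheticDataset) -> list[AlignmentRecord]:
    """BLAST-tabular rows emulating CDS queries hit against long direct-RNA
    reads of a second strain.  Pairs retained (per-class sharing
    probability) get 2-3 clean reads; a handful of unretained pairs get
    boundary decoy rows sitting exactly at the identity/coverage/read-length
    thresholds, which strict filters must exclude."""
    config = dataset.config
    rng = _rng(config.seed, 5)
    gene_by_id = {g.gene_id: g for g in dataset.genes}
    rows: list[AlignmentRecord] = []
    read_n = 0
    dropped: list[PairTruth] = []

    for pair in dataset.pairs:
        if rng.random() >= config.sharing_prob_by_class[pair.class_label]:
            dropped.append(pair)
            continue
        g1, g2 = gene_by_id[pair.gene1_id], gene_by_id[pair.gene2_id]
        span = g1.length + g2.length + (pair.spacer_end - pair.spacer_start)
        for _ in range(int(rng.integers(2, 4))):
            read_n += 1
            read_id = f"read{read_n:06d}"
            flank5 = int(rng.integers(20, 80))
            slen = span + flank5 + int(rng.integers(20, 80))
            if slen <= 1000:
                slen = 1001 + int(rng.integers(0, 50))
            minus = rng.random() < 0.2
            pos = flank5
            for gene in (g1, g2):
                qlen = gene.length
                aln = math.ceil(qlen * 0.995)
                ident = float(np.round(rng.uniform(92.0, 99.9), 2))
                s, e = pos + 1, pos + qlen
                if minus:
                    s, e = slen - s + 1, slen - e + 1
                rows.append(
                    AlignmentRecord(
                        query_id=gene.gene_id,
                        subject_id=read_id,
                        percent_identity=ident,
                        alignment_length=aln,
                        query_length=qlen,
                        query_coverage=100.0 * aln / qlen,
                        strand="-" if minus else "+",
                        subject_start=min(s, e),
                        subject_end=max(s, e),
                        subject_length=slen,
                    )
                )
                pos += gene.length + (pair.spacer_end - pair.spacer_start)

    # boundary decoys: each failing exactly one strict filter
    for k, pair in enumerate(dropped[:6]):
        g1, g2 = gene_by_id[pair.gene1_id], gene_by_id[pair.gene2_id]
        mode = k % 3
        for _ in range(2):
            read_n += 1
            read_id = f"decoy{read_n:06d}"
            slen = 1000 if mode == 2 else 1500
            pos = 30
            for gene in (g1, g2):
                if mode == 1:
                    qlen, aln = 300, 297  # coverage exactly 99.0
                else:
                    qlen = gene.length
                    aln = math.ceil(qlen * 0.995)
                ident = 90.0 if mode == 0 else 97.0
                rows.append(
                    AlignmentRecord(
                        query_id=gene.gene_id,
                        subject_id=read_id,
                        percent_identity=ident,
                        alignment_length=aln,
                        query_length=qlen,
                        query_coverage=100.0 * aln / qlen,
                        strand="+",
                        subject_start=pos + 1,
                        subject_end=pos + qlen,
                        subject_length=slen,
                    )
                )
                pos += qlen + 50
    dataset.longread_alignments = rows
    return rows


def generate_ortholog_alignments(
    dataset: SyntheticDataset,
    p: float | None = None,
    q: float | None = None,
) -> dict[str, tuple[str, str]]:
    """Ortholog alignment per BT spacer: the second sequence carries a
    transition with probability p and a transversion with probability q at
    each site (gapless, so every site is comparable)."""
    config = dataset.config
    if p is None:
        p = config.ortholog_transition_prob
    if q is None:
        q = config.ortholog_transversion_prob
    rng = _rng(config.seed, 6)
    transition = str.maketrans("ACGT", "GTAC")
    transversions = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}
    out: dict[str, tuple[str, str]] = {}
    for pair in dataset.pairs:
        seq = dataset.spacer_sequence(pair)
        u = rng.random(len(seq))
        pick = rng.integers(0, 2, len(seq))
        mutated = []
        for i, base in enumerate(seq):
            if u[i] < p:
                mutated.append(base.translate(transition))
            elif u[i] < p + q:
                mutated.append(transversions[base][pick[i]])
            else:
                mutated.append(base)
        out[f"{pair.gene1_id}_{pair.gene2_id}"] = (seq, "".join(mutated))
    dataset.ortholog_pairs = out
    return out


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run every generator with per-component RNG streams derived from
    ``config.seed``; the result is byte-identical across runs."""
    if config is None:
        config = SimulationConfig()
    dataset = generate_genome(config)
    generate_isoforms(dataset)
    generate_expression_profiles(dataset)
    generate_ages(dataset)
    generate_second_condition(dataset)
    generate_longread_alignments(dataset)
    generate_ortholog_alignments(dataset)
    return dataset


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the dataset as plain-text files and return the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.gff3",
        "genome": outdir / "genome.fa",
        "isoforms": outdir / "isoforms.tsv",
        "expression": outdir / "expression.tsv",
        "ages": outdir / "ages.tsv",
        "longreads": outdir / "longreads.tsv",
        "orthologs": outdir / "orthologs.fa",
        "second_condition": outdir / "second_condition.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_gene_annotation_gff3(dataset.genes, paths["annotation"])
    write_fasta(dataset.genome, paths["genome"])
    write_isoform_table(dataset.isoforms, paths["isoforms"])
    write_expression_table(dataset.expressions, paths["expression"])
    write_age_table(dataset.ages, paths["ages"])
    write_alignment_table(dataset.longread_alignments, paths["longreads"])
    ortho = {}
    for name, (a, b) in dataset.ortholog_pairs.items():
        ortho[f"{name}|a"] = a
        ortho[f"{name}|b"] = b
    write_fasta(ortho, paths["orthologs"])
    with open(paths["second_condition"], "w") as fh:
        fh.write("gene1\tgene2\n")
        for g1, g2 in sorted(dataset.second_condition):
            fh.write(f"{g1}\t{g2}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("gene1\tgene2\tclass\tmono1\tmono2\tbt\n")
        for pair in dataset.pairs:
            fh.write(
                f"{pair.gene1_id}\t{pair.gene2_id}\t{pair.class_label}\t"
                f"{pair.mono1}\t{pair.mono2}\t{pair.bt}\n"
            )
    return paths
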