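"""Structural and evolutionary features of intergenic spacers.

Covers the intergenic span between the two genes of a pair, GC content,
minimum folding energy under a simple base-pair energy model (a weighted
Nussinov dynamic program over pseudoknot-free structures), the Kimura
2-parameter distance between aligned ortholog sequences, and selection of
matched non-BT control pairs.

The MFE model scores each allowed pair (GC/CG -3, AU/UA -2, GU/UG -1 by
default, in model units) with a minimum hairpin loop of 3 unpaired bases.
Absolute energies are not comparable to thermodynamic folders; the analysis
uses MFE comparatively, and only orderings between groups are meaningful.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import UndefinedStatisticError, ValidationError
from .io_formats import GeneAnnotation

logger = logging.getLogger(__name__)

DEFAULT_PAIR_ENERGIES: dict[frozenset, float] = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}
MIN_HAIRPIN_LOOP = 3


@dataclass(frozen=True)
class IntergenicRecord:
    gene1_id: str
    gene2_id: str
    length: int
    gc: float
    mfe: float
    sequence: str


@dataclass(frozen=True)
class OrthologPair:
    seq_a: str
    seq_b: str
    p_transitions: float
    q_transversions: float
    k2p: float


# ---------------------------------------------------------------------------
# intergenic span


def intergenic_span(gene1: GeneAnnotation, gene2: GeneAnnotation) -> tuple[int, int, int]:
    """Genomic (start, end, length) of the spacer between two non-overlapping
    same-strand genes on one chromosome.  Adjacent genes give length 0."""
    if gene1.chrom != gene2.chrom:
        raise ValidationError("genes on different chromosomes")
    if gene1.strand != gene2.strand:
        raise ValidationError("genes on different strands")
    up, down = sorted((gene1, gene2), key=lambda g: g.start)
    if up.end > down.start:
        raise ValidationError(
            f"genes {gene1.gene_id}/{gene2.gene_id} overlap; spacer undefined"
        )
    return up.end, down.start, down.start - up.end


def gc_content(sequence: str) -> float:
    """GC fraction over A/C/G/T(U) symbols only; other symbols are ignored."""
    seq = sequence.upper().replace("U", "T")
    gc = sum(seq.count(x) for x in "GC")
    at = sum(seq.count(x) for x in "AT")
    if gc + at == 0:
        raise UndefinedStatisticError("no unambiguous nucleotides in sequence")
    return gc / (gc + at)


# ---------------------------------------------------------------------------
# minimum folding energy


def mfe_fold(
    sequence: str,
    energies: Mapping[frozenset, float] | None = None,
    min_loop: int = MIN_HAIRPIN_LOOP,
) -> tuple[float, str]:
    """Minimum folding energy and one optimal dot-bracket structure.

    Dynamic-programming minimization over nested (pseudoknot-free)
    structures with at least ``min_loop`` unpaired bases in every hairpin.
    T is read as U; the returned energy is <= 0 and the returned structure
    attains it.
    """
    if energies is None:
        energies = DEFAULT_PAIR_ENERGIES
    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("sequence must be nonempty")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid symbols in sequence: {sorted(bad)}")
    n = len(seq)

    pairable: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            e = energies.get(frozenset((seq[i], seq[j])))
            if e is not None:
                pairable[(i, j)] = e

    # M stored by diagonals: diag[L][i] = M[i, i+L]; pure-slice bifurcation
    # keeps the cubic recurrence in vectorized numpy.
    diag = [np.zeros(n - L) for L in range(n)]
    Epair = [
        np.array([pairable.get((i, i + L), np.inf) for i in range(n - L)])
        for L in range(n)
    ]
    for L in range(min_loop + 1, n):
        m = n - L
        best = np.minimum(diag[L - 1][1 : 1 + m], diag[L - 1][:m])  # i or j unpaired
        if L >= min_loop + 1:
            inner = diag[L - 2][1 : 1 + m] if L >= 2 else np.zeros(m)
            best = np.minimum(best, Epair[L][:m] + inner)  # i pairs j
        for d in range(1, L - 1):  # bifurcation at k = i + d
            best = np.minimum(best, diag[d][:m] + diag[L - d - 1][d + 1 : d + 1 + m])
        diag[L] = best

    M = np.zeros((n, n))
    for L in range(1, n):
        idx = np.arange(n - L)
        M[idx, idx + L] = diag[L]

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = M[i, j]
        if target == 0:
            continue  # the empty structure attains 0; leave the region unpaired
        if target == M[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if target == M[i, j - 1]:
            stack.append((i, j - 1))
            continue
        if (i, j) in pairable and target == pairable[(i, j)] + M[i + 1, j - 1]:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
            continue
        for k in range(i + 1, j):
            if target == M[i, k] + M[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
        else:  # pragma: no cover - DP and traceback use identical arithmetic
            raise AssertionError("traceback failed to reproduce DP decision")

    return float(M[0, n - 1]), "".join(structure)


def structure_energy(
    sequence: str,
    structure: str,
    energies: Mapping[frozenset, float] | None = None,
) -> float:
    """Energy of a given dot-bracket structure on a sequence; validates
    nesting, pairability and the hairpin-loop constraint."""
    if energies is None:
        energies = DEFAULT_PAIR_ENERGIES
    seq = sequence.upper().replace("T", "U")
    if len(seq) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    total = 0.0
    stack = []
    for idx, ch in enumerate(structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            i = stack.pop()
            if idx - i <= MIN_HAIRPIN_LOOP:
                raise ValueError("hairpin loop too small")
            e = energies.get(frozenset((seq[i], seq[idx])))
            if e is None:
                raise ValueError(f"unpairable bases {seq[i]}-{seq[idx]}")
            total += e
    if stack:
        raise ValueError("unbalanced structure")
    return total


# ---------------------------------------------------------------------------
# Kimura 2-parameter distance

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_NUCS = set("ACGT")


def k2p_distance(seq_a: str, seq_b: str) -> tuple[float, float, float]:
    """(p, q, d): transition and transversion fractions over comparable
    sites and the Kimura 2-parameter distance
    d = -1/2 ln(1 - 2p - q) - 1/4 ln(1 - 2q).

    Sites with a gap or ambiguity symbol in either sequence are excluded
    pairwise (MEGA's pairwise-deletion convention).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _NUCS or y not in _NUCS:
            continue
        n += 1
        if x != y:
            if frozenset((x, y)) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise UndefinedStatisticError("no comparable sites in alignment")
    p, q = ts / n, tv / n
    w1 = 1 - 2 * p - q
    w2 = 1 - 2 * q
    if w1 <= 0 or w2 <= 0:
        raise UndefinedStatisticError(
            f"K2P distance saturated (p={p:.3f}, q={q:.3f})"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return p, q, d


# ---------------------------------------------------------------------------
# control pairs and feature tables


def select_control_pairs(
    genes: Sequence[GeneAnnotation],
    bt_pairs: Iterable[tuple[str, str]],
    seed: int | None = None,
    n: int | None = None,
) -> list[tuple[GeneAnnotation, GeneAnnotation]]:
    """Adjacent same-strand non-overlapping gene pairs with no bicistronic
    evidence (matched transcriptional direction, absent from the call set).

    With ``n`` set, a seeded subsample of that size is drawn
    deterministically.
    """
    excluded = {frozenset(p) for p in bt_pairs}
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    controls = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end))
        for g1, g2 in zip(ordered, ordered[1:]):
            if g1.strand != g2.strand:
                continue
            if g1.end > g2.start:
                continue
            if frozenset((g1.gene_id, g2.gene_id)) in excluded:
                continue
            controls.append((g1, g2))
    if n is not None and n < len(controls):
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(controls), size=n, replace=False))
        controls = [controls[i] for i in idx]
    return controls


def intergenic_record(
    gene1: GeneAnnotation,
    gene2: GeneAnnotation,
    genome: Mapping[str, str],
    compute_mfe: bool = True,
) -> IntergenicRecord:
    """Feature record for the spacer between two genes; genes are given in
    transcript order (gene1 = 5') but the spacer is strand-symmetric."""
    start, end, length = intergenic_span(gene1, gene2)
    seq = genome[gene1.chrom][start:end]
    if length == 0:
        gc = 0.0
        mfe = 0.0
    else:
        gc = gc_content(seq)
        mfe = mfe_fold(seq)[0] if compute_mfe else math.nan
    return IntergenicRecord(gene1.gene_id, gene2.gene_id, length, gc, mfe, seq)


def ortholog_pair(seq_a: str, seq_b: str) -> OrthologPair:
    p, q, d = k2p_distance(seq_a, seq_b)
    return OrthologPair(seq_a, seq_b, p, q, d)
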