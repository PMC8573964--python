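"""Translation efficiency and its group contrasts.

TE for a gene is the ratio of ribosome-footprint RPKM to mRNA RPKM: values
below the genomic baseline indicate translational repression.  Group
contrasts (each bicistronic class against non-BT control genes, and the 5'
gene against the 3' gene within a class) use a two-sided Mann-Whitney U
test implemented here; the U convention, exact-enumeration cutoff and the
tie/continuity corrections of the normal approximation are documented on
:func:`mann_whitney_u`.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .classifier import BTClassification
from .exceptions import UndefinedStatisticError
from .io_formats import ExpressionRecord

logger = logging.getLogger(__name__)

EXACT_TOTAL_N = 12  # exact enumeration when n_a + n_b <= this and no ties


@dataclass(frozen=True)
class TEValue:
    gene_id: str
    te: float
    position_in_bt: int | None = None  # 1 or 2
    class_label: str | None = None  # bh / sh / bl / nonBT


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p_two_sided: float
    median_a: float
    median_b: float


def translation_efficiency(mrna_rpkm: float, footprint_rpkm: float) -> float:
    """TE = footprint RPKM / mRNA RPKM; undefined at zero mRNA."""
    if mrna_rpkm < 0 or footprint_rpkm < 0:
        raise ValueError("RPKM values must be non-negative")
    if mrna_rpkm == 0:
        raise UndefinedStatisticError("TE undefined for mrna_rpkm = 0")
    return footprint_rpkm / mrna_rpkm


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    U counts the (a, b) pairs with a < b, plus half of the tied pairs, so
    U = n_a*n_b means every a is below every b.  The two-sided p is computed
    by exact enumeration of all group assignments when n_a + n_b <= 12 and
    there are no ties, and otherwise by the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be nonempty")
    U = float(np.sum(a[:, None] < b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :]))

    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < na + nb
    mean = na * nb / 2.0
    if na + nb <= EXACT_TOTAL_N and not has_ties:
        order = np.argsort(pooled)
        ranks = np.empty(na + nb)
        ranks[order] = np.arange(1, na + nb + 1)
        obs_dev = abs(U - mean)
        count = total = 0
        for combo in itertools.combinations(range(na + nb), na):
            ra = ranks[list(combo)].sum()
            # rank sum of group a -> number of pairs with a > b
            u_gt = ra - na * (na + 1) / 2.0
            u_lt = na * nb - u_gt
            count += abs(u_lt - mean) >= obs_dev - 1e-12
            total += 1
        p = count / total
    else:
        n = na + nb
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            dev = abs(U - mean)
            z = max(dev - 0.5, 0.0) / math.sqrt(var)
            p = min(1.0, 2 * float(norm.sf(z)))
    return GroupComparison(
        group_a="a",
        group_b="b",
        n_a=na,
        n_b=nb,
        U=U,
        p_two_sided=p,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


# ---------------------------------------------------------------------------
# building TE tables and running the contrast set


def te_table(
    expressions: Iterable[ExpressionRecord],
    classifications: Iterable[BTClassification],
    control_genes: Iterable[str] = (),
) -> list[TEValue]:
    """Assign class labels and within-pair positions to TE values.

    Genes with zero mRNA RPKM are excluded (logged).  ``control_genes`` are
    labelled nonBT; genes appearing in a classification win over the control
    label.
    """
    position: dict[str, tuple[str, int]] = {}
    for c in classifications:
        position[c.gene1_id] = (c.label, 1)
        position[c.gene2_id] = (c.label, 2)
    controls = set(control_genes) - set(position)
    out = []
    n_zero = 0
    for rec in expressions:
        if rec.mrna_rpkm == 0:
            n_zero += 1
            continue
        te = translation_efficiency(rec.mrna_rpkm, rec.footprint_rpkm)
        if rec.gene_id in position:
            label, pos = position[rec.gene_id]
            out.append(TEValue(rec.gene_id, te, pos, label))
        elif rec.gene_id in controls:
            out.append(TEValue(rec.gene_id, te, None, "nonBT"))
        else:
            out.append(TEValue(rec.gene_id, te))
    if n_zero:
        logger.info("te_table: %d genes with zero mRNA RPKM excluded", n_zero)
    return out


def compare_te_groups(te_values: Iterable[TEValue]) -> list[GroupComparison]:
    """The full contrast set: each class vs the non-BT controls, and gene 1
    vs gene 2 within each class.  Contrasts with a group of fewer than two
    values are skipped with a warning."""
    values = list(te_values)
    by_class: dict[str, list[float]] = {}
    by_class_pos: dict[tuple[str, int], list[float]] = {}
    for v in values:
        if v.class_label is None:
            continue
        by_class.setdefault(v.class_label, []).append(v.te)
        if v.position_in_bt is not None:
            by_class_pos.setdefault((v.class_label, v.position_in_bt), []).append(v.te)

    results = []

    def run(name_a, sample_a, name_b, sample_b):
        if len(sample_a) < 2 or len(sample_b) < 2:
            logger.warning("contrast %s vs %s skipped (group too small)", name_a, name_b)
            return
        cmp = mann_whitney_u(sample_a, sample_b)
        results.append(
            GroupComparison(
                name_a, name_b, cmp.n_a, cmp.n_b, cmp.U, cmp.p_two_sided,
                cmp.median_a, cmp.median_b,
            )
        )

    non_bt = by_class.get("nonBT", [])
    for label in ("bh", "sh", "bl"):
        if label in by_class:
            run(label, by_class[label], "nonBT", non_bt)
    for label in ("bh", "sh", "bl"):
        run(
            f"{label}:gene1", by_class_pos.get((label, 1), []),
            f"{label}:gene2", by_class_pos.get((label, 2), []),
        )
    return results


TE_COLUMNS = ["group_a", "group_b", "n_a", "n_b", "U", "p_two_sided", "median_a", "median_b"]


def write_comparisons(comparisons: list[GroupComparison], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TE_COLUMNS) + "\n")
        for c in comparisons:
            fh.write(
                f"{c.group_a}\t{c.group_b}\t{c.n_a}\t{c.n_b}\t{c.U:g}\t"
                f"{c.p_two_sided:.6g}\t{c.median_a:.6g}\t{c.median_b:.6g}\n"
            )
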