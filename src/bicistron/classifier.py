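"""Expression classification of bicistronic transcripts.

Each bicistronic pair is compared against the monocistronic isoforms of its
two genes.  The rate statistic bt/(bt+mono) is 0.50 at equal expression; a
gene is "higher" in the bicistronic form only under a strict inequality
bt > mono, which makes the three labels exhaustive and exclusive:

    bh  both genes higher in the bicistronic form
    sh  exactly one gene higher
    bl  neither gene higher (ties count as not higher)
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata, t as t_dist

from .bt_caller import OperonCall
from .enrichment import ContingencyTable2x2
from .exceptions import UndefinedStatisticError

logger = logging.getLogger(__name__)

LABELS = ("bh", "sh", "bl")


@dataclass(frozen=True)
class BTClassification:
    gene1_id: str  # 5' gene
    gene2_id: str
    bt_reads: int
    mono1_reads: int
    mono2_reads: int
    rate1: float
    rate2: float
    label: str
    sh_high_gene: str | None = None  # "gene1"/"gene2", set iff label == "sh"


def bt_rate(bt_reads: int, mono_reads: int) -> float:
    """Rate statistic bt/(bt+mono); 0.50 means equal expression."""
    if bt_reads < 0 or mono_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = bt_reads + mono_reads
    if total == 0:
        raise UndefinedStatisticError("rate undefined when bt and mono are both 0")
    return bt_reads / total


def classify(bt_reads: int, mono1_reads: int, mono2_reads: int) -> tuple[str, str | None]:
    """Return (label, sh_high_gene) for one bicistronic pair."""
    if min(bt_reads, mono1_reads, mono2_reads) < 0:
        raise ValueError("read counts must be non-negative")
    higher1 = bt_reads > mono1_reads
    higher2 = bt_reads > mono2_reads
    if higher1 and higher2:
        return "bh", None
    if higher1 or higher2:
        return "sh", "gene1" if higher1 else "gene2"
    return "bl", None


def classify_calls(
    calls: Iterable[OperonCall], mono_reads: Mapping[str, int]
) -> list[BTClassification]:
    """Classify every bicistronic call against its genes' monocistronic
    read support (genes with no mono isoform contribute 0)."""
    out = []
    for call in calls:
        if not call.is_bicistronic:
            continue
        g1, g2 = call.gene_ids
        m1 = mono_reads.get(g1, 0)
        m2 = mono_reads.get(g2, 0)
        label, high = classify(call.read_support, m1, m2)
        out.append(
            BTClassification(
                gene1_id=g1,
                gene2_id=g2,
                bt_reads=call.read_support,
                mono1_reads=m1,
                mono2_reads=m2,
                rate1=bt_rate(call.read_support, m1),
                rate2=bt_rate(call.read_support, m2),
                label=label,
                sh_high_gene=high,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Spearman correlation of rate against monocistronic expression


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman rho, enumerating all
    permutations of one rank vector (chunked for memory)."""
    n = len(rx)
    mx, my = rx.mean(), ry.mean()
    sx = rx.std()
    sy = ry.std()
    perms = itertools.permutations(range(n))
    total = math.factorial(n)
    count = 0
    chunk_size = 100_000
    it = iter(perms)
    while True:
        chunk = list(itertools.islice(it, chunk_size))
        if not chunk:
            break
        P = np.asarray(chunk)
        s = ry[P] @ rx  # sum of rx[i]*ry[perm[i]] per permutation
        rho = (s / n - mx * my) / (sx * sy)
        count += int(np.sum(np.abs(rho) >= abs(rho_obs) - 1e-12))
    return count / total


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with average ranks for ties; two-sided p via the
    t-approximation for n > 10 and exact permutation for n <= 10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("correlation undefined for constant input")
    rx = rankdata(x)
    ry = rankdata(y)
    sx, sy = rx.std(), ry.std()
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    n = len(x)
    if n <= 10:
        p = _spearman_exact_p(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            tval = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = 2 * float(t_dist.sf(abs(tval), df=n - 2))
    return rho, min(p, 1.0)


def rate_vs_expression(
    classifications: Iterable[BTClassification],
) -> tuple[float, float]:
    """Spearman correlation of the per-gene rate statistic against the
    gene's monocistronic read count, pooled over both genes of each pair."""
    mono, rate = [], []
    for c in classifications:
        mono.extend([c.mono1_reads, c.mono2_reads])
        rate.extend([c.rate1, c.rate2])
    if len(mono) < 3:
        raise ValueError("need at least 3 (mono, rate) points")
    return spearman(mono, rate)


# ---------------------------------------------------------------------------
# per-class summaries


def gene1_higher_proportion(
    classifications: Iterable[BTClassification],
) -> dict[str, tuple[float, float]]:
    """Per class, the fraction of pairs where the bicistronic form exceeds
    the monocistronic form, separately for gene 1 and gene 2."""
    counts: dict[str, list[int]] = {}
    for c in classifications:
        n1, n2, tot = counts.setdefault(c.label, [0, 0, 0])
        counts[c.label] = [
            n1 + (c.bt_reads > c.mono1_reads),
            n2 + (c.bt_reads > c.mono2_reads),
            tot + 1,
        ]
    out = {}
    for label in LABELS:
        if label not in counts:
            logger.warning("class %s empty; omitted from proportions", label)
            continue
        n1, n2, tot = counts[label]
        out[label] = (n1 / tot, n2 / tot)
    return out


def pebt_pemt_split(
    sh_classifications: Iterable[BTClassification],
    ages: Mapping[str, int],
    young_levels: frozenset[int] | set[int] = frozenset({1, 2, 3, 4}),
) -> ContingencyTable2x2:
    """Cross-tabulate sh-pair genes by expression preference and age.

    Row 1 = PEBT genes (preferentially expressed as a bicistronic
    transcript, bt > mono), row 2 = PEMT genes; columns = young / old.
    """
    a = b = c = d = 0
    n_missing = 0
    for cls in sh_classifications:
        if cls.label != "sh":
            continue
        for gene, mono in (
            (cls.gene1_id, cls.mono1_reads),
            (cls.gene2_id, cls.mono2_reads),
        ):
            if gene not in ages:
                n_missing += 1
                continue
            young = ages[gene] in young_levels
            pebt = cls.bt_reads > mono
            if pebt:
                a += young
                b += not young
            else:
                c += young
                d += not young
    if n_missing:
        logger.info("pebt_pemt_split: %d genes skipped for missing age", n_missing)
    return ContingencyTable2x2(a, b, c, d)


# ---------------------------------------------------------------------------
# classification table round trip

CLASSIFICATION_COLUMNS = [
    "gene1", "gene2", "bt_reads", "mono1", "mono2", "rate1", "rate2",
    "label", "sh_high_gene",
]


def write_classifications(classifications: list[BTClassification], path) -> None:
    rows = sorted(classifications, key=lambda c: (c.gene1_id, c.gene2_id))
    with open(path, "w") as fh:
        fh.write("\t".join(CLASSIFICATION_COLUMNS) + "\n")
        for c in rows:
            fh.write(
                f"{c.gene1_id}\t{c.gene2_id}\t{c.bt_reads}\t{c.mono1_reads}\t"
                f"{c.mono2_reads}\t{c.rate1:.6g}\t{c.rate2:.6g}\t{c.label}\t"
                f"{c.sh_high_gene or '.'}\n"
            )


def read_classifications(path) -> list[BTClassification]:
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    for line in lines[1:]:
        g1, g2, bt, m1, m2, r1, r2, label, high = line.split("\t")
        out.append(
            BTClassification(
                g1, g2, int(bt), int(m1), int(m2), float(r1), float(r2),
                label, None if high == "." else high,
            )
        )
    return out
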