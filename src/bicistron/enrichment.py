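"""Conservation sharing and gene-age enrichment.

Shared/unique accounting of bicistronic transcripts across growth conditions
and strains (identity of a transcript is its ordered gene pair), fold
changes, young-gene fractions, and a two-sided Fisher exact test implemented
by full hypergeometric enumeration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

CLASS_LABELS = ("bh", "sh", "bl")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")


@dataclass(frozen=True)
class SharingSummary:
    class_label: str
    n_shared: int
    n_unique: int
    fold_change: float  # shared/unique; inf when n_unique == 0


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact test.

    p sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (the
    probability-mass rule).  Odds ratio is (a*d)/(b*c), infinite when b*c = 0
    with a*d > 0.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b + c + d == 0:
        raise ValidationError("Fisher test undefined for an all-zero table")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_pmf(x: int) -> float:
        return _log_binom(r1, x) + _log_binom(r2, c1 - x) - _log_binom(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = math.exp(log_pmf(a))
    p = sum(
        math.exp(lp)
        for x in range(lo, hi + 1)
        if math.exp(lp := log_pmf(x)) <= p_obs * (1 + 1e-9)
    )
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return odds, min(p, 1.0)


# ---------------------------------------------------------------------------
# sharing across conditions / strains


def _pair_keys(calls) -> set[tuple[str, str]]:
    keys = set()
    for c in calls:
        if isinstance(c, tuple):
            keys.add(c)
        elif c.is_bicistronic:
            keys.add(c.gene_ids)
    return keys


def condition_overlap(
    calls_a,
    calls_b,
    labels: Mapping[tuple[str, str], str],
    unique_from: str = "union",
) -> dict[str, SharingSummary]:
    """Per-class shared/unique accounting between two growth conditions.

    ``labels`` maps ordered gene pairs to bh/sh/bl (taken from the reference
    condition's classification).  Pairs without a label are ignored.
    ``unique_from`` selects the denominator convention: "union" counts pairs
    unique to either condition, "a" only those unique to the first.
    """
    if unique_from not in ("union", "a"):
        raise ValueError("unique_from must be 'union' or 'a'")
    set_a = _pair_keys(calls_a)
    set_b = _pair_keys(calls_b)
    shared = set_a & set_b
    unique = (set_a ^ set_b) if unique_from == "union" else (set_a - set_b)
    out = {}
    for label in CLASS_LABELS:
        n_sh = sum(1 for k in shared if labels.get(k) == label)
        n_un = sum(1 for k in unique if labels.get(k) == label)
        if n_un == 0:
            fold = math.inf
            logger.info("class %s: no unique pairs; fold change flagged inf", label)
        else:
            fold = n_sh / n_un
        out[label] = SharingSummary(label, n_sh, n_un, fold)
    return out


def strain_sharing(
    calls_ref,
    calls_other,
    labels: Mapping[tuple[str, str], str],
) -> tuple[dict[str, tuple[int, int, float]], dict[tuple[str, str], tuple[float, float]]]:
    """Per class, the proportion of reference-strain calls also found in the
    other strain, plus pairwise Fisher tests (shared/unshared x class).

    Returns ({class: (n_shared, n_total, proportion)},
             {(classA, classB): (odds_ratio, p)}).
    """
    ref = _pair_keys(calls_ref)
    other = _pair_keys(calls_other)
    counts: dict[str, tuple[int, int]] = {}
    for label in CLASS_LABELS:
        members = [k for k in ref if labels.get(k) == label]
        if not members:
            logger.warning("class %s empty in reference call set; omitted", label)
            continue
        n_shared = sum(1 for k in members if k in other)
        counts[label] = (n_shared, len(members))
    proportions = {
        lab: (s, t, s / t) for lab, (s, t) in counts.items()
    }
    tests = {}
    labs = [lab for lab in CLASS_LABELS if lab in counts]
    for i, la in enumerate(labs):
        for lb in labs[i + 1 :]:
            sa, ta = counts[la]
            sb, tb = counts[lb]
            table = ContingencyTable2x2(sa, ta - sa, sb, tb - sb)
            tests[(la, lb)] = fisher_exact_2x2(table)
    return proportions, tests


# ---------------------------------------------------------------------------
# gene-age enrichment


def young_gene_enrichment(
    genes_by_class: Mapping[str, Iterable[str]],
    ages: Mapping[str, int],
    young_levels: frozenset[int] | set[int] = frozenset({1, 2, 3, 4}),
) -> tuple[dict[str, tuple[int, int, float]], dict[tuple[str, str], tuple[float, float]]]:
    """Per class (bh/sh/bl/nonBT), the fraction of genes whose age level
    falls in ``young_levels``, plus pairwise Fisher tests between classes.

    Genes without an age are excluded (logged).  Returns
    ({class: (n_young, n_total, fraction)}, {(classA, classB): (odds, p)}).
    """
    if not set(young_levels) <= set(range(1, 11)):
        raise ValueError("young_levels must be a subset of 1..10")
    counts: dict[str, tuple[int, int]] = {}
    for label, genes in genes_by_class.items():
        n_young = n_total = n_missing = 0
        for g in genes:
            if g not in ages:
                n_missing += 1
                continue
            n_total += 1
            n_young += ages[g] in young_levels
        if n_missing:
            logger.info("class %s: %d genes without age excluded", label, n_missing)
        if n_total == 0:
            logger.warning("class %s has no aged genes; omitted", label)
            continue
        counts[label] = (n_young, n_total)
    fractions = {lab: (y, t, y / t) for lab, (y, t) in counts.items()}
    tests = {}
    labs = sorted(counts)
    for i, la in enumerate(labs):
        for lb in labs[i + 1 :]:
            ya, ta = counts[la]
            yb, tb = counts[lb]
            table = ContingencyTable2x2(ya, ta - ya, yb, tb - yb)
            tests[(la, lb)] = fisher_exact_2x2(table)
    return fractions, tests
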