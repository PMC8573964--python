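# bicistron

Detection and characterization of operon-like (bi-/tricistronic)
transcripts in yeast-style transcriptomes.

Although eukaryotic genes are overwhelmingly monocistronic, transcript
isoform sequencing (TIF-seq) and long direct-RNA reads reveal transcripts
whose boundaries fully contain two or more adjacent same-strand genes.
`bicistron` is for researchers who want to (1) call such transcripts from
transcript-boundary tables or BLAST-tabular long-read alignments, (2)
classify each bicistronic pair by expression relative to its monocistronic
equivalents, and (3) quantify the genomic and translational signatures
that separate candidate-functional transcripts from transcriptional noise
— all reproducibly, with a seeded synthetic-data generator in place of the
original sequencing resources.

## The statistics at the core

For a gene with bicistronic read support *bt* and monocistronic support
*mono*, the **rate statistic** is

    rate = bt / (bt + mono)          (0.50 ⇔ equal expression)

Each bicistronic pair is labelled by strict comparisons of *bt* against
both genes' *mono* counts: **bh** (both higher), **sh** (exactly one
higher), **bl** (neither; ties are not higher). Downstream quantities:

* **Translation efficiency** TE = footprint RPKM / mRNA RPKM, contrasted
  between classes and within pairs with a two-sided Mann-Whitney U test
  (exact for combined n ≤ 12 without ties, tie- and continuity-corrected
  normal approximation otherwise).
* **Intergenic features**: spacer length; GC content; minimum folding
  energy from a weighted Nussinov DP (pair energies GC = −3, AU = −2,
  GU = −1, minimum hairpin loop 3 — comparative, not thermodynamic); and
  the Kimura 2-parameter distance
  d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q) for ortholog alignments.
* **Conservation and age**: per-class shared/unique fold changes across
  conditions, shared proportions across strains, and young-gene fractions
  (age levels 1–4 of 10), tested with a two-sided Fisher exact test
  (probability-mass rule over the hypergeometric distribution).

The long-read caller applies the strict filters >90% identity, >99% query
coverage and >1 kb read length, with ≥2 supporting reads; rows exactly at
a threshold are excluded.

See `docs/methods.md` for the full model description, generator design and
numerical choices.

## Worked example

Generate a dataset at the default study conditions (300 gene pairs, class
proportions 0.10/0.25/0.65, mean depth 100 reads) and run the pipeline:

```python
from bicistron import (call_operons, classify_calls, compare_te_groups,
                       mono_summaries, rate_vs_expression, te_table)
from bicistron.bt_caller import GeneIndex
from bicistron.synthetic_data import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(seed=1))
index = GeneIndex(ds.genes)
calls = call_operons(ds.isoforms, index)                 # 300 calls
monos = {m.gene_id: m.mono_reads for m in mono_summaries(ds.isoforms, index)}
classifications = classify_calls(calls, monos)

rho, p = rate_vs_expression(classifications)
print(f"rho={rho:.3f} p={p:.3g}")                        # rho=-0.502 p=1.09e-39

values = te_table(ds.expressions, classifications, sorted(ds.control_gene_ids))
for c in compare_te_groups(values):
    print(c.group_a, "vs", c.group_b, f"p={c.p_two_sided:.3g}")
```

which prints (classes recovered: 30 bh, 75 sh, 195 bl):

```
       bh vs nonBT     p=0.00062
       sh vs nonBT     p=7.26e-12
       bl vs nonBT     p=0.289
 bh:gene1 vs bh:gene2  p=3.52e-07
 sh:gene1 vs sh:gene2  p=9.53e-19
 bl:gene1 vs bl:gene2  p=0.729
```

Read: the rate statistic falls with monocistronic expression (negative ρ,
consistent with most bicistronic transcripts being molecular errors); TE
of highly expressed classes is depressed relative to non-BT controls while
bl is indistinguishable from them; and within bh/sh pairs the 3′ gene — but
not the 5′ gene — is translationally repressed.

The same pipeline is available from the shell:

```sh
bicistron run-all --seed 1 --outdir results/
bicistron simulate --seed 1 --outdir data/
bicistron call --annotation data/annotation.gff3 --isoforms data/isoforms.tsv --out calls.tsv
```

`run-all` writes `calls.tsv`, `classifications.tsv`, `te_contrasts.tsv`,
`features.tsv` and a `summary.json` with per-class counts, the
rate–expression correlation, contrast p-values, per-class feature medians,
sharing fold changes and young-gene fractions.

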