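"""The synthetic-data generator: determinism, self-checks, forced cases."""

import math

import numpy as np
import pytest

from bicistron.bt_caller import GeneIndex, call_bt_from_alignments, call_operons, mono_summaries
from bicistron.classifier import classify_calls
from bicistron.exceptions import ValidationError
from bicistron.intergenic_features import gc_content, k2p_distance
from bicistron.io_formats import read_gene_annotation, read_isoform_table
from bicistron.synthetic_data import (
    SimulationConfig,
    generate_genome,
    generate_isoforms,
    generate_ortholog_alignments,
    simulate_dataset,
    write_dataset,
)


class TestConfig:
    def test_default_config_valid(self):
        SimulationConfig().validate()

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(class_proportions=(0.5, 0.5, 0.5)).validate()

    def test_bad_probability_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(minus_strand_prob=1.5).validate()

    def test_json_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_gene_pairs=7, seed=42)
        p = tmp_path / "cfg.json"
        cfg.to_json(p)
        assert SimulationConfig.from_json(p) == cfg


class TestDeterminism:
    def test_outputs_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(n_gene_pairs=10, n_control_pairs=5, seed=1)
        d1 = tmp_path / "run1"
        d2 = tmp_path / "run2"
        p1 = write_dataset(simulate_dataset(cfg), d1)
        p2 = write_dataset(simulate_dataset(cfg), d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seeds_differ(self):
        a = simulate_dataset(SimulationConfig(n_gene_pairs=10, n_control_pairs=2, seed=1))
        b = simulate_dataset(SimulationConfig(n_gene_pairs=10, n_control_pairs=2, seed=2))
        assert a.genome != b.genome


class TestGenome:
    def test_gc_medians_ordered_by_class(self):
        cfg = SimulationConfig(n_gene_pairs=200, n_control_pairs=0, seed=4)
        ds = generate_genome(cfg)
        by_class = {}
        for pair in ds.pairs:
            by_class.setdefault(pair.class_label, []).append(
                gc_content(ds.spacer_sequence(pair))
            )
        med = {k: float(np.median(v)) for k, v in by_class.items()}
        assert med["bh"] > med["bl"]

    def test_minimal_config_parseable(self, tmp_path):
        cfg = SimulationConfig(n_gene_pairs=1, n_control_pairs=1, seed=9)
        paths = write_dataset(simulate_dataset(cfg), tmp_path)
        genes = read_gene_annotation(paths["annotation"])
        assert len(genes) == 4
        isoforms = read_isoform_table(paths["isoforms"])
        assert len(isoforms) >= 5
        calls = call_operons(isoforms, genes)
        assert len(calls) == 1

    def test_spacer_boundaries_between_genes(self):
        ds = generate_genome(SimulationConfig(n_gene_pairs=20, n_control_pairs=0, seed=3))
        genes = {g.gene_id: g for g in ds.genes}
        for pair in ds.pairs:
            g1, g2 = genes[pair.gene1_id], genes[pair.gene2_id]
            left, right = sorted((g1, g2), key=lambda g: g.start)
            assert pair.spacer_start == left.end
            assert pair.spacer_end == right.start


class TestIsoforms:
    def test_pure_bl_config_recovered(self):
        cfg = SimulationConfig(
            n_gene_pairs=100, n_control_pairs=0,
            class_proportions=(0.0, 0.0, 1.0), seed=6,
        )
        ds = generate_genome(cfg)
        generate_isoforms(ds)
        index = GeneIndex(ds.genes)
        calls = call_operons(ds.isoforms, index)
        monos = {m.gene_id: m.mono_reads for m in mono_summaries(ds.isoforms, index)}
        labels = [c.label for c in classify_calls(calls, monos)]
        assert len(labels) == 100
        assert labels.count("bl") / len(labels) >= 0.95

    def test_class_assignment_exactly_recovered(self, default_dataset):
        """Counts are drawn conditional on class, so the classifier must
        recover the generator's label for every called pair."""
        ds = default_dataset
        index = GeneIndex(ds.genes)
        calls = call_operons(ds.isoforms, index)
        monos = {m.gene_id: m.mono_reads for m in mono_summaries(ds.isoforms, index)}
        recovered = {
            (c.gene1_id, c.gene2_id): c.label
            for c in classify_calls(calls, monos)
        }
        truth = {pair.key: pair.class_label for pair in ds.pairs}
        assert recovered == truth


class TestAncillaryGenerators:
    def test_full_sharing_forces_all_shared(self):
        cfg = SimulationConfig(
            n_gene_pairs=30, n_control_pairs=0, seed=8,
            sharing_prob_by_class={"bh": 1.0, "sh": 1.0, "bl": 1.0},
        )
        ds = simulate_dataset(cfg)
        assert ds.second_condition == {p.key for p in ds.pairs}

    def test_boundary_alignment_rows_excluded_by_caller(self, default_dataset):
        rows = default_dataset.longread_alignments
        decoys = [r for r in rows if r.subject_id.startswith("decoy")]
        assert decoys, "generator must plant threshold-equal rows"
        assert any(r.percent_identity == 90.0 for r in decoys)
        assert any(r.query_coverage == 99.0 for r in decoys)
        assert any(r.subject_length == 1000 for r in decoys)
        called = {g for c in call_bt_from_alignments(rows) for g in c.gene_ids}
        assert not called & {r.query_id for r in decoys if r.percent_identity == 90.0}

    def test_ortholog_mutation_rates_match_closed_form(self):
        cfg = SimulationConfig(n_gene_pairs=6, n_control_pairs=0, seed=10,
                               intergenic_length_by_class={"bh": 2500.0, "sh": 2500.0, "bl": 2500.0},
                               stem_length_by_class={"bh": 0, "sh": 0, "bl": 0})
        ds = generate_genome(cfg)
        pairs = generate_ortholog_alignments(ds, p=0.1, q=0.05)
        seqs_a = "".join(a for a, _ in pairs.values())
        seqs_b = "".join(b for _, b in pairs.values())
        assert len(seqs_a) >= 10_000
        p, q, d = k2p_distance(seqs_a, seqs_b)
        expected = -0.5 * math.log(0.75) - 0.25 * math.log(0.90)
        assert d == pytest.approx(expected, abs=0.01)

    def test_expression_null_when_repression_off(self):
        cfg = SimulationConfig(n_gene_pairs=60, n_control_pairs=0, seed=12,
                               te_repression_gene2=1.0)
        ds = simulate_dataset(cfg)
        te = {r.gene_id: r.footprint_rpkm / r.mrna_rpkm for r in ds.expressions}
        g1 = [te[p.gene1_id] for p in ds.pairs if p.class_label == "bh"]
        g2 = [te[p.gene2_id] for p in ds.pairs if p.class_label == "bh"]
        from bicistron.te_stats import mann_whitney_u

        assert mann_whitney_u(g1, g2).p_two_sided > 0.01
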