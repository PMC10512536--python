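"""The generator's own guarantees: determinism, truth-log consistency,
and agreement with birth-death expectations."""

import numpy as np
import pytest

from opsinkit.errors import OpsinkitError
from opsinkit.io_core import extract_cds_and_flanks, parse_newick, to_newick
from opsinkit.reconciliation import lca_reconcile
from opsinkit.synthetic_data import (
    ArtifactSpec,
    ExpressionSpec,
    SimConfig,
    emit_sequences,
    inject_assembly_artifacts,
    make_expression_matrix,
    simulate_gene_family,
)


class TestGeneFamily:
    def test_no_turnover_gives_one_congruent_gene_per_species(self):
        cfg = SimConfig(seed=1, dup_rate=0.0, loss_rate=0.0)
        fam = simulate_gene_family(cfg)
        assert len(fam.gene_tree.leaf_names()) == 7
        assert all(len(v) == 1 for v in fam.genes_by_species.values())
        rec = lca_reconcile(fam.gene_tree, fam.species_tree)
        assert rec.cost == 0

    def test_event_log_accounts_for_every_extra_leaf(self):
        """With no loss, each duplication on a branch adds exactly one
        leaf per species below that branch."""
        stree = parse_newick(SimConfig(seed=0).species_tree_newick)
        label_to_leaves = {}
        for node in stree.postorder():
            label = node.name or "+".join(sorted(node.leaf_names()))
            label_to_leaves[label] = len(node.leaf_names())
        for seed in range(30):
            cfg = SimConfig(seed=seed, dup_rate=0.35, loss_rate=0.0)
            fam = simulate_gene_family(cfg)
            expected = 7 + sum(label_to_leaves[e.species_branch]
                               for e in fam.truth.events
                               if e.kind == "duplication")
            assert len(fam.gene_tree.leaf_names()) == expected

    def test_true_counts_match_reconciliation_when_no_loss(self):
        cfg = SimConfig(seed=13, dup_rate=0.3, loss_rate=0.0)
        fam = simulate_gene_family(cfg)
        rec = lca_reconcile(fam.gene_tree, fam.species_tree)
        for node in fam.species_tree.postorder():
            if node.is_leaf:
                continue
            label = node.name or "+".join(sorted(node.leaf_names()))
            assert rec.implied_counts[node] == fam.truth.true_counts[label]

    def test_mean_leaf_count_matches_birth_death_expectation(self):
        """Monte-Carlo mean per-species gene count vs e^{(lambda-mu)T}
        on the depth-4 ultrametric default tree."""
        lam, mu, depth = 0.15, 0.05, 4.0
        counts = []
        for seed in range(1000):
            cfg = SimConfig(seed=seed, dup_rate=lam, loss_rate=mu, retry_cap=1)
            try:
                fam = simulate_gene_family(cfg)
                per_species = [len(v) for v in fam.genes_by_species.values()]
            except OpsinkitError:
                per_species = [0] * 7
            counts.extend(per_species)
        counts = np.array(counts, dtype=float)
        expected = np.exp((lam - mu) * depth)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected) < 3 * se + 1e-9

    def test_seed_reproducibility(self):
        cfg = SimConfig(seed=99, dup_rate=0.3, loss_rate=0.1)
        t1 = to_newick(simulate_gene_family(cfg).gene_tree)
        t2 = to_newick(simulate_gene_family(cfg).gene_tree)
        assert t1 == t2

    def test_mandatory_seed(self):
        with pytest.raises(OpsinkitError):
            SimConfig(seed=None)


class TestEmission:
    def test_cds_round_trip_through_extraction(self):
        cfg = SimConfig(seed=5, dup_rate=0.25, loss_rate=0.1)
        fam = simulate_gene_family(cfg)
        emitted = emit_sequences(fam, cfg)
        for model in emitted.models:
            ext = extract_cds_and_flanks(emitted.genome, model, flank_len=100)
            assert ext.cds == next(c.seq for c in emitted.cds
                                   if c.id == model.gene_id)
            assert ext.protein == next(p.seq for p in emitted.proteins
                                       if p.id == model.gene_id)

    def test_retro_duplicates_are_intronless(self):
        cfg = SimConfig(seed=21, dup_rate=0.6, loss_rate=0.0, retro_prob=1.0)
        fam = simulate_gene_family(cfg)
        assert fam.truth.n_duplications > 0
        assert all(e.mechanism == "retro" for e in fam.truth.events
                   if e.kind == "duplication")
        emitted = emit_sequences(fam, cfg)
        models = {m.gene_id: m for m in emitted.models}
        for gene in fam.retro_genes:
            assert models[gene].n_introns == 0
        assert fam.retro_genes  # the scenario actually exercises the rule

    def test_planted_intron_truth_matches_models(self):
        from opsinkit.intron_projection import cds_intron_phases
        cfg = SimConfig(seed=8, dup_rate=0.2, loss_rate=0.0)
        fam = simulate_gene_family(cfg)
        emitted = emit_sequences(fam, cfg)
        for model in emitted.models:
            bounds = cds_intron_phases(model)
            assert [(b.residue_index, b.phase) for b in bounds] \
                == fam.truth.planted_introns[model.gene_id]

    def test_emission_deterministic_under_seed(self):
        cfg = SimConfig(seed=44, dup_rate=0.3, loss_rate=0.1)
        a = emit_sequences(simulate_gene_family(cfg), cfg)
        b = emit_sequences(simulate_gene_family(cfg), cfg)
        assert a.genome == b.genome
        assert [(m.gene_id, m.exons) for m in a.models] \
            == [(m.gene_id, m.exons) for m in b.models]


class TestArtifactInjection:
    def test_zero_injections_leave_genome_unchanged(self):
        cfg = SimConfig(seed=3, artifact=ArtifactSpec(n_artifacts=0,
                                                      n_true_tandem=0))
        fam = simulate_gene_family(cfg)
        emitted = emit_sequences(fam, cfg)
        asm = inject_assembly_artifacts(emitted, fam, cfg)
        assert asm.genome == emitted.genome
        assert asm.second_genome == emitted.genome

    def test_artifact_copies_absent_from_second_assembly(self):
        cfg = SimConfig(seed=4, artifact=ArtifactSpec(n_artifacts=2,
                                                      n_true_tandem=1))
        fam = simulate_gene_family(cfg)
        asm = inject_assembly_artifacts(emit_sequences(fam, cfg), fam, cfg)
        ids1 = {m.gene_id for m in asm.models}
        ids2 = {m.gene_id for m in asm.second_models}
        artifacts = {b for _, b, k in fam.truth.artifact_pairs if k == "artifact"}
        tandems = {b for _, b, k in fam.truth.artifact_pairs if k == "true_tandem"}
        assert artifacts <= ids1 and not (artifacts & ids2)
        assert tandems <= ids1 and tandems <= ids2

    def test_n_run_separates_artifact_pair(self):
        cfg = SimConfig(seed=6, artifact=ArtifactSpec(
            n_artifacts=1, n_true_tandem=0, n_run_length=120))
        fam = simulate_gene_family(cfg)
        asm = inject_assembly_artifacts(emit_sequences(fam, cfg), fam, cfg)
        orig, copy, _ = fam.truth.artifact_pairs[0]
        models = {m.gene_id: m for m in asm.models}
        lo = models[orig].span[1]
        hi = models[copy].span[0]
        between = asm.genome[models[orig].chrom][lo:hi]
        assert "N" * 120 in between


class TestExpression:
    def test_zero_noise_recovers_planted_peaks_exactly(self):
        cfg = SimConfig(seed=10, expression=ExpressionSpec(noise_sigma=0.0))
        matrix, sheet = make_expression_matrix(cfg, [f"t{i}" for i in range(40)])
        truth = matrix.attrs["truth"]
        stages = sheet.loc[list(matrix.columns), "stage"]
        means = matrix.T.groupby(stages.values).mean().T
        for t in matrix.index:
            assert means.loc[t].idxmax() == truth[t]["peak"]

    def test_fixed_seed_is_byte_identical(self):
        cfg = SimConfig(seed=10)
        a, _ = make_expression_matrix(cfg, ["t1", "t2", "t3"])
        b, _ = make_expression_matrix(cfg, ["t1", "t2", "t3"])
        assert a.equals(b)
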