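"""Reconciliation, support gating, and count parsimony."""

import numpy as np
import pytest
from scipy.optimize import minimize

from opsinkit.errors import OpsinkitError
from opsinkit.io_core import CountTable, parse_newick
from opsinkit.reconciliation import (
    ancestral_counts_continuous,
    ancestral_counts_meristic,
    collapse_by_support,
    lca_reconcile,
    repertoire_history,
    resolve_polytomies,
)
from oracles import (
    all_gene_trees,
    brute_force_dl_cost,
    brute_force_sankoff,
    shape_to_tree,
)


class TestCollapseBySupport:
    def test_fully_supported_tree_unchanged(self):
        tree = parse_newick("((A,B)100/100,(C,D)100/100);")
        out = collapse_by_support(tree)
        assert all(len(n.children) in (0, 2) for n in out.postorder())

    @pytest.mark.parametrize("support", ["70/99", "85/90", "79/96"])
    def test_branch_failing_either_threshold_collapsed(self, support):
        tree = parse_newick(f"((A,B){support},C);")
        out = collapse_by_support(tree)
        assert len(out.root.children) == 3  # polytomy at the root

    def test_missing_support_kept_with_warning(self):
        tree = parse_newick("((A,B),C);")
        with pytest.warns(UserWarning, match="support"):
            out = collapse_by_support(tree)
        assert len(out.root.children) == 2


class TestLcaReconcile:
    def test_congruent_trees_have_zero_events(self):
        g = parse_newick("((A__1,B__1),C__1);")
        s = parse_newick("((A,B),C);")
        rec = lca_reconcile(g, s)
        assert rec.duplications_total == 0 and rec.losses_total == 0
        assert rec.implied_counts[s.root] == 1

    def test_two_subclades_mean_two_at_the_ancestor(self):
        g = parse_newick(
            "((Ceriantharia__1,OtherHexacorallia__1),"
            "(Ceriantharia__2,OtherHexacorallia__2));")
        s = parse_newick("(Ceriantharia,OtherHexacorallia);")
        rec = lca_reconcile(g, s)
        assert rec.duplications_total == 1
        assert rec.implied_counts[s.root] == 2

    def test_duplication_with_loss_in_the_other_species(self):
        g = parse_newick("((A__1,B__1),A__2);")
        s = parse_newick("(A,B);")
        rec = lca_reconcile(g, s)
        assert rec.duplications_total == 1
        assert rec.losses_total == 1
        b_leaf = next(n for n in s.leaves() if n.name == "B")
        assert rec.losses_per_branch[b_leaf] == 1

    def test_non_total_leaf_map_is_an_error(self):
        g = parse_newick("(x,y);")
        s = parse_newick("(A,B);")
        with pytest.raises(OpsinkitError, match="leaf map"):
            lca_reconcile(g, s, {"x": "A"})

    @pytest.mark.parametrize("species_newick,species", [
        ("(A,B);", ["A", "B"]),
        ("((A,B),C);", ["A", "B", "C"]),
    ])
    def test_cost_matches_exhaustive_enumeration(self, species_newick, species):
        """LCA reconciliation is the duplication-loss minimum on every
        rooted binary gene tree with up to 4 leaves (the 5-leaf sweep
        runs in the acceptance suite)."""
        stree = parse_newick(species_newick)
        for shape in all_gene_trees(species, 4):
            gtree, lmap = shape_to_tree(shape)
            rec = lca_reconcile(gtree, stree, lmap)
            assert rec.cost == brute_force_dl_cost(gtree, stree, lmap), shape


class TestResolvePolytomies:
    def test_star_tree_resolves_congruently(self):
        g = parse_newick("(A__1,B__1,C__1);")
        s = parse_newick("((A,B),C);")
        resolved = resolve_polytomies(g, s)
        rec = lca_reconcile(resolved, s)
        assert rec.duplications_total == 0 and rec.losses_total == 0

    def test_collapse_then_resolve_minimizes_spurious_duplications(self):
        # weakly supported conflict: ((A,C) 50/50, B) -> collapsed -> star
        g = parse_newick("((A__1,C__1)50/50,B__1);")
        s = parse_newick("((A,B),C);")
        collapsed = collapse_by_support(g)
        rec = lca_reconcile(collapsed, s)
        assert rec.duplications_total == 0


class TestMeristic:
    def test_uniform_counts_cost_zero(self):
        s = parse_newick("(((A,B),C),D);")
        anc = ancestral_counts_meristic(s, {"A": 2, "B": 2, "C": 2, "D": 2})
        assert anc.cost == 0
        assert all(v == 2 for v in anc.values.values())

    def test_balanced_four_leaf_matches_brute_force(self):
        s = parse_newick("((L1,L2),(L3,L4));")
        counts = {"L1": 2, "L2": 2, "L3": 0, "L4": 1}
        anc = ancestral_counts_meristic(s, counts)
        bcost, broots = brute_force_sankoff(s, counts, n_states=5)
        assert anc.cost == bcost
        assert anc.optimal_sets[s.root] == broots

    def test_two_leaf_linear_cost_telescopes(self):
        s = parse_newick("(X,Y);")
        anc = ancestral_counts_meristic(s, {"X": 0, "Y": 4})
        assert anc.cost == 4
        assert anc.optimal_sets[s.root] == {0, 1, 2, 3, 4}
        assert s.root in anc.ties

    def test_missing_leaves_do_not_constrain(self):
        s = parse_newick("((A,B),C);")
        anc = ancestral_counts_meristic(s, {"A": 3, "B": 3}, missing={"C"})
        assert anc.values[s.root] == 3 and anc.cost == 0

    def test_negative_counts_rejected(self):
        s = parse_newick("(A,B);")
        with pytest.raises(OpsinkitError):
            ancestral_counts_meristic(s, {"A": -1, "B": 2})


class TestContinuous:
    def test_constant_leaves_give_constant_nodes(self):
        s = parse_newick("((A:1,B:2):1,C:3);")
        anc = ancestral_counts_continuous(s, {"A": 5, "B": 5, "C": 5})
        assert all(v == pytest.approx(5) for v in anc.values.values())

    def test_two_leaf_equal_lengths_midpoint(self):
        s = parse_newick("(X:1,Y:1);")
        anc = ancestral_counts_continuous(s, {"X": 0, "Y": 4})
        assert anc.values[s.root] == pytest.approx(2.0)

    def test_matches_generic_numeric_optimizer(self):
        s = parse_newick("(((A:0.5,B:2):1.5,C:1):0.7,D:3);")
        counts = {"A": 1.0, "B": 6.0, "C": 0.0, "D": 4.0}
        anc = ancestral_counts_continuous(s, counts)
        internal = [n for n in s.postorder() if not n.is_leaf]
        leaves = {n.name: n for n in s.leaves()}

        def objective(x):
            vals = {n: x[i] for i, n in enumerate(internal)}
            vals.update({leaves[k]: v for k, v in counts.items()})
            total = 0.0
            for n in s.postorder():
                if n.parent is not None:
                    total += (vals[n.parent] - vals[n]) ** 2 / n.length
            return total

        res = minimize(objective, np.zeros(len(internal)), method="BFGS",
                       options={"gtol": 1e-12})
        for i, n in enumerate(internal):
            assert anc.values[n] == pytest.approx(res.x[i], abs=1e-8)

    def test_zero_gradient_at_every_internal_node(self):
        s = parse_newick("(((A:0.5,B:2):1.5,C:1):0.7,D:3);")
        anc = ancestral_counts_continuous(s, {"A": 1, "B": 6, "C": 0, "D": 4})
        for n in s.postorder():
            if n.is_leaf:
                continue
            grad = 0.0
            if n.parent is not None:
                grad += 2 * (anc.values[n] - anc.values[n.parent]) / n.length
            for c in n.children:
                grad += 2 * (anc.values[n] - anc.values[c]) / c.length
            assert abs(grad) < 1e-10

    def test_non_positive_branch_length_rejected(self):
        s = parse_newick("(A:0,B:1);")
        with pytest.raises(OpsinkitError):
            ancestral_counts_continuous(s, {"A": 1, "B": 2})


class TestRepertoireHistory:
    def test_two_subclades_spanning_all_species_give_ancestral_two(self, tmp_path):
        species = ["A", "B", "C", "D"]
        stree = parse_newick("(((A,B),C),D);")
        clade_a = "(((A__a1,B__a1),C__a1),D__a1)"
        clade_b = "(((A__b1,B__b1),C__b1),D__b1)"
        gtree = parse_newick(f"({clade_a},{clade_b});")
        path = tmp_path / "counts.tsv"
        path.write_text("species\tASO-I\n" + "".join(f"{sp}\t2\n" for sp in species))
        table = CountTable.from_tsv(path)
        hist = repertoire_history(table, stree, {"ASO-I": (gtree, None)})
        root_label = "+".join(sorted(species))
        assert hist.counts.loc[root_label, "ASO-I"] == 2
        assert hist.methods.loc[root_label, "ASO-I"] == "reconciliation"

    def test_missing_cells_excluded_zeros_included(self, tmp_path):
        stree = parse_newick("((A,B),C);")

        def history(c_cell):
            path = tmp_path / f"counts_{c_cell}.tsv"
            path.write_text(f"species\tclade\nA\t2\nB\t2\nC\t{c_cell}\n")
            return repertoire_history(CountTable.from_tsv(path), stree)

        # no transcriptomic evidence for C: C does not constrain the root
        missing = history("NA")
        assert missing.counts.loc["A+B+C", "clade"] == 2
        # genomic zero for C: a true absence, pulling the root into a
        # 0..2 tie reported as its minimum and flagged
        zero = history("0")
        assert zero.counts.loc["A+B+C", "clade"] == 0
        assert zero.methods.loc["A+B+C", "clade"] == "meristic (tie)"
        assert missing.methods.loc["A+B+C", "clade"] == "meristic"

    def test_species_mismatch_is_an_error(self, tmp_path):
        stree = parse_newick("(A,B);")
        path = tmp_path / "counts.tsv"
        path.write_text("species\tclade\nA\t1\nZ\t1\n")
        with pytest.raises(OpsinkitError, match="absent"):
            repertoire_history(CountTable.from_tsv(path), stree)
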