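"""Duplication-loss reconciliation and ancestral gene-count parsimony.

Two complementary routes to ancestral repertoires:

* **LCA reconciliation** embeds a rooted binary gene tree into a rooted
  species tree.  Each gene node maps to the most recent common ancestor
  of its leaves' species; a node mapping onto the same species node as
  one of its children is a duplication, and lineages that skip species
  nodes imply losses.  The LCA mapping minimizes duplications + losses.

* **Count parsimony** works from per-species gene counts alone:
  Sankoff dynamic programming with cost |i - j| for meristic (integer)
  counts, and squared-change parsimony (weighted by branch length) for
  a continuous reading of the same data.  Count-only methods can miss
  losses that gene-tree topology reveals, so reconciliation counts take
  precedence when a gene tree is available.

Branches whose support fails the joint SH-aLRT/UFboot gate can be
collapsed first; the resulting polytomies are resolved in favor of the
species tree so that weakly supported conflict does not inflate
duplication counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import OpsinkitError
from .io_core import (
    CountTable,
    PROV_MISSING,
    Tree,
    TreeNode,
)

SPECIATION = "speciation"
DUPLICATION = "duplication"


# ---------------------------------------------------------------------------
# Support gating
# ---------------------------------------------------------------------------

def collapse_by_support(tree: Tree, min_shalrt: float = 80.0,
                        min_ufboot: float = 95.0) -> Tree:
    """Contract internal branches failing the joint support gate.

    A clade counts as supported only when SH-aLRT > ``min_shalrt`` AND
    UFboot > ``min_ufboot``; a branch failing either is collapsed into a
    polytomy.  Branches without support values are kept, with a warning.
    Leaves are never touched.
    """
    out = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(out.root.postorder()):
            if node.is_leaf or node.parent is None:
                continue
            if node.support is None:
                warnings.warn("internal branch without support values kept as-is")
                continue
            sh, uf = node.support
            if sh > min_shalrt and uf > min_ufboot:
                continue
            parent = node.parent
            idx = parent.children.index(node)
            parent.children.pop(idx)
            for k, child in enumerate(node.children):
                child.parent = parent
                parent.children.insert(idx + k, child)
            changed = True
            break
    return out


# ---------------------------------------------------------------------------
# Leaf maps
# ---------------------------------------------------------------------------

def leaf_map_from_labels(gene_tree: Tree, sep: str = "__") -> dict[str, str]:
    """Infer gene-leaf -> species from ``species__gene`` leaf labels."""
    return {name: name.split(sep)[0] for name in gene_tree.leaf_names()}


def _check_leaf_map(gene_tree: Tree, species_tree: Tree,
                    leaf_map: Mapping[str, str]) -> None:
    gene_leaves = set(gene_tree.leaf_names())
    missing = gene_leaves - set(leaf_map)
    if missing:
        raise OpsinkitError(f"leaf map not total; missing {sorted(missing)[:5]}")
    species = set(species_tree.leaf_names())
    bad = {leaf_map[g] for g in gene_leaves} - species
    if bad:
        raise OpsinkitError(f"leaf map targets unknown species {sorted(bad)[:5]}")


# ---------------------------------------------------------------------------
# Species-tree indexing helpers
# ---------------------------------------------------------------------------

class _SpeciesIndex:
    """Parent/depth bookkeeping for LCA queries on the species tree."""

    def __init__(self, species_tree: Tree):
        self.tree = species_tree
        self.depth: dict[TreeNode, int] = {}
        self.by_leaf: dict[str, TreeNode] = {}
        for node in species_tree.preorder():
            self.depth[node] = 0 if node.parent is None else self.depth[node.parent] + 1
            if node.is_leaf:
                self.by_leaf[node.name] = node

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        while a is not b:
            if self.depth[a] < self.depth[b]:
                b = b.parent
            elif self.depth[a] > self.depth[b]:
                a = a.parent
            else:
                a, b = a.parent, b.parent
        return a

    def path_down(self, top: TreeNode, bottom: TreeNode) -> list[TreeNode]:
        """Nodes from ``top`` down to ``bottom``, inclusive."""
        path = [bottom]
        node = bottom
        while node is not top:
            node = node.parent
            if node is None:
                raise OpsinkitError("path_down: top is not an ancestor of bottom")
            path.append(node)
        return path[::-1]


def species_node_by_leaves(species_tree: Tree, leaf_names: Iterable[str]) -> TreeNode:
    """The MRCA of the named species leaves."""
    idx = _SpeciesIndex(species_tree)
    nodes = [idx.by_leaf[n] for n in leaf_names]
    node = nodes[0]
    for other in nodes[1:]:
        node = idx.lca(node, other)
    return node


# ---------------------------------------------------------------------------
# LCA reconciliation
# ---------------------------------------------------------------------------

@dataclass
class ReconciliationResult:
    gene_tree: Tree
    species_tree: Tree
    mapping: dict[TreeNode, TreeNode]           # gene node -> species node
    events: dict[TreeNode, str]                 # internal gene node -> event
    losses_per_branch: dict[TreeNode, int]      # species node -> losses on branch above it
    implied_counts: dict[TreeNode, int]         # species node -> gene lineages present

    @property
    def duplications_total(self) -> int:
        return sum(1 for e in self.events.values() if e == DUPLICATION)

    @property
    def losses_total(self) -> int:
        return sum(self.losses_per_branch.values())

    @property
    def cost(self) -> int:
        return self.duplications_total + self.losses_total

    def implied_count_at(self, leaf_names: Iterable[str]) -> int:
        """Implied gene count at the MRCA of the given species leaves."""
        node = species_node_by_leaves(self.species_tree, leaf_names)
        return self.implied_counts.get(node, 0)

    def annotated_gene_tree_newick(self) -> str:
        """Gene-tree Newick with D/S event labels on internal nodes."""
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name or ""
            inner = ",".join(fmt(c) for c in node.children)
            tag = "D" if self.events.get(node) == DUPLICATION else "S"
            return f"({inner}){tag}"
        return fmt(self.gene_tree.root) + ";"


def lca_reconcile(
    gene_tree: Tree,
    species_tree: Tree,
    leaf_map: Mapping[str, str] | None = None,
) -> ReconciliationResult:
    """Reconcile a rooted binary gene tree against a rooted species tree.

    Returns per-node events, per-branch loss counts, and the number of
    gene lineages implied at every species-tree node.  The event total
    (duplications + losses) is the duplication-loss parsimony minimum.
    """
    species_tree.require_rooted_binary("species tree")
    if not gene_tree.is_binary:
        # polytomies (e.g. from support collapsing) are resolved in
        # favor of the species tree before mapping
        gene_tree = resolve_polytomies(gene_tree, species_tree, leaf_map)
    if leaf_map is None:
        leaf_map = leaf_map_from_labels(gene_tree)
    _check_leaf_map(gene_tree, species_tree, leaf_map)
    sidx = _SpeciesIndex(species_tree)

    mapping: dict[TreeNode, TreeNode] = {}
    events: dict[TreeNode, str] = {}
    for g in gene_tree.postorder():
        if g.is_leaf:
            mapping[g] = sidx.by_leaf[leaf_map[g.name]]
        else:
            m = mapping[g.children[0]]
            for c in g.children[1:]:
                m = sidx.lca(m, mapping[c])
            mapping[g] = m
            events[g] = (
                DUPLICATION
                if any(mapping[c] is m for c in g.children)
                else SPECIATION
            )

    losses: dict[TreeNode, int] = {n: 0 for n in species_tree.postorder()}
    counts: dict[TreeNode, int] = {n: 0 for n in species_tree.postorder()}

    def edge_contribution(top_sp: TreeNode, bottom_sp: TreeNode,
                          parent_is_dup: bool, child_is_dup: bool) -> None:
        path = sidx.path_down(top_sp, bottom_sp)
        for t in path:
            if t is bottom_sp and child_is_dup:
                continue
            if t is top_sp and not parent_is_dup:
                continue
            counts[t] += 1
        # a lineage passing a speciation without an event loses the
        # sibling branch there
        for k, t in enumerate(path[:-1]):
            if t is top_sp and not parent_is_dup:
                continue
            toward = path[k + 1]
            for child in t.children:
                if child is not toward:
                    losses[child] += 1

    for g, m in mapping.items():
        if g.parent is None:
            # the family originates at M(root); no events are charged
            # above it, and species nodes above it carry count 0
            if events.get(g) != DUPLICATION:
                counts[m] += 1
        else:
            p = g.parent
            edge_contribution(
                mapping[p], m,
                parent_is_dup=events.get(p) == DUPLICATION,
                child_is_dup=events.get(g) == DUPLICATION,
            )

    return ReconciliationResult(
        gene_tree=gene_tree, species_tree=species_tree, mapping=mapping,
        events=events, losses_per_branch=losses, implied_counts=counts,
    )


# ---------------------------------------------------------------------------
# Polytomy resolution (species-tree-guided)
# ---------------------------------------------------------------------------

def resolve_polytomies(
    gene_tree: Tree,
    species_tree: Tree,
    leaf_map: Mapping[str, str] | None = None,
) -> Tree:
    """Resolve gene-tree polytomies in favor of the species tree.

    Children of a polytomy are grouped by which side of the relevant
    species split they map to and joined following the species topology,
    which minimizes the duplications the subsequent reconciliation must
    infer.  Children straddling the split are joined on top (each
    necessarily a duplication).
    """
    work = gene_tree.copy()
    if leaf_map is None:
        leaf_map = leaf_map_from_labels(work)
    _check_leaf_map(work, species_tree, leaf_map)
    sidx = _SpeciesIndex(species_tree)

    def node_species(n: TreeNode) -> TreeNode:
        leaves = n.leaf_names()
        m = sidx.by_leaf[leaf_map[leaves[0]]]
        for name in leaves[1:]:
            m = sidx.lca(m, sidx.by_leaf[leaf_map[name]])
        return m

    def join(children: list[TreeNode], sp: TreeNode) -> TreeNode:
        if len(children) == 1:
            return children[0]
        if sp.is_leaf:
            node = children[0]
            for c in children[1:]:
                node = TreeNode(children=[node, c])
            return node
        straddle: list[TreeNode] = []
        by_side: dict[int, list[TreeNode]] = {i: [] for i in range(len(sp.children))}
        for c in children:
            m = node_species(c)
            side = None
            for i, sp_child in enumerate(sp.children):
                t = m
                while t is not None:
                    if t is sp_child:
                        side = i
                        break
                    t = t.parent
                if side is not None:
                    break
            if side is None:
                straddle.append(c)
            else:
                by_side[side].append(c)
        parts = [
            join(group, sp.children[i])
            for i, group in by_side.items() if group
        ]
        if not parts:
            node = straddle[0]
            rest = straddle[1:]
        elif len(parts) == 1:
            node = parts[0]
            rest = straddle
        else:
            node = parts[0]
            for p in parts[1:]:
                node = TreeNode(children=[node, p])
            rest = straddle
        for c in rest:
            node = TreeNode(children=[node, c])
        return node

    def rebuild(n: TreeNode) -> TreeNode:
        if n.is_leaf:
            return n
        kids = [rebuild(c) for c in n.children]
        for k in kids:
            k.parent = None
        joined = join(kids, node_species(n))
        joined.name = n.name
        joined.length = n.length
        joined.support = n.support
        return joined

    return Tree(rebuild(work.root))


# ---------------------------------------------------------------------------
# Count parsimony
# ---------------------------------------------------------------------------

@dataclass
class AncestralCounts:
    """Per-node ancestral count estimates.

    ``optimal_sets`` (meristic) holds the full optimal state set per
    node; ``values`` holds the point estimate — the minimum of the
    optimal set in meristic mode (ties flagged), the unique solution in
    continuous mode.
    """

    species_tree: Tree
    values: dict[TreeNode, float]
    optimal_sets: dict[TreeNode, set[int]] | None = None
    ties: set[TreeNode] = field(default_factory=set)
    cost: float = 0.0

    def value_at(self, leaf_names: Iterable[str]) -> float:
        return self.values[species_node_by_leaves(self.species_tree, leaf_names)]


_INF = float("inf")


def ancestral_counts_meristic(
    species_tree: Tree,
    leaf_counts: Mapping[str, int],
    max_state: int | None = None,
    missing: Iterable[str] = (),
) -> AncestralCounts:
    """Sankoff parsimony on integer counts with linear cost |i - j|.

    Leaves in ``missing`` (no evidence either way) are left free: their
    cost vector is zero for every state, so they do not constrain the
    reconstruction.  State space is 0..max(observed)+2 unless capped.
    """
    counts = dict(leaf_counts)
    missing = set(missing)
    if any(v < 0 for v in counts.values()):
        raise OpsinkitError("counts must be non-negative")
    observed = [v for k, v in counts.items() if k not in missing]
    top = (max(observed) if observed else 0) + 2
    if max_state is not None:
        top = max_state
    states = list(range(top + 1))
    n_states = len(states)

    down: dict[TreeNode, np.ndarray] = {}
    for node in species_tree.postorder():
        if node.is_leaf:
            if node.name in missing or node.name not in counts:
                vec = np.zeros(n_states)
            else:
                vec = np.full(n_states, _INF)
                vec[counts[node.name]] = 0.0
            down[node] = vec
        else:
            vec = np.zeros(n_states)
            for child in node.children:
                cvec = down[child]
                trans = np.abs(np.subtract.outer(states, states)).astype(float)
                vec = vec + (trans + cvec[None, :]).min(axis=1)
            down[node] = vec

    root_vec = down[species_tree.root]
    best = root_vec.min()

    # up-pass: cost of the rest of the tree given each state at the node
    up: dict[TreeNode, np.ndarray] = {species_tree.root: np.zeros(n_states)}
    for node in species_tree.preorder():
        for child in node.children:
            sib_sum = np.zeros(n_states)
            for sib in node.children:
                if sib is not child:
                    cvec = down[sib]
                    trans = np.abs(np.subtract.outer(states, states)).astype(float)
                    sib_sum = sib_sum + (trans + cvec[None, :]).min(axis=1)
            base = up[node] + sib_sum
            trans = np.abs(np.subtract.outer(states, states)).astype(float)
            up[child] = (trans + base[:, None]).min(axis=0)

    values: dict[TreeNode, float] = {}
    optimal: dict[TreeNode, set[int]] = {}
    ties: set[TreeNode] = set()
    for node in species_tree.postorder():
        total = down[node] + up[node]
        opts = {s for s in states if total[s] == best}
        optimal[node] = opts
        values[node] = float(min(opts))
        if len(opts) > 1:
            ties.add(node)
    return AncestralCounts(
        species_tree=species_tree, values=values, optimal_sets=optimal,
        ties=ties, cost=float(best),
    )


def ancestral_counts_continuous(
    species_tree: Tree,
    leaf_counts: Mapping[str, float],
    missing: Iterable[str] = (),
) -> AncestralCounts:
    """Squared-change parsimony: minimize sum (parent-child)^2 / branch.

    Unit branch lengths are assumed where none are given; lengths must
    be positive.  The optimum is the unique solution of the linear
    system given by the zero-gradient condition at every free node.
    """
    missing = set(missing)
    free: list[TreeNode] = []
    fixed: dict[TreeNode, float] = {}
    for node in species_tree.postorder():
        if node.is_leaf and node.name in leaf_counts and node.name not in missing:
            fixed[node] = float(leaf_counts[node.name])
        else:
            free.append(node)
    index = {n: i for i, n in enumerate(free)}
    n = len(free)
    A = np.zeros((n, n))
    b = np.zeros(n)

    def weight(child: TreeNode) -> float:
        bl = child.length if child.length is not None else 1.0
        if bl <= 0:
            raise OpsinkitError("branch lengths must be positive")
        return 1.0 / bl

    for node in species_tree.postorder():
        if node.parent is None:
            continue
        w = weight(node)
        pair = [(node, node.parent), (node.parent, node)]
        for u, v in pair:
            if u in index:
                A[index[u], index[u]] += w
                if v in index:
                    A[index[u], index[v]] -= w
                else:
                    b[index[u]] += w * fixed[v]
    x = np.linalg.solve(A, b) if n else np.array([])
    values = dict(fixed)
    for node, i in index.items():
        values[node] = float(x[i])
    cost = 0.0
    for node in species_tree.postorder():
        if node.parent is not None:
            cost += weight(node) * (values[node.parent] - values[node]) ** 2
    return AncestralCounts(species_tree=species_tree, values=values, cost=cost)


# ---------------------------------------------------------------------------
# Repertoire history
# ---------------------------------------------------------------------------

@dataclass
class RepertoireHistory:
    species_tree: Tree
    counts: pd.DataFrame      # internal-node label x clade -> ancestral count
    methods: pd.DataFrame     # same shape; {"reconciliation", "meristic"}
    branch_events: pd.DataFrame  # per species branch: gains/losses per clade


def _node_label(node: TreeNode) -> str:
    return node.name or "+".join(sorted(node.leaf_names()))


def repertoire_history(
    count_table: CountTable,
    species_tree: Tree,
    gene_trees: Mapping[str, tuple[Tree, Mapping[str, str] | None]] | None = None,
) -> RepertoireHistory:
    """Ancestral repertoire per opsin subclade across the species tree.

    Subclades with a gene tree are reconciled (reconciliation counts
    take precedence — count-only parsimony misses losses the gene-tree
    topology reveals); the rest fall back to meristic Sankoff parsimony
    on the count column, with transcriptomic-missing cells excluded and
    genomic zeros included as true zeros.
    """
    gene_trees = gene_trees or {}
    species = set(species_tree.leaf_names())
    table_species = set(count_table.counts.index)
    if not table_species <= species:
        raise OpsinkitError(
            f"count table species absent from tree: {sorted(table_species - species)}"
        )
    internal = [n for n in species_tree.postorder() if not n.is_leaf]
    labels = [_node_label(n) for n in internal]
    counts = pd.DataFrame(index=labels, columns=list(count_table.counts.columns),
                          dtype=float)
    methods = pd.DataFrame("", index=labels, columns=list(count_table.counts.columns))
    branch_rows = []

    for clade in count_table.counts.columns:
        if clade in gene_trees:
            gtree, lmap = gene_trees[clade]
            rec = lca_reconcile(gtree, species_tree, lmap)
            for node, lab in zip(internal, labels):
                counts.loc[lab, clade] = rec.implied_counts.get(node, 0)
                methods.loc[lab, clade] = "reconciliation"
            for node in species_tree.postorder():
                if node.parent is None:
                    continue
                dups_here = sum(
                    1 for g, e in rec.events.items()
                    if e == DUPLICATION and rec.mapping[g] is node
                )
                branch_rows.append({
                    "clade": clade, "branch_to": _node_label(node),
                    "gains": dups_here, "losses": rec.losses_per_branch.get(node, 0),
                })
        else:
            col = count_table.counts[clade]
            prov = count_table.provenance[clade]
            missing = {sp for sp in col.index if prov[sp] == PROV_MISSING}
            missing |= species - table_species
            leaf_counts = {sp: int(col[sp]) for sp in col.index if sp not in missing}
            anc = ancestral_counts_meristic(species_tree, leaf_counts, missing=missing)
            for node, lab in zip(internal, labels):
                counts.loc[lab, clade] = anc.values[node]
                methods.loc[lab, clade] = (
                    "meristic (tie)" if node in anc.ties else "meristic"
                )
            for node in species_tree.postorder():
                if node.parent is None:
                    continue
                delta = anc.values.get(node, 0) - anc.values[node.parent]
                if node.is_leaf and node.name in missing:
                    continue
                branch_rows.append({
                    "clade": clade, "branch_to": _node_label(node),
                    "gains": max(0, int(delta)), "losses": max(0, int(-delta)),
                })
    return RepertoireHistory(
        species_tree=species_tree, counts=counts, methods=methods,
        branch_events=pd.DataFrame(branch_rows),
    )
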