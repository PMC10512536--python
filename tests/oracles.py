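"""Independent brute-force oracles for reconciliation and count parsimony.

These deliberately share no code with the package: trees are nested
tuples, costs come from exhaustive enumeration, and the loss count uses
the closed-form depth formula rather than path walking.
"""

from __future__ import annotations

import itertools

import numpy as np

from opsinkit.io_core import Tree, TreeNode

# ---------------------------------------------------------------------------
# Tree enumeration (nested-tuple representation; leaves are species strings)
# ---------------------------------------------------------------------------


def all_tree_shapes(leaf_multiset: tuple[str, ...]) -> set:
    """All distinct unordered rooted binary shapes over a leaf multiset."""
    if len(leaf_multiset) == 1:
        return {leaf_multiset[0]}
    out = set()
    n = len(leaf_multiset)
    seen_splits = set()
    for r in range(1, n):
        for combo in itertools.combinations(range(n), r):
            left = tuple(sorted(leaf_multiset[i] for i in combo))
            rest = tuple(sorted(leaf_multiset[i] for i in range(n)
                                if i not in combo))
            key = tuple(sorted((left, rest)))
            if key in seen_splits:
                continue
            seen_splits.add(key)
            for lt in all_tree_shapes(left):
                for rt in all_tree_shapes(rest):
                    out.add(tuple(sorted((lt, rt), key=repr)))
    return out


def all_gene_trees(species: list[str], max_leaves: int):
    """Every species-labeled rooted binary shape with <= max_leaves leaves."""
    shapes = set()
    for n in range(1, max_leaves + 1):
        for ms in itertools.combinations_with_replacement(sorted(species), n):
            shapes |= all_tree_shapes(ms)
    return shapes


def shape_to_tree(shape) -> tuple[Tree, dict[str, str]]:
    """Materialize a shape as an opsinkit Tree with unique leaf names."""
    counter = itertools.count(1)
    leaf_map = {}

    def build(node):
        if isinstance(node, str):
            name = f"{node}__x{next(counter)}"
            leaf_map[name] = node
            return TreeNode(name=name)
        left, right = node
        return TreeNode(children=[build(left), build(right)])

    return Tree(build(shape)), leaf_map


# ---------------------------------------------------------------------------
# Brute-force duplication-loss cost
# ---------------------------------------------------------------------------

def _species_info(species_tree: Tree):
    nodes = list(species_tree.postorder())
    depth = {}
    for node in species_tree.preorder():
        depth[node] = 0 if node.parent is None else depth[node.parent] + 1
    ancestors = {}
    for node in nodes:
        anc = []
        t = node
        while t is not None:
            anc.append(t)
            t = t.parent
        ancestors[node] = anc  # node itself first
    by_leaf = {n.name: n for n in nodes if n.is_leaf}
    return nodes, depth, ancestors, by_leaf


def brute_force_dl_cost(gene_tree: Tree, species_tree: Tree,
                        leaf_map: dict[str, str]) -> int:
    """Minimum duplications + losses over ALL valid gene->species maps.

    A map is valid when every internal node maps to an ancestor-or-self
    of both children's images.  A node is a speciation only if its
    children's images lie in distinct child subtrees of its own image;
    losses on the edge above a node mapped d levels below its parent's
    image are d - 1 (+1 if the parent is a duplication).
    """
    _nodes, depth, ancestors, by_leaf = _species_info(species_tree)
    gene_nodes = list(gene_tree.postorder())
    internal = [g for g in gene_nodes if not g.is_leaf]
    fixed = {g: by_leaf[leaf_map[g.name]] for g in gene_nodes if g.is_leaf}

    anc_sets = {n: set(a) for n, a in ancestors.items()}

    def subtree_of(node, child):
        """Is `node` inside the subtree rooted at `child`?"""
        return child in anc_sets[node]

    best = [np.inf]

    def cost_of(assign):
        dups = set()
        total = 0
        for g in internal:
            m = assign[g]
            c1, c2 = (assign[c] for c in g.children)
            distinct = any(
                subtree_of(c1, k1) and subtree_of(c2, k2)
                for k1 in m.children for k2 in m.children if k1 is not k2
            )
            if not distinct:
                dups.add(g)
                total += 1
        for g in gene_nodes:
            if g.parent is None:
                continue
            d = depth[assign[g]] - depth[assign[g.parent]]
            if d > 0:
                total += d - 1 + (1 if g.parent in dups else 0)
        return total

    def rec(i, assign):
        if i == len(internal):
            best[0] = min(best[0], cost_of(assign))
            return
        g = internal[i]
        images = [assign[c] for c in g.children]
        allowed = set.intersection(*(set(ancestors[m]) for m in images))
        for m in allowed:
            assign[g] = m
            rec(i + 1, assign)
        del assign[g]

    # postorder ensures children assigned before parents
    rec(0, dict(fixed))
    return int(best[0])


# ---------------------------------------------------------------------------
# Brute-force Sankoff (linear cost) — vectorized exhaustive enumeration
# ---------------------------------------------------------------------------

def brute_force_sankoff(species_tree: Tree, leaf_counts: dict[str, int],
                        n_states: int) -> tuple[float, set[int]]:
    """Exhaustive min cost and optimal root states over states 0..n_states-1."""
    nodes = list(species_tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    leaves = [n for n in nodes if n.is_leaf]
    k = len(internal)
    idx = {n: i for i, n in enumerate(internal)}
    grids = np.meshgrid(*[np.arange(n_states)] * k, indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1)  # (n_states^k, k)
    cost = np.zeros(len(combos))
    for n in nodes:
        if n.parent is None:
            continue
        pv = combos[:, idx[n.parent]]
        cv = (np.full(len(combos), leaf_counts[n.name]) if n.is_leaf
              else combos[:, idx[n]])
        cost += np.abs(pv - cv)
    best = cost.min()
    root_col = combos[:, idx[species_tree.root]]
    opt_roots = {int(s) for s in np.unique(root_col[cost == best])}
    return float(best), opt_roots
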