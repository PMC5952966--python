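"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: parsimony scores are
minimized by exhaustive enumeration of internal labelings, midpoint depth by
scanning subdivision points on every edge, Fisher p-values by enumerating
all tables with the observed margins.
"""

from __future__ import annotations

import itertools
import math

import dendropy
import numpy as np


# --- rooted binary tree enumeration ---------------------------------------

def all_rooted_topologies(leaves: list[str]):
    """Yield newick strings of every rooted binary topology on the leaves."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    # choose the subset joined with `first` under the root's left child
    for k in range(0, len(rest)):
        for combo in itertools.combinations(rest, k):
            left = [first, *combo]
            right = [x for x in rest if x not in combo]
            if not right:
                continue
            for lt in all_rooted_topologies(left):
                for rt in all_rooted_topologies(right):
                    yield f"({lt},{rt})"


def random_rooted_tree(rng: np.random.Generator, n_leaves: int,
                       labels=None) -> dendropy.Tree:
    labels = labels or [f"L{i}" for i in range(n_leaves)]
    nodes = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = dendropy.Taxon(label=lab)
        node.edge.length = float(rng.uniform(0.1, 2.0))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.uniform(0.1, 2.0))
        nodes.append(parent)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(seed_node=nodes[0], taxon_namespace=ns)
    for leaf in tree.leaf_node_iter():
        ns.add_taxon(leaf.taxon)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


# --- brute-force parsimony -------------------------------------------------

def brute_force_parsimony(tree: dendropy.Tree, leaf_states: dict[str, int],
                          n_states: int = 2) -> int:
    """Minimal change count over every assignment of internal node states."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = math.inf
    for labeling in itertools.product(range(n_states), repeat=len(internals)):
        assigned = dict(zip(map(id, internals), labeling))

        def state_of(node):
            if node.is_leaf():
                return leaf_states[node.taxon.label]
            return assigned[id(node)]

        changes = sum(
            1
            for node in tree.preorder_node_iter()
            if node.parent_node is not None
            and state_of(node) != state_of(node.parent_node)
        )
        best = min(best, changes)
    return int(best)


# --- midpoint oracle --------------------------------------------------------

def min_max_leaf_depth(tree: dendropy.Tree, step_fraction: float = 0.02) -> float:
    """Smallest achievable maximum root-to-leaf distance over all rootings
    obtained by subdividing edges (dense scan), computed from pairwise leaf
    distances: for a root point p, depth(p) = max_leaf d(p, leaf)."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = list(tree.leaf_node_iter())
    dist = {(a.taxon.label, b.taxon.label):
            pdm.patristic_distance(a.taxon, b.taxon)
            for a in leaves for b in leaves}

    def leaf_depths_from_point(edge, frac):
        # distance from a point at `frac` along edge (head side) to each leaf
        head, tail = edge.head_node, edge.tail_node
        head_leaves = set(l.taxon.label for l in head.leaf_iter())
        out = []
        length = edge.length or 0.0
        for leaf in leaves:
            lab = leaf.taxon.label
            d_head = _node_leaf_distance(head, leaf, dist)
            d_tail = _node_leaf_distance(tail, leaf, dist)
            if lab in head_leaves:
                out.append(d_head + frac * length)
            else:
                out.append(d_tail + (1 - frac) * length)
        return max(out)

    best = math.inf
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None or not edge.length:
            continue
        for frac in np.arange(0.0, 1.0 + 1e-9, step_fraction):
            best = min(best, leaf_depths_from_point(edge, float(frac)))
    return best


def _node_leaf_distance(node, leaf, dist):
    # distance from an internal node to a leaf via stored leaf-leaf distances
    # d(node, leaf) computed by walking up from the leaf is simpler:
    d = 0.0
    walker = leaf
    seen = {}
    while walker is not None:
        seen[id(walker)] = d
        d += walker.edge.length or 0.0
        walker = walker.parent_node
    if id(node) in seen:
        return seen[id(node)]
    # node not on leaf's root path: climb from node until hitting that path
    d2 = 0.0
    walker = node
    while id(walker) not in seen:
        d2 += walker.edge.length or 0.0
        walker = walker.parent_node
    return d2 + seen[id(walker)]


# --- exact Fisher enumeration ----------------------------------------------

def fisher_enumeration(a: int, b: int, c: int, d: int):
    """(one_sided_greater, two_tailed) by enumerating fixed-margin tables."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: table_prob(x) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    one_sided = sum(p for x, p in probs.items() if x >= a)
    two_tailed = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))
    return one_sided, two_tailed
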