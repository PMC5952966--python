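"""Alignment and tree utilities.

Pairwise identity follows the shorter-sequence normalization: identical
aligned residues divided by the length of the shorter ungapped sequence.
Trees are dendropy objects throughout.  A neighbor-joining builder on
1 - identity distances stands in for external maximum-likelihood inference
when no tree is supplied; midpoint rooting places the root halfway along
the longest leaf-to-leaf path.
"""

from __future__ import annotations

import io
import itertools
import logging
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np

log = logging.getLogger(__name__)

GAP = "-"


class Msa:
    """A multiple sequence alignment: ordered ids, equal-length gapped rows."""

    def __init__(self, ids: Sequence[str], rows: dict[str, str]):
        self.ids = list(ids)
        self.rows = dict(rows)
        lengths = {len(rows[i]) for i in self.ids}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.ncols = lengths.pop() if lengths else 0

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.rows

    def __len__(self) -> int:
        return len(self.ids)

    def row(self, seq_id: str) -> str:
        return self.rows[seq_id]

    def degapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")

    def drop(self, seq_ids: Iterable[str]) -> "Msa":
        gone = set(seq_ids)
        keep = [i for i in self.ids if i not in gone]
        return Msa(keep, {i: self.rows[i] for i in keep})

    def replace_row(self, seq_id: str, row: str) -> "Msa":
        if len(row) != self.ncols:
            raise ValueError("replacement row has wrong length")
        rows = dict(self.rows)
        rows[seq_id] = row
        return Msa(self.ids, rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i in self.ids:
                fh.write(f">{i}\n{self.rows[i]}\n")

    @classmethod
    def from_fasta(cls, path) -> "Msa":
        from Bio import SeqIO
        ids, rows = [], {}
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows[rec.id] = str(rec.seq)
        return cls(ids, rows)


def pairwise_identity(msa: Msa, id_a: str, id_b: str) -> float:
    """Fraction of identical aligned residues over the shorter ungapped length."""
    for sid in (id_a, id_b):
        if sid not in msa:
            raise KeyError(f"sequence {sid!r} not in alignment")
    a, b = msa.row(id_a), msa.row(id_b)
    ident = sum(1 for x, y in zip(a, b) if x == y and x != GAP)
    shorter = min(len(a) - a.count(GAP), len(b) - b.count(GAP))
    if shorter == 0:
        return 0.0
    return ident / shorter


def identity_distributions(
    mixed_clusters,
    max_identity: Optional[float] = None,
) -> dict[str, dict]:
    """Pairwise identity samples of mixed clusters, split by SP status of the pair.

    Every unordered within-cluster pair lands in exactly one of three samples:
    ``both`` (both members secreted), ``neither``, ``one``.  With
    ``max_identity`` set, pairs at or above the threshold are dropped first.
    """
    from .types import ConsensusState
    samples: dict[str, list[float]] = {"both": [], "neither": [], "one": []}
    for cluster in mixed_clusters:
        msa = cluster.msa
        for ma, mb in itertools.combinations(cluster.member_ids(), 2):
            ident = pairwise_identity(msa, ma, mb)
            if max_identity is not None and ident >= max_identity:
                continue
            sa = cluster.states[ma] is ConsensusState.POSITIVE
            sb = cluster.states[mb] is ConsensusState.POSITIVE
            key = "both" if sa and sb else "neither" if not (sa or sb) else "one"
            samples[key].append(ident)
    return {
        key: {"values": vals, "mean": float(np.mean(vals)) if vals else float("nan")}
        for key, vals in samples.items()
    }


def distance_matrix(msa: Msa) -> tuple[list[str], np.ndarray]:
    """1 - pairwise identity for every pair of rows."""
    ids = list(msa.ids)
    n = len(ids)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = 1.0 - pairwise_identity(msa, ids[i], ids[j])
        dm[i, j] = dm[j, i] = d
    return ids, dm


def build_nj_tree(msa: Msa) -> dendropy.Tree:
    """Neighbor-joining tree on 1 - identity distances (stand-in for external
    ML inference).  Negative branch lengths are clamped to zero."""
    if len(msa) < 3:
        raise ValueError("neighbor joining needs at least 3 sequences")
    ids, dm = distance_matrix(msa)
    buf = io.StringIO()
    buf.write("," + ",".join(ids) + "\n")
    for i, sid in enumerate(ids):
        buf.write(sid + "," + ",".join(f"{x:.10f}" for x in dm[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        buf, delimiter=",", taxon_namespace=dendropy.TaxonNamespace(ids))
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    tree.is_rooted = False
    return tree


def total_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter())


def _leaf_path(leaf_a, leaf_b):
    """Node path from leaf_a to leaf_b plus cumulative distances from leaf_a."""
    anc_a = []
    node = leaf_a
    while node is not None:
        anc_a.append(node)
        node = node.parent_node
    index_a = {id(n): k for k, n in enumerate(anc_a)}
    chain_b = []
    node = leaf_b
    while id(node) not in index_a:
        chain_b.append(node)
        node = node.parent_node
    join = node
    path = anc_a[:index_a[id(join)] + 1] + list(reversed(chain_b))
    dists = [0.0]
    for prev, cur in zip(path, path[1:]):
        if cur.parent_node is prev:
            step = cur.edge.length or 0.0
        else:
            step = prev.edge.length or 0.0
        dists.append(dists[-1] + step)
    return path, dists


def tree_diameter_pair(tree: dendropy.Tree):
    """Leaf pair with maximal patristic distance; ties broken by the
    lexicographically smallest (label, label) pair."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    best = None
    for la, lb in itertools.combinations(leaves, 2):
        d = pdm.patristic_distance(la.taxon, lb.taxon)
        if best is None or d > best[0] + 1e-15:
            best = (d, la, lb)
    return best


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The two diameter endpoints end up equidistant from the root (tolerance
    1e-9).  A zero-diameter tree is rooted at an arbitrary internal node with
    a warning.  The input is not modified.
    """
    work = tree.clone(depth=1)
    diameter, leaf_a, leaf_b = tree_diameter_pair(work)
    if diameter <= 0:
        log.warning("zero-diameter tree: rooting at an arbitrary internal node")
        internal = next(work.preorder_internal_node_iter())
        work.reroot_at_node(internal, update_bipartitions=False)
        work.is_rooted = True
        return work
    path, dists = _leaf_path(leaf_a, leaf_b)
    target = diameter / 2.0
    for k in range(1, len(path)):
        if dists[k] >= target - 1e-12:
            below, above = path[k - 1], path[k]
            offset = target - dists[k - 1]  # distance from `below` toward `above`
            if abs(dists[k] - target) <= 1e-12 and not path[k].is_leaf():
                work.reroot_at_node(path[k], update_bipartitions=False)
                work.is_rooted = True
                return work
            if abs(offset) <= 1e-12 and not below.is_leaf():
                work.reroot_at_node(below, update_bipartitions=False)
                work.is_rooted = True
                return work
            if above.parent_node is below:
                # descending: `below` is the tail (parent) of the edge
                edge = above.edge
                from_tail = offset
            else:
                # ascending: `below` is the head (child) of the edge
                edge = below.edge
                from_tail = (edge.length or 0.0) - offset
            edge_length = edge.length or 0.0
            from_tail = min(max(from_tail, 0.0), edge_length)
            work.reroot_at_edge(edge, length1=from_tail,
                                length2=edge_length - from_tail,
                                update_bipartitions=False)
            work.is_rooted = True
            return work
    raise AssertionError("midpoint not located on diameter path")


def tree_from_newick(text: str, rooted: bool = True) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text, schema="newick",
        rooting="force-rooted" if rooted else "force-unrooted")


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
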