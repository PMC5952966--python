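"""Pairwise identity, NJ stand-in, and midpoint rooting."""

import pytest

from oracles import min_max_leaf_depth, random_rooted_tree
from sigpevo.phylo import Msa, build_nj_tree, identity_distributions, \
    midpoint_root, pairwise_identity, total_length, tree_from_newick
from sigpevo.types import ConsensusState, OrthologCluster, ProteinRecord


class TestPairwiseIdentity:
    @pytest.mark.parametrize("row_a,row_b,expected", [
        ("ACDE", "ACDE", 1.0),
        ("ACDE", "ACDF", 0.75),       # 3 identical / min(4, 4)
        ("AC--", "ACDE", 1.0),        # 2 identical / min(2, 4)
        ("A--C", "AG-C", 1.0),        # gaps never count as identical
        ("----", "ACDE", 0.0),        # zero shared columns
    ])
    def test_examples(self, row_a, row_b, expected):
        msa = Msa(["x", "y"], {"x": row_a, "y": row_b})
        assert pairwise_identity(msa, "x", "y") == pytest.approx(expected)
        assert pairwise_identity(msa, "y", "x") == pytest.approx(expected)

    def test_unknown_id_raises(self):
        msa = Msa(["x"], {"x": "ACDE"})
        with pytest.raises(KeyError):
            pairwise_identity(msa, "x", "zz")

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError):
            Msa(["x", "y"], {"x": "ACDE", "y": "ACD"})

    def test_range_and_symmetry_on_random_rows(self, rng):
        alphabet = list("ACDEFG-")
        for _ in range(30):
            a = "".join(rng.choice(alphabet, size=12))
            b = "".join(rng.choice(alphabet, size=12))
            if a.count("-") == 12 or b.count("-") == 12:
                continue
            msa = Msa(["a", "b"], {"a": a, "b": b})
            ident = pairwise_identity(msa, "a", "b")
            assert 0.0 <= ident <= 1.0
            assert ident == pairwise_identity(msa, "b", "a")


def _mixed_cluster(states, rows):
    ids = list(rows)
    members = [ProteinRecord(i, i, rows[i].replace("-", "")) for i in ids]
    cluster = OrthologCluster("g", members, {
        i: ConsensusState.POSITIVE if states[i] else ConsensusState.NEGATIVE
        for i in ids}, Msa(ids, rows))
    return cluster


class TestIdentityDistributions:
    def test_pair_partition_for_ppn_cluster(self):
        cluster = _mixed_cluster({"a": 1, "b": 1, "c": 0},
                                 {"a": "ACDE", "b": "ACDE", "c": "ACDE"})
        dists = identity_distributions([cluster])
        assert len(dists["both"]["values"]) == 1
        assert len(dists["one"]["values"]) == 2
        assert len(dists["neither"]["values"]) == 0
        assert dists["both"]["mean"] == 1.0

    def test_identity_filter_removes_pairs_at_threshold(self):
        cluster = _mixed_cluster(
            {"a": 1, "b": 0, "c": 0},
            {"a": "ACDEFGHI", "b": "ACDEFGHI", "c": "ACDEWWWW"})
        unfiltered = identity_distributions([cluster])
        filtered = identity_distributions([cluster], max_identity=0.95)
        assert len(unfiltered["one"]["values"]) == 2
        # the identical a/b pair (identity 1.0 >= 0.95) is dropped
        assert filtered["one"]["values"] == [0.5]
        assert len(filtered["neither"]["values"]) == 1


class TestNeighborJoining:
    def test_three_taxon_tree_satisfies_three_point_formulas(self):
        msa = Msa(["A", "B", "C"],
                  {"A": "AAAAAAAA", "B": "AAAAAACC", "C": "AACCCCCC"})
        d = {("A", "B"): 0.25, ("A", "C"): 0.75, ("B", "C"): 0.5}
        # leaf-to-junction lengths from the closed-form three-point formulas
        v = {
            "A": (d["A", "B"] + d["A", "C"] - d["B", "C"]) / 2,
            "B": (d["A", "B"] + d["B", "C"] - d["A", "C"]) / 2,
            "C": (d["A", "C"] + d["B", "C"] - d["A", "B"]) / 2,
        }
        tree = build_nj_tree(msa)
        # the (unique) unrooted 3-taxon tree reproduces the inputs exactly
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for (a, b), dist in d.items():
            assert pdm.patristic_distance(taxa[a], taxa[b]) == \
                pytest.approx(dist, abs=1e-9)
        assert total_length(tree) == pytest.approx(sum(v.values()), abs=1e-9)

    def test_additive_distances_recover_generating_topology(self):
        # mutations on disjoint position sets make Hamming distances additive
        # for the tree ((A,B),(C,D)): edge sizes A:2 B:3 C:2 D:4 inner:6
        base = list("A" * 40)
        def mutate(positions, char):
            s = list(base)
            for p in positions:
                s[p] = char
            return "".join(s)
        seq_a = mutate(range(0, 2), "C")
        seq_b = mutate(range(2, 5), "D")
        inner = set(range(30, 36))
        seq_c = mutate(sorted(inner | set(range(5, 7))), "E")
        seq_d = mutate(sorted(inner | set(range(7, 11))), "F")
        # C and D share the inner-edge mutations but to different residues:
        seq_c = list(seq_c)
        seq_d = list(seq_d)
        for p in inner:
            seq_c[p] = "G"
            seq_d[p] = "G"
        msa = Msa(["A", "B", "C", "D"],
                  {"A": "".join(seq_a), "B": "".join(seq_b),
                   "C": "".join(seq_c), "D": "".join(seq_d)})
        tree = build_nj_tree(msa)
        tree.encode_bipartitions()
        splits = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                  for e in tree.preorder_edge_iter() if e.tail_node}
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_identical_sequences_give_zero_lengths(self):
        msa = Msa(list("ABC"), {i: "AAAA" for i in "ABC"})
        tree = build_nj_tree(msa)
        assert total_length(tree) == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_sequences_rejected(self):
        with pytest.raises(ValueError):
            build_nj_tree(Msa(["A", "B"], {"A": "AA", "B": "AA"}))


class TestMidpointRoot:
    def test_two_leaf_symmetric_split(self):
        rooted = midpoint_root(tree_from_newick("(A:1,B:3);", rooted=False))
        depths = {l.taxon.label: l.distance_from_root()
                  for l in rooted.leaf_node_iter()}
        assert depths["A"] == pytest.approx(2.0)
        assert depths["B"] == pytest.approx(2.0)

    def test_caterpillar_diameter_endpoints_equidistant(self):
        tree = tree_from_newick("((A:1,B:2):3,(C:4,D:1):2);", rooted=False)
        rooted = midpoint_root(tree)
        depths = {l.taxon.label: l.distance_from_root()
                  for l in rooted.leaf_node_iter()}
        # diameter pair is B..C at distance 11
        assert depths["B"] == pytest.approx(5.5, abs=1e-9)
        assert depths["C"] == pytest.approx(5.5, abs=1e-9)

    def test_ultrametric_tree_keeps_all_leaves_equidistant(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=False)
        rooted = midpoint_root(tree)
        depths = [l.distance_from_root() for l in rooted.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_random_trees_properties(self, rng):
        """Equidistant diameter endpoints, conserved total length, and
        brute-force-minimal maximum leaf depth."""
        for i in range(12):
            n = int(rng.integers(4, 9))
            tree = random_rooted_tree(rng, n)
            tree_copy = tree.clone(depth=1)
            before = total_length(tree)
            rooted = midpoint_root(tree)
            depths = {l.taxon.label: l.distance_from_root()
                      for l in rooted.leaf_node_iter()}
            pdm = tree_copy.phylogenetic_distance_matrix()
            leaves = list(tree_copy.leaf_node_iter())
            diameter = max(pdm.patristic_distance(a.taxon, b.taxon)
                           for a in leaves for b in leaves)
            assert max(depths.values()) == pytest.approx(diameter / 2, abs=1e-9)
            assert total_length(rooted) == pytest.approx(before, abs=1e-9)
            oracle = min_max_leaf_depth(tree_copy)
            assert max(depths.values()) <= oracle + 1e-6
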