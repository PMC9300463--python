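"""Neighbor joining, identity distances and monophyly tests."""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

import strychmine as sm
from strychmine import phylo
from strychmine.align import OrthologPair


def pair(a, b, identity):
    return OrthologPair(id_a=a, id_b=b, aligned_a="", aligned_b="",
                        score=0.0, percent_identity=identity)


class TestDistanceFromIdentity:
    def test_identity_to_distance_arithmetic(self):
        dm = sm.distance_from_identity(
            [pair("x", "y", 74.0), pair("x", "z", 100.0), pair("y", "z", 50.0)]
        )
        assert dm["x", "y"] == pytest.approx(0.26)
        assert dm["x", "z"] == pytest.approx(0.0)
        assert dm["y", "z"] == pytest.approx(0.5)

    def test_symmetric_zero_diagonal(self):
        seqs = {f"s{i}": sm.simulate.random_protein(60, i) for i in range(4)}
        ids = list(seqs)
        pairs = [
            sm.global_align(seqs[a], seqs[b], id_a=a, id_b=b)
            for i, a in enumerate(ids) for b in ids[i + 1:]
        ]
        dm = sm.distance_from_identity(pairs)
        d = dm.data
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d >= 0).all()

    def test_missing_pair_raises(self):
        with pytest.raises(ValueError, match="missing"):
            sm.distance_from_identity([pair("x", "y", 80.0), pair("x", "z", 70.0)])


class TestNeighborJoining:
    def test_additive_four_taxon_round_trip(self):
        # distances generated from ((a,b),(c,d)) with known branch lengths
        dm = DistanceMatrix(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 5], [9, 10, 5, 0]],
            ["a", "b", "c", "d"],
        )
        tree = sm.neighbor_joining(dm)
        assert phylo.topology_splits(tree) == {frozenset({"a", "b"})} or \
            phylo.topology_splits(tree) == {frozenset({"c", "d"})}

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 5, 7], [5, 0, 8], [7, 8, 0]], ["a", "b", "c"])
        tree = sm.neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        # three-point formulas: la = (dab + dac - dbc)/2, etc.
        assert lengths["a"] == pytest.approx((5 + 7 - 8) / 2)
        assert lengths["b"] == pytest.approx((5 + 8 - 7) / 2)
        assert lengths["c"] == pytest.approx((7 + 8 - 5) / 2)

    def test_tight_pairs_become_cherries(self):
        dm = DistanceMatrix(
            [
                [0.0, 0.1, 1.0, 1.0, 1.0],
                [0.1, 0.0, 1.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.1, 1.0],
                [1.0, 1.0, 0.1, 0.0, 1.0],
                [1.0, 1.0, 1.0, 1.0, 0.0],
            ],
            ["p1", "p2", "q1", "q2", "out"],
        )
        tree = sm.neighbor_joining(dm)
        splits = phylo.topology_splits(tree)
        assert frozenset({"p1", "p2"}) in splits
        assert frozenset({"q1", "q2"}) in splits

    def test_recovers_random_additive_topologies(self):
        for seed in range(10):
            n = 5 + seed % 4
            true = phylo.random_tree(n, seed=seed)
            recovered = sm.neighbor_joining(phylo.path_distance_matrix(true))
            assert phylo.topology_splits(recovered) == phylo.topology_splits(true)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            sm.neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    def test_negative_branch_lengths_clamped(self):
        # non-additive matrix known to produce a negative NJ branch
        dm = DistanceMatrix(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0.0]],
            ["a", "b", "c", "d"],
        )
        tree = sm.neighbor_joining(dm)
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0


class TestNewickRoundTrip:
    def test_topology_preserved(self, tmp_path):
        tree = phylo.random_tree(7, seed=2)
        path = tmp_path / "tree.nwk"
        phylo.write_newick(tree, path)
        back = phylo.read_newick(path)
        assert phylo.topology_splits(back) == phylo.topology_splits(tree)


class TestIsMonophyletic:
    @pytest.fixture()
    def tree(self):
        return TreeNode.read(["((a:1,b:1):1,(c:1,(d:1,e:1):1):1,out:1);"])

    def test_whole_ingroup_is_a_clade(self, tree):
        assert sm.is_monophyletic(tree, {"a", "b", "c", "d", "e"}, "out")

    def test_singleton_is_a_clade(self, tree):
        assert sm.is_monophyletic(tree, {"c"}, "out")

    def test_true_and_false_clades(self, tree):
        assert sm.is_monophyletic(tree, {"a", "b"}, "out")
        assert sm.is_monophyletic(tree, {"d", "e"}, "out")
        assert sm.is_monophyletic(tree, {"c", "d", "e"}, "out")
        assert not sm.is_monophyletic(tree, {"a", "c"}, "out")
        assert not sm.is_monophyletic(tree, {"b", "d", "e"}, "out")

    def test_subset_split_across_root_is_not_a_clade(self, tree):
        assert not sm.is_monophyletic(tree, {"a", "b", "c"}, "out")

    def test_unknown_taxon_raises(self, tree):
        with pytest.raises(KeyError):
            sm.is_monophyletic(tree, {"a", "zz"}, "out")

    def test_outgroup_in_subset_rejected(self, tree):
        with pytest.raises(ValueError):
            sm.is_monophyletic(tree, {"a", "out"}, "out")

    def test_orthologue_pair_clusters_against_divergent_family(self):
        """Two cross-species orthologues at high identity form a clade apart
        from more divergent family members -- the acetyl/malonyl-transferase
        clade scenario at desk scale."""
        base = sm.simulate.random_protein(150, seed=50)
        seqs = {
            "producer_AT": base,
            "nonproducer_AT": sm.mutate_orthologue(base, 0.85, seed=51),
            "family1": sm.mutate_orthologue(base, 0.45, seed=52),
            "family2": sm.mutate_orthologue(base, 0.45, seed=53),
            "outgrp": sm.simulate.random_protein(150, seed=54),
        }
        ids = list(seqs)
        pairs = [
            sm.global_align(seqs[a], seqs[b], id_a=a, id_b=b)
            for i, a in enumerate(ids) for b in ids[i + 1:]
        ]
        tree = sm.neighbor_joining(sm.distance_from_identity(pairs))
        assert sm.is_monophyletic(tree, {"producer_AT", "nonproducer_AT"}, "outgrp")
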