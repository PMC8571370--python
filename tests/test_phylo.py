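import math
import random

import numpy as np
import pytest

from _oracles import random_additive_tree
from conftest import random_dna
from numtriage.evodist import DistanceMatrix, distance_matrix
from numtriage.msa import Alignment
from numtriage.phylo import (bootstrap_support, from_newick, midpoint_root,
                             neighbor_joining, root_at_outgroup,
                             smallest_containing_clade, to_newick)
from numtriage.seqio import SequenceRecord


def _dm(labels, dist):
    n = len(labels)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = dist[frozenset((labels[i], labels[j]))]
    return DistanceMatrix(labels, M)


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # distances generated from ((A:1,B:2):1,(C:3,D:1))
        labels = ["A", "B", "C", "D"]
        dist = {
            frozenset("AB"): 3.0, frozenset("AC"): 5.0, frozenset("AD"): 3.0,
            frozenset("BC"): 6.0, frozenset("BD"): 4.0, frozenset("CD"): 4.0,
        }
        tree = neighbor_joining(_dm(labels, dist))
        # canonical side is the one without the smallest label
        assert set(tree.bipartitions().keys()) == {frozenset("CD")}
        for pair, d in dist.items():
            a, b = sorted(pair)
            assert tree.leaf_distance(a, b) == pytest.approx(d, abs=1e-9)

    def test_three_taxon_closed_form(self):
        labels = ["A", "B", "C"]
        dist = {frozenset("AB"): 3.0, frozenset("AC"): 4.0, frozenset("BC"): 5.0}
        tree = neighbor_joining(_dm(labels, dist))
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_recovers_random_additive_trees(self):
        # exact topology and path lengths on additive matrices, up to 12 taxa
        r = random.Random(42)
        for trial in range(20):
            n = r.randint(4, 12)
            labels, dist, splits = random_additive_tree(n, r)
            tree = neighbor_joining(_dm(labels, dist))
            assert set(tree.bipartitions().keys()) == splits
            for pair, d in dist.items():
                a, b = sorted(pair)
                assert tree.leaf_distance(a, b) == pytest.approx(d, rel=1e-9)

    def test_agrees_with_dendropy_on_additive_matrix(self):
        import dendropy

        r = random.Random(7)
        labels, dist, splits = random_additive_tree(8, r)
        csv = "," + ",".join(labels) + "\n"
        for a in labels:
            row = [a] + [
                "0" if a == b else str(dist[frozenset((a, b))]) for b in labels
            ]
            csv += ",".join(row) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        ref = min(labels)
        oracle_splits = set()
        for edge in dtree.preorder_edge_iter():
            side = frozenset(
                t.label for t in edge.bipartition.leafset_taxa(dtree.taxon_namespace)
            )
            if 2 <= len(side) <= len(labels) - 2:
                canon = side if ref not in side else frozenset(labels) - side
                oracle_splits.add(canon)
        tree = neighbor_joining(_dm(labels, dist))
        assert set(tree.bipartitions().keys()) == oracle_splits

    def test_deterministic_on_ultrametric_ties(self):
        labels = list("ABCD")
        M = np.ones((4, 4)) - np.eye(4)
        t1 = to_newick(neighbor_joining(DistanceMatrix(labels, M)))
        t2 = to_newick(neighbor_joining(DistanceMatrix(labels, M)))
        assert t1 == t2

    def test_undefined_distances_rejected_with_pairs(self):
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = math.nan
        with pytest.raises(ValueError, match="a~b"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], M))


def _two_cluster_alignment(rng, n_per=4, length=200, divergence=40):
    base = random_dna(rng, length)
    other = list(base)
    for pos in rng.sample(range(length), divergence):
        other[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[pos]]
    other = "".join(other)
    recs = [SequenceRecord(f"a{i}", base) for i in range(n_per)]
    recs += [SequenceRecord(f"b{i}", other) for i in range(n_per)]
    return Alignment(recs)


class TestBootstrap:
    def test_forced_bipartition_gets_full_support(self, rng):
        aln = _two_cluster_alignment(rng)
        tree = bootstrap_support(aln, B=100, seed=3)
        split_support = {
            frozenset(s): n.support for s, n in tree.bipartitions().items()
        }
        # canonicalized on the side without the smallest leaf name
        cluster = frozenset({"b0", "b1", "b2", "b3"})
        assert split_support[cluster] == 100.0

    def test_supports_within_range(self, rng):
        base = random_dna(rng, 100)
        recs = []
        for i in range(6):
            m = list(base)
            for pos in rng.sample(range(100), 3 * i):
                m[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[m[pos]]
            recs.append(SequenceRecord(f"s{i}", "".join(m)))
        tree = bootstrap_support(Alignment(recs), B=100, seed=1)
        sups = [n.support for n in tree.root.walk() if n.support is not None]
        assert sups and all(0.0 <= s <= 100.0 for s in sups)

    def test_invariant_to_leaf_order(self, rng):
        aln = _two_cluster_alignment(rng)
        shuffled = list(aln.records)
        random.Random(5).shuffle(shuffled)
        t1 = bootstrap_support(aln, B=100, seed=9)
        t2 = bootstrap_support(Alignment(shuffled), B=100, seed=9)
        s1 = {s: n.support for s, n in t1.bipartitions().items()}
        s2 = {s: n.support for s, n in t2.bipartitions().items()}
        cluster = frozenset({"b0", "b1", "b2", "b3"})
        assert s1[cluster] == s2[cluster] == 100.0


class TestCladeQueries:
    def _tree(self):
        labels = ["A", "B", "C", "D"]
        dist = {
            frozenset("AB"): 3.0, frozenset("AC"): 5.0, frozenset("AD"): 3.0,
            frozenset("BC"): 6.0, frozenset("BD"): 4.0, frozenset("CD"): 4.0,
        }
        return neighbor_joining(_dm(labels, dist))

    def test_all_ids_returns_all_leaves(self):
        t = self._tree()
        assert smallest_containing_clade(t, ["A", "B", "C", "D"]) == \
            frozenset("ABCD")

    def test_single_id(self):
        assert smallest_containing_clade(self._tree(), ["A"]) == frozenset("A")

    def test_cherry_clade_with_outgroup_rooting(self):
        assert smallest_containing_clade(self._tree(), ["A", "B"],
                                         outgroup="C") == frozenset("AB")

    def test_unknown_id_rejected(self):
        with pytest.raises(KeyError):
            smallest_containing_clade(self._tree(), ["Z"])


class TestNewick:
    def test_cherry_serialization(self):
        labels = ["A", "B"]
        M = np.array([[0.0, 2.0], [2.0, 0.0]])
        text = to_newick(neighbor_joining(DistanceMatrix(labels, M)))
        assert text == "(A:1,B:1);"

    def test_round_trip_topology_and_lengths(self):
        r = random.Random(11)
        labels, dist, splits = random_additive_tree(9, r)
        tree = neighbor_joining(_dm(labels, dist))
        back = from_newick(to_newick(tree))
        assert set(back.bipartitions().keys()) == splits
        for pair in dist:
            a, b = sorted(pair)
            assert back.leaf_distance(a, b) == \
                pytest.approx(tree.leaf_distance(a, b), abs=1e-9)

    def test_support_threshold_hides_low_values(self, rng):
        aln = _two_cluster_alignment(rng)
        tree = bootstrap_support(aln, B=100, seed=3)
        for split, node in tree.bipartitions().items():
            node.support = 59.0
        text = to_newick(tree, support_threshold=60.0)
        assert "59" not in text
        for split, node in tree.bipartitions().items():
            node.support = 61.0
        assert "61" in to_newick(tree, support_threshold=60.0)

    def test_rooting_preserves_leaf_distances(self):
        r = random.Random(3)
        labels, dist, _ = random_additive_tree(7, r)
        tree = neighbor_joining(_dm(labels, dist))
        for rooted in (midpoint_root(tree), root_at_outgroup(tree, labels[0])):
            for pair, d in dist.items():
                a, b = sorted(pair)
                assert rooted.leaf_distance(a, b) == pytest.approx(d, rel=1e-9)
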