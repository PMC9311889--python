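import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from helpers import make_alignment
from mitopop.distances import DistanceMatrix
from mitopop.errors import MitopopError
from mitopop.trees import (
    bipartitions,
    bootstrap_support,
    is_ultrametric,
    neighbor_joining,
    read_newick,
    root_with_outgroup,
    upgma,
    write_newick,
)


def _dm(labels, values):
    return DistanceMatrix(labels=labels, values=np.asarray(values, float))


def _random_additive(rng, n_leaves=8):
    """Random caterpillar-ish additive matrix built from a random tree."""
    import networkx as nx

    g = nx.Graph()
    leaves = [f"L{i}" for i in range(n_leaves)]
    internal = [f"I{i}" for i in range(n_leaves - 2)]
    # unrooted binary caterpillar with random edge lengths
    for a, b in zip(internal, internal[1:]):
        g.add_edge(a, b, weight=float(rng.uniform(0.5, 2)))
    hosts = [internal[0]] + internal + [internal[-1]]
    for leaf, host in zip(leaves, hosts):
        g.add_edge(leaf, host, weight=float(rng.uniform(0.5, 3)))
    d = np.zeros((n_leaves, n_leaves))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            d[i, j] = lengths[a][b]
    d = (d + d.T) / 2.0  # exact symmetry despite float path sums
    np.fill_diagonal(d, 0.0)
    return _dm(leaves, d)


class TestUpgma:
    def test_forced_three_leaf_example(self):
        t = upgma(_dm(["A", "B", "C"], [[0, 2, 6], [2, 0, 6], [6, 6, 0]]))
        assert write_newick(t) == "((A:1.0,B:1.0):2.0,C:3.0);"

    def test_two_leaf_cherry(self):
        t = upgma(_dm(["A", "B"], [[0, 3], [3, 0]]))
        assert write_newick(t) == "(A:1.5,B:1.5);"

    def test_output_ultrametric(self, rng):
        n = 7
        x = rng.uniform(0, 5, size=(n, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        t = upgma(_dm([f"L{i}" for i in range(n)], d))
        assert is_ultrametric(t)

    def test_ultrametric_input_recovered(self, rng):
        # cophenetic distances of an average-linkage dendrogram are
        # ultrametric; UPGMA must reproduce them exactly
        n = 9
        x = rng.uniform(0, 5, size=(n, 4))
        raw = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        coph = squareform(cophenet(average(squareform(raw, checks=False))))
        labels = [f"L{i}" for i in range(n)]
        t = upgma(_dm(labels, coph))
        for i, a in enumerate(labels):
            for j in range(i + 1, n):
                got = t.find(a).distance(t.find(labels[j]))
                assert got == pytest.approx(coph[i, j], abs=1e-9)

    def test_label_order_invariance(self, rng):
        labels = ["A", "B", "C", "D", "E"]
        x = rng.uniform(0, 4, size=(5, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        t1 = upgma(_dm(labels, d))
        perm = [3, 0, 4, 1, 2]
        t2 = upgma(_dm([labels[i] for i in perm], d[np.ix_(perm, perm)]))
        assert t1.compare_rfd(t2) == 0


class TestNeighborJoining:
    def test_additive_four_leaf_exact(self):
        # true tree ((A:1,B:2):1,(C:3,D:4))
        labs = ["A", "B", "C", "D"]
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        t = neighbor_joining(_dm(labs, d))
        for i, a in enumerate(labs):
            for j in range(i + 1, 4):
                assert t.find(a).distance(t.find(labs[j])) == pytest.approx(
                    d[i][j], abs=1e-9)

    def test_additivity_preserved_on_random_trees(self, rng):
        dm = _random_additive(rng)
        t = neighbor_joining(dm)
        for i, a in enumerate(dm.labels):
            for j in range(i + 1, len(dm.labels)):
                b = dm.labels[j]
                assert t.find(a).distance(t.find(b)) == pytest.approx(
                    dm.values[i, j], abs=1e-9)

    def test_star_distances_give_zero_internal_edges(self):
        labs = ["A", "B", "C", "D"]
        d = np.ones((4, 4)) - np.eye(4)
        t = neighbor_joining(_dm(labs, d))
        for node in t.non_tips():
            assert node.length == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_labels_rejected(self):
        with pytest.raises(MitopopError):
            neighbor_joining(_dm(["A", "B"], [[0, 1], [1, 0]]))

    def test_agrees_with_reference_nj_topology(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        dm = _random_additive(rng)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(SkbioDM(dm.values, ids=dm.labels))
        assert ours.compare_rfd(theirs) == 0


class TestBootstrap:
    @staticmethod
    def _structured_alignment():
        # two clades, 20 diagnostic sites apart; small within-clade noise
        L = 120
        base = "A" * L
        clade2 = "G" * 20 + "A" * (L - 20)
        seqs, pops = [], []
        variants = {"p1": base, "p2": "A" * (L - 1) + "T",
                    "p3": clade2, "p4": clade2[:-1] + "C"}
        for pop, seq in variants.items():
            seqs += [seq] * 5
            pops += [pop] * 5
        return make_alignment(seqs, pops=pops)

    def test_strong_split_high_support(self):
        aln = self._structured_alignment()
        t = bootstrap_support(aln, tree_method="nj", B=100, seed=1)
        supports = [float(n.name) for n in t.non_tips(include_self=False)
                    if n.name is not None]
        assert supports and min(supports) >= 95.0

    def test_single_replicate_supports_binary(self):
        aln = self._structured_alignment()
        t = bootstrap_support(aln, tree_method="nj", B=1, seed=2)
        supports = {float(n.name) for n in t.non_tips(include_self=False)
                    if n.name is not None}
        assert supports <= {0.0, 100.0}

    def test_identical_sequences_no_supported_bipartitions(self):
        seqs = ["ACGT" * 10] * 12
        pops = ["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4
        t = bootstrap_support(make_alignment(seqs, pops=pops), B=10, seed=3)
        assert bipartitions(t) == set()

    def test_invalid_b(self):
        with pytest.raises(MitopopError):
            bootstrap_support(self._structured_alignment(), B=0)


class TestNewick:
    def test_round_trip(self, rng):
        dm = _random_additive(rng)
        t = neighbor_joining(dm)
        back = read_newick(write_newick(t))
        assert back.compare_rfd(t) == 0
        for a in dm.labels:
            for b in dm.labels:
                if a < b:
                    assert back.find(a).distance(back.find(b)) == \
                        pytest.approx(t.find(a).distance(t.find(b)), abs=1e-9)

    def test_outgroup_rooting(self):
        labs = ["A", "B", "C", "D"]
        d = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
        t = root_with_outgroup(neighbor_joining(_dm(labs, d)), "D")
        assert {x.name for x in t.tips()} == set(labs)
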