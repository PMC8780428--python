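import numpy as np
import pytest

from smirnet.graphlets import (
    InteractionCounter,
    SimilarityNetwork,
    binarize_similarity,
    count_interactions,
    count_interactions_bruteforce,
    enumerate_isomers,
)
from smirnet.similarity import SimilarityMatrix

from conftest import network_from_edges, random_network


class TestIsomerCatalogue:
    @pytest.mark.parametrize("max_nodes,expected", [(2, 1), (3, 5), (4, 28)])
    def test_class_counts(self, max_nodes, expected):
        assert len(enumerate_isomers(max_nodes)) == expected

    def test_deterministic_ordering(self):
        assert enumerate_isomers().classes == enumerate_isomers().classes

    def test_involution_structure(self, catalogue):
        """Source<->target swap is an involution with 12 fixed classes.

        12 symmetric classes plus 8 swapped pairs account for all 28.
        """
        inv = catalogue.involution()
        assert np.array_equal(inv[inv], np.arange(28))
        assert int((inv == np.arange(28)).sum()) == 12

    def test_unordered_collapse_yields_20_classes(self, catalogue):
        inv = catalogue.involution()
        orbits = {frozenset({i, int(inv[i])}) for i in range(28)}
        assert len(orbits) == 20

    def test_every_labelled_graphlet_maps_to_one_class(self, catalogue):
        # regenerating from scratch finds no class outside the catalogue
        from itertools import combinations, product

        from smirnet.graphlets import _connected, canonical_key

        idx = catalogue.index
        for k in (2, 3, 4):
            for bits in product((0, 1), repeat=k * (k - 1) // 2):
                edges = [
                    p for p, b in zip(combinations(range(k), 2), bits) if b
                ]
                if _connected(k, edges):
                    assert canonical_key(k, edges) in idx


class TestBinarize:
    def test_full_retention_gives_complete_graph(self):
        m = SimilarityMatrix(("a", "b", "c"), np.array(
            [[1.0, 0.2, 0.8], [0.2, 1.0, 0.5], [0.8, 0.5, 1.0]]))
        net = binarize_similarity(m, 1.0)
        assert net.adjacency.sum() == 6  # all three undirected edges

    def test_quantile_rule_keeps_top_pair(self):
        m = SimilarityMatrix(("1", "2", "3"), np.array(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.5], [0.1, 0.5, 1.0]]))
        net = binarize_similarity(m, 1 / 3)
        assert net.adjacency[0, 1] == 1
        assert net.adjacency.sum() == 2

    def test_ties_all_included(self):
        m = SimilarityMatrix(("a", "b", "c"), np.full((3, 3), 0.5) + 0.5 * np.eye(3))
        net = binarize_similarity(m, 0.5)
        assert net.adjacency.sum() == 6

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        m = SimilarityMatrix(("a", "b"), np.array([[1.0, 0.3], [0.3, 1.0]]))
        with pytest.raises(ValueError):
            binarize_similarity(m, fraction)

    def test_density_tracks_retention(self, rng):
        v = rng.random((40, 40))
        v = np.clip((v + v.T) / 2, 0, 1)
        np.fill_diagonal(v, 1.0)
        m = SimilarityMatrix(tuple(f"e{i}" for i in range(40)), v)
        net = binarize_similarity(m, 0.1)
        density = net.adjacency.sum() / 2 / (40 * 39 / 2)
        assert density == pytest.approx(0.1, abs=0.02)


class TestCountInteractions:
    def test_single_edge_network(self, catalogue):
        net = network_from_edges(["a", "b"], [("a", "b")])
        v = count_interactions(net, "a", "b", catalogue)
        assert v.sum() == 1
        assert v[catalogue.index[(2, ((0, 1),))]] == 1

    def test_triangle_counts_edge_and_triangle(self, catalogue):
        net = network_from_edges(["a", "b", "c"],
                                 [("a", "b"), ("b", "c"), ("a", "c")])
        v = count_interactions(net, "a", "b", catalogue)
        assert v.sum() == 2
        assert v[catalogue.index[(2, ((0, 1),))]] == 1
        assert v[catalogue.index[(3, ((0, 1), (0, 2), (1, 2)))]] == 1

    def test_path_through_middle_node(self, catalogue):
        net = network_from_edges(["a", "b", "c"], [("a", "c"), ("c", "b")])
        v = count_interactions(net, "a", "b", catalogue)
        assert v.sum() == 1  # {a,b} induces no edge; only the 3-path counts

    def test_complete_k4_subset_count(self, catalogue):
        ids = ["a", "b", "c", "d"]
        net = network_from_edges(
            ids, [(u, v) for i, u in enumerate(ids) for v in ids[i + 1:]]
        )
        v = count_interactions(net, "a", "b", catalogue)
        # subsets {a,b}, {a,b,c}, {a,b,d}, {a,b,c,d} all connected
        assert v.sum() == 4

    def test_identical_nodes_rejected(self, catalogue):
        net = network_from_edges(["a", "b"], [("a", "b")])
        with pytest.raises(ValueError):
            count_interactions(net, "a", "a", catalogue)

    def test_absent_node_rejected(self, catalogue):
        net = network_from_edges(["a", "b"], [("a", "b")])
        with pytest.raises(KeyError):
            count_interactions(net, "a", "z", catalogue)

    def test_empty_network_gives_zero_vector(self, catalogue):
        net = network_from_edges(["a", "b", "c"], [])
        assert count_interactions_bruteforce(net, "a", "b", catalogue).sum() == 0

    def test_relabeling_equivariance(self, rng, catalogue):
        """Counts depend only on network structure, not on node labels."""
        net = random_network(rng, 9)
        perm = rng.permutation(9)
        relabeled = SimilarityNetwork(
            ids=tuple(net.ids[i] for i in perm),
            adjacency=net.adjacency[np.ix_(perm, perm)],
            threshold_rule={},
        )
        cnt = InteractionCounter(net, catalogue)
        cnt2 = InteractionCounter(relabeled, catalogue)
        for a, b in [("v0", "v5"), ("v3", "v8")]:
            assert np.array_equal(cnt.count(a, b), cnt2.count(a, b))

    def test_transpose_symmetry(self, rng, catalogue):
        inv = catalogue.involution()
        net = random_network(rng, 10)
        cnt = InteractionCounter(net, catalogue)
        for _ in range(10):
            a, b = rng.choice(10, size=2, replace=False)
            f = cnt.count(f"v{a}", f"v{b}")
            g = cnt.count(f"v{b}", f"v{a}")
            assert np.array_equal(f[inv], g)

    def test_edge_addition_never_decreases_totals(self, rng, catalogue):
        """A new edge only grows each pair's family of connected subsets."""
        for _ in range(10):
            net = random_network(rng, 8, p=0.25)
            absent = np.argwhere(np.triu(net.adjacency == 0, 1))
            if not len(absent):
                continue
            i, j = absent[rng.integers(len(absent))]
            denser = net.adjacency.copy()
            denser[i, j] = denser[j, i] = 1
            net2 = SimilarityNetwork(ids=net.ids, adjacency=denser, threshold_rule={})
            c1 = InteractionCounter(net, catalogue)
            c2 = InteractionCounter(net2, catalogue)
            for _ in range(5):
                a, b = rng.choice(8, size=2, replace=False)
                assert (
                    c2.count(f"v{a}", f"v{b}").sum()
                    >= c1.count(f"v{a}", f"v{b}").sum()
                )

    def test_weighted_matrix_matches_per_pair_counts(self, rng, catalogue):
        net = random_network(rng, 8)
        w = rng.random(28)
        W = InteractionCounter(net, catalogue).weighted_matrix(w)
        cnt = InteractionCounter(net, catalogue)
        for i in range(8):
            for j in range(8):
                if i == j:
                    assert W[i, j] == 0.0
                else:
                    expected = float(cnt.count(f"v{i}", f"v{j}") @ w)
                    assert W[i, j] == pytest.approx(expected, rel=1e-12)
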