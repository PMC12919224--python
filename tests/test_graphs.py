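import itertools

import numpy as np
import pytest

import treefuse as tf
from treefuse.graphs import DirectedWeightedGraph


def brute_force_digraph(tree_paths, count_mode="per-tree"):
    """Independent oracle: enumerate ordered feature pairs over all paths."""
    nodes = sorted({f for _, p in tree_paths for f in p if p})
    weights = {}
    if count_mode == "per-tree":
        trees = {}
        for t, p in tree_paths:
            trees.setdefault(t, []).append(p)
        for paths in trees.values():
            pairs = set()
            for p in paths:
                for i, j in itertools.combinations(range(len(p)), 2):
                    if p[i] != p[j]:
                        pairs.add((p[i], p[j]))
            for pr in pairs:
                weights[pr] = weights.get(pr, 0) + 1
    else:
        for _, p in tree_paths:
            pairs = set()
            for i, j in itertools.combinations(range(len(p)), 2):
                if p[i] != p[j]:
                    pairs.add((p[i], p[j]))
            for pr in pairs:
                weights[pr] = weights.get(pr, 0) + 1
    return nodes, weights


TOY_ENSEMBLES = [
    # (name, [(tree, path), ...])
    ("two-trees", [(0, [1, 2]), (0, [1, 3]), (1, [1, 2])]),
    ("repeat-feature", [(0, [1, 2, 1]), (0, [1, 4])]),
    ("five-trees", [(0, [0, 1]), (1, [1, 0]), (2, [2, 3, 4]),
                    (3, [4, 3]), (3, [4, 5]), (4, [5])]),
]


class TestBuildDigraph:
    @pytest.mark.parametrize("name,paths", TOY_ENSEMBLES,
                             ids=[t[0] for t in TOY_ENSEMBLES])
    @pytest.mark.parametrize("mode", ["per-tree", "per-path"])
    def test_matches_brute_force_enumeration(self, name, paths, mode):
        g = tf.build_digraph(paths, count_mode=mode)
        nodes, weights = brute_force_digraph(paths, mode)
        assert g.nodes == nodes
        assert g.edges == weights

    def test_hand_example_weights(self):
        # tree1 {[f1,f2],[f1,f3]}, tree2 {[f1,f2]}
        g = tf.build_digraph([(0, [1, 2]), (0, [1, 3]), (1, [1, 2])])
        assert g.nodes == [1, 2, 3]
        assert g.edges == {(1, 2): 2, (1, 3): 1}

    def test_single_feature_path(self):
        g = tf.build_digraph([(0, [1])])
        assert g.nodes == [1]
        assert g.edges == {}

    def test_repeat_creates_two_cycle(self):
        g = tf.build_digraph([(0, [1, 2, 1])])
        assert g.edges == {(1, 2): 1, (2, 1): 1}

    def test_all_empty_paths_error(self):
        with pytest.raises(ValueError, match="no features selected"):
            tf.build_digraph([(0, []), (1, [])])

    def test_weights_bounded_by_tree_count(self):
        paths = [(t, [0, 1]) for t in range(7)] + [(3, [0, 1])]
        g = tf.build_digraph(paths, count_mode="per-tree")
        assert g.edges[(0, 1)] == 7  # once per tree despite duplicate path


class TestEnsemblePaths:
    def test_boosted_separable_feature_at_root(self, rng):
        # one perfectly separating feature -> appears at some root split
        n = 80
        X = rng.random((n, 6))
        y = (X[:, 4] > 0.5).astype(int)
        X[:, 4] = np.where(y, 0.9, 0.1)  # make it cleanly separable
        ens = tf.train_ensemble(X, y, M=5, kind="boosted", seed=0)
        paths = tf.extract_paths(ens)
        assert any(p[0] == 4 for _, p in paths)

    def test_random_forest_paths_root_to_leaf(self, rng):
        X = rng.random((60, 5))
        y = (X[:, 0] + X[:, 1] > 1).astype(int)
        ens = tf.train_ensemble(X, y, M=3, kind="random-forest", seed=1)
        paths = tf.extract_paths(ens)
        assert len(paths) > 0
        # every path lists feature ids valid for this matrix
        assert all(0 <= f < 5 for _, p in paths for f in p)

    def test_fixed_seed_reproducible(self, rng):
        X = rng.random((60, 8))
        y = rng.integers(0, 2, 60)
        p1 = tf.extract_paths(tf.train_ensemble(X, y, M=10, seed=3))
        p2 = tf.extract_paths(tf.train_ensemble(X, y, M=10, seed=3))
        assert p1 == p2

    def test_single_class_rejected(self, rng):
        X = rng.random((20, 3))
        with pytest.raises(ValueError, match="single class"):
            tf.train_ensemble(X, np.zeros(20, dtype=int), M=5)


class TestNormalizeAdjacency:
    def test_no_edges_gives_identity(self):
        g = DirectedWeightedGraph(nodes=[0, 1], edges={})
        np.testing.assert_allclose(tf.normalize_adjacency(g), np.eye(2),
                                   atol=1e-12)

    def test_single_edge_closed_form(self):
        g = DirectedWeightedGraph(nodes=[0, 1], edges={(0, 1): 1})
        expected = np.array([[0.5, 0.7071067811865475], [0.0, 1.0]])
        np.testing.assert_allclose(tf.normalize_adjacency(g), expected,
                                   atol=1e-12)

    def test_weighted_edge_closed_form(self):
        g = DirectedWeightedGraph(nodes=[0, 1], edges={(0, 1): 3})
        expected = np.array([[0.25, 1.5], [0.0, 1.0]])
        np.testing.assert_allclose(tf.normalize_adjacency(g), expected,
                                   atol=1e-12)

    def test_entrywise_formula_on_random_graphs(self, rng):
        for _ in range(10):
            p = int(rng.integers(2, 7))
            nodes = list(range(p))
            edges = {}
            for a in range(p):
                for b in range(p):
                    if a != b and rng.random() < 0.4:
                        edges[(a, b)] = float(rng.integers(1, 5))
            g = DirectedWeightedGraph(nodes=nodes, edges=edges)
            N = tf.normalize_adjacency(g)
            At = g.adjacency() + np.eye(p)
            rs = At.sum(axis=1)
            for a in range(p):
                for b in range(p):
                    assert N[a, b] == pytest.approx(
                        At[a, b] / np.sqrt(rs[a] * rs[b]), abs=1e-12)
            assert np.isfinite(N).all() and (N >= 0).all()


class TestSymmetrize:
    def test_one_way_edge_mirrored(self):
        g = DirectedWeightedGraph(nodes=[0, 1], edges={(0, 1): 2})
        s = tf.symmetrize(g)
        assert s.edges == {(0, 1): 2, (1, 0): 2}

    def test_two_cycle_weights_add(self):
        g = DirectedWeightedGraph(nodes=[0, 1], edges={(0, 1): 1, (1, 0): 3})
        s = tf.symmetrize(g)
        assert s.edges == {(0, 1): 4, (1, 0): 4}
        A = s.adjacency()
        np.testing.assert_array_equal(A, A.T)

    def test_not_idempotent_weights_double(self):
        g = DirectedWeightedGraph(nodes=[0, 1], edges={(0, 1): 2})
        once = tf.symmetrize(g)
        twice = tf.symmetrize(once)
        assert twice.edges[(0, 1)] == 2 * once.edges[(0, 1)]

    def test_max_mode(self):
        g = DirectedWeightedGraph(nodes=[0, 1], edges={(0, 1): 1, (1, 0): 3})
        s = tf.symmetrize(g, mode="max")
        assert s.edges == {(0, 1): 3, (1, 0): 3}


class TestReduceAndStats:
    def test_column_selection_in_node_order(self, rng):
        X = rng.random((4, 10))
        g = DirectedWeightedGraph(nodes=[2, 7], edges={(2, 7): 1})
        Xs = tf.reduce_features(X, g)
        np.testing.assert_array_equal(Xs, X[:, [2, 7]])

    def test_same_graph_on_held_out_rows(self, rng):
        X = rng.random((8, 10))
        g = DirectedWeightedGraph(nodes=[1, 3, 5], edges={})
        a = tf.reduce_features(X[:5], g)
        b = tf.reduce_features(X[5:], g)
        assert a.shape[1] == b.shape[1] == 3

    def test_missing_node_errors(self, rng):
        g = DirectedWeightedGraph(nodes=[0, 12], edges={})
        with pytest.raises(ValueError, match="absent"):
            tf.reduce_features(rng.random((3, 5)), g)

    def test_stats_ratio(self):
        g = DirectedWeightedGraph(nodes=[0, 1, 2],
                                  edges={(0, 1): 1, (1, 2): 1})
        s = tf.graph_stats(g)
        assert s.node_count == 3 and s.edge_count == 2
        assert s.edge_node_ratio == pytest.approx(2 / 3)

    def test_single_node_zero_edges(self):
        s = tf.graph_stats(DirectedWeightedGraph(nodes=[5], edges={}))
        assert s.edge_node_ratio == 0.0


class TestGraphIO:
    def test_round_trip(self, tmp_path):
        g = DirectedWeightedGraph(nodes=[3, 1, 5],
                                  edges={(3, 1): 2, (1, 5): 7})
        ep, np_ = str(tmp_path / "e.tsv"), str(tmp_path / "n.tsv")
        tf.write_graph(g, ep, np_)
        back = tf.read_graph(ep, np_)
        assert back.nodes == g.nodes  # node order persisted
        assert back.edges == g.edges

    def test_networkx_export(self):
        from treefuse.graphs import to_networkx
        g = DirectedWeightedGraph(nodes=[0, 1], edges={(0, 1): 2})
        nxg = to_networkx(g)
        assert nxg.number_of_nodes() == 2
        assert nxg[0][1]["weight"] == 2
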