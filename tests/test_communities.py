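"""Modularity, fast-greedy community detection, and mask pooling."""

import numpy as np
import pytest

import veingraph as vg
from veingraph.communities import VeinGraphClustering

from conftest import clique_edges, make_graph


def iter_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=np.intp)

    def rec(i: int, max_used: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(max_used + 2):
            labels[i] = c
            yield from rec(i + 1, max(max_used, c))

    yield from rec(1, 0)


def exhaustive_best_q(g) -> float:
    return max(vg.modularity(g, labels) for labels in iter_partitions(g.n_nodes))


class TestModularity:
    def test_single_edge_merged_is_zero(self):
        g = make_graph(2, [(0, 1, 1.0)])
        assert vg.modularity(g, [0, 0]) == pytest.approx(0.0)

    def test_single_edge_split_is_minus_half(self):
        g = make_graph(2, [(0, 1, 1.0)])
        assert vg.modularity(g, [0, 1]) == pytest.approx(-0.5)

    def test_two_disjoint_cliques(self):
        g = make_graph(10, clique_edges(list(range(5))) + clique_edges(list(range(5, 10))))
        labels = [0] * 5 + [1] * 5
        assert vg.modularity(g, labels) == pytest.approx(0.5)

    def test_matches_networkx(self):
        networkx = pytest.importorskip("networkx")
        rng = np.random.default_rng(10)
        n = 25
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.15:
                    edges.append((i, j, float(rng.uniform(0.1, 1.0))))
        g = make_graph(n, edges)
        labels = rng.integers(0, 4, size=n)
        gx = networkx.Graph()
        gx.add_nodes_from(range(n))
        gx.add_weighted_edges_from(edges)
        comms = [set(np.nonzero(labels == c)[0]) for c in range(4)]
        expected = networkx.community.modularity(gx, comms, weight="weight")
        assert vg.modularity(g, labels) == pytest.approx(expected, abs=1e-12)

    def test_zero_weight_rejected(self):
        g = make_graph(3, [])
        with pytest.raises(ValueError, match="zero total"):
            vg.modularity(g, [0, 1, 2])


class TestFastGreedy:
    def test_edgeless_graph_all_singletons(self):
        g = make_graph(5, [])
        p = vg.fast_greedy_partition(g)
        assert p.n_communities == 5
        assert p.modularity == 0.0

    def test_two_cliques_with_bridge_recovered(self):
        edges = (
            clique_edges(list(range(5)))
            + clique_edges(list(range(5, 10)))
            + [(4, 5, 1.0)]
        )
        g = make_graph(10, edges)
        p = vg.fast_greedy_partition(g)
        assert p.n_communities == 2
        assert len(set(p.labels[:5])) == 1 and len(set(p.labels[5:])) == 1
        assert p.labels[0] != p.labels[5]
        # greedy finds the global optimum here
        assert p.modularity == pytest.approx(exhaustive_best_q(g), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_attains_exhaustive_optimum_on_planted_cliques(self, seed):
        """Two planted 4-cliques plus random weights: greedy Q == brute-force max."""
        rng = np.random.default_rng(seed)
        edges = clique_edges([0, 1, 2, 3], 1.0) + clique_edges([4, 5, 6, 7], 1.0)
        edges.append((int(rng.integers(0, 4)), int(rng.integers(4, 8)), 0.5))
        g = make_graph(8, edges)
        p = vg.fast_greedy_partition(g)
        assert p.modularity == pytest.approx(exhaustive_best_q(g), abs=1e-12)

    def test_partition_modularity_recomputes(self, phantom_run):
        _, _, model = phantom_run
        q = vg.modularity(model.graph_, model.labels_)
        assert q == pytest.approx(model.modularity_, abs=1e-9)

    def test_trace_nondecreasing_up_to_cut(self):
        edges = (
            clique_edges(list(range(5)))
            + clique_edges(list(range(5, 10)))
            + [(0, 5, 0.3), (1, 6, 0.3)]
        )
        p = vg.fast_greedy_partition(make_graph(10, edges))
        trace = p.q_trace[: p.cut_step]
        assert np.all(np.diff(trace) >= -1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        n = 14
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    edges.append((i, j, float(rng.uniform(0.2, 1.0))))
        g = make_graph(n, edges)
        p = vg.fast_greedy_partition(g)
        perm = rng.permutation(n)
        pedges = [(min(perm[i], perm[j]), max(perm[i], perm[j]), w) for i, j, w in edges]
        p2 = vg.fast_greedy_partition(make_graph(n, pedges))
        # same grouping up to relabeling
        co1 = p.labels[:, None] == p.labels[None, :]
        co2 = p2.labels[perm][:, None] == p2.labels[perm][None, :]
        assert np.array_equal(co1, co2)

    def test_isolated_nodes_stay_singletons(self):
        g = make_graph(6, clique_edges([0, 1, 2]))
        p = vg.fast_greedy_partition(g)
        for node in (3, 4, 5):
            assert p.sizes[p.labels[node]] == 1

    def test_close_to_igraph_reference(self):
        """Independent cross-check against igraph's fast-greedy clustering."""
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(13)
        n = 40
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                block = (i < 20) == (j < 20)
                if rng.random() < (0.4 if block else 0.03):
                    edges.append((i, j, float(rng.uniform(0.3, 1.0))))
        g = make_graph(n, edges)
        mine = vg.fast_greedy_partition(g)
        gi = igraph.Graph(n=n, edges=[(i, j) for i, j, _ in edges])
        gi.es["weight"] = [w for _, _, w in edges]
        ref = gi.community_fastgreedy(weights="weight").as_clustering()
        q_ref = gi.modularity(ref.membership, weights="weight")
        assert mine.modularity >= q_ref - 0.02


class TestPooling:
    def _partition_with_sizes(self, sizes):
        labels = np.concatenate([np.full(s, k) for k, s in enumerate(sizes)])
        return vg.Partition(
            labels=labels.astype(np.intp), sizes=np.array(sizes), modularity=0.0
        )

    def _map_and_brain(self, n):
        shape = (n, 1, 1)
        brain = vg.Mask3D(data=np.ones(shape, dtype=np.uint8), affine=np.eye(4))
        return vg.voxel_index_map(brain), brain

    @pytest.mark.parametrize(
        "sizes, expected",
        [([60, 49, 3], 60), ([50], 50), ([49, 30], 0), ([50, 49], 50)],
        ids=["mixed", "exact-boundary", "all-small", "boundary-pair"],
    )
    def test_inclusive_size_threshold(self, sizes, expected):
        p = self._partition_with_sizes(sizes)
        imap, brain = self._map_and_brain(sum(sizes))
        res = vg.pool_large_clusters(p, imap, brain, min_size=50)
        assert res.n_voxels == expected
        assert sum(s for _, s in res.included_clusters) == expected

    def test_min_size_validated(self):
        p = self._partition_with_sizes([10])
        imap, brain = self._map_and_brain(10)
        with pytest.raises(ValueError, match="min_size"):
            vg.pool_large_clusters(p, imap, brain, min_size=0)


class TestVeinGraphClusteringEstimator:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = VeinGraphClustering(min_cluster_size=3, threshold=0.8)
        assert clone(est).get_params()["min_cluster_size"] == 3

    def test_fit_predict_on_planted_blocks(self):
        rng = np.random.default_rng(14)
        t = 80
        shared = rng.standard_normal(t)
        X = rng.standard_normal((12, t))
        X[:6] = 0.95 * shared + 0.2 * X[:6]
        est = VeinGraphClustering(threshold=0.8, min_cluster_size=5)
        labels = est.fit_predict(X)
        assert np.array_equal(labels, est.labels_)
        assert len(set(labels[:6])) == 1
        assert est.is_vein_[:6].all()
        assert not est.is_vein_[6:].any()
        assert est.sparsity_.n_edges >= 15
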