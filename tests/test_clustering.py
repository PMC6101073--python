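import numpy as np
import igraph as ig
import pytest

from sctfidf.clustering import (
    CellGraph,
    ClusterAssignment,
    build_cell_graph,
    cluster_graph,
    gmm_em,
    hierarchical_ward,
    kmeans,
    per_cluster_silhouette,
    recursive_partition,
    relabel_contiguous,
    spherical_kmeans,
)
from sctfidf.distances import DistanceMatrix, pairwise


def dm(d, metric="euclidean"):
    return DistanceMatrix(d=np.asarray(d, float), metric=metric)


class TestRelabel:
    def test_contiguous_first_occurrence(self):
        out = relabel_contiguous([5, 5, 2, 7, 2])
        assert out.tolist() == [0, 0, 1, 2, 1]


class TestKmeans:
    def test_k1(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        assert kmeans(x, 1, 0).k == 1

    def test_two_clouds(self):
        rng = np.random.default_rng(1)
        x = np.vstack(
            [rng.normal(0, 0.1, (20, 2)), rng.normal(50, 0.1, (20, 2))]
        )
        a = kmeans(x, 2, 0)
        assert a.k == 2
        assert len(set(a.labels[:20])) == 1
        assert len(set(a.labels[20:])) == 1

    def test_k_equals_n(self):
        x = np.arange(6, dtype=float).reshape(-1, 1) * 10
        a = kmeans(x, 6, 0)
        assert a.k == 6

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            kmeans(np.zeros((3, 2)), 4, 0)

    def test_deterministic(self):
        x = np.random.default_rng(2).normal(size=(40, 5))
        a = kmeans(x, 3, 7)
        b = kmeans(x, 3, 7)
        assert np.array_equal(a.labels, b.labels)


class TestSphericalKmeans:
    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 4)) + 2
        a = spherical_kmeans(x, 3, 0)
        x2 = x.copy()
        x2[5] *= 37.0
        b = spherical_kmeans(x2, 3, 0)
        assert np.array_equal(a.labels, b.labels)

    def test_orthogonal_bundles(self):
        rng = np.random.default_rng(4)
        a_dir = np.array([1.0, 0.0, 0.0])
        b_dir = np.array([0.0, 1.0, 0.0])
        pts = np.vstack(
            [
                a_dir * rng.uniform(1, 10, (25, 1)) + rng.normal(0, 0.02, (25, 3)),
                b_dir * rng.uniform(1, 10, (25, 1)) + rng.normal(0, 0.02, (25, 3)),
            ]
        )
        out = spherical_kmeans(pts, 2, 0)
        assert len(set(out.labels[:25])) == 1
        assert len(set(out.labels[25:])) == 1

    def test_k1(self):
        x = np.random.default_rng(5).normal(size=(8, 3)) + 5
        assert spherical_kmeans(x, 1, 0).k == 1

    def test_zero_norm_rejected(self):
        x = np.zeros((4, 3))
        x[0] = 1
        with pytest.raises(ValueError):
            spherical_kmeans(x, 2, 0)


class TestGmm:
    def test_separated_gaussians(self):
        rng = np.random.default_rng(6)
        x = np.vstack(
            [rng.normal(0, 1, (200, 2)), rng.normal(10, 1, (200, 2))]
        )
        a = gmm_em(x, 2, 0)
        truth = np.array([0] * 200 + [1] * 200)
        match = max(
            (a.labels == truth).mean(), (a.labels == 1 - truth).mean()
        )
        assert match >= 0.99

    def test_k1(self):
        x = np.random.default_rng(7).normal(size=(20, 2))
        assert gmm_em(x, 1, 0).k == 1

    def test_em_loglik_nondecreasing(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal(0, 1, (60, 2)), rng.normal(4, 1, (60, 2))])
        gm = GaussianMixture(
            n_components=2, max_iter=1, warm_start=True, random_state=0,
            n_init=1, tol=0.0,
        )
        lls = []
        for _ in range(15):
            gm.fit(x)
            lls.append(gm.lower_bound_)
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def naive_ward(d):
    """Independent Lance-Williams Ward agglomeration: returns the list of
    frozenset partitions after each merge."""
    d = np.array(d, dtype=float)
    n = d.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    partitions = []
    next_id = n
    while len(clusters) > 1:
        (a, b), _ = min(dist.items(), key=lambda kv: kv[1])
        na, nb = sizes[a], sizes[b]
        merged = clusters[a] | clusters[b]
        dab = dist[(a, b)]
        new_dist = {}
        for c in clusters:
            if c in (a, b):
                continue
            nc = sizes[c]
            dac = dist[(min(a, c), max(a, c))]
            dbc = dist[(min(b, c), max(b, c))]
            val = np.sqrt(
                ((na + nc) * dac**2 + (nb + nc) * dbc**2 - nc * dab**2)
                / (na + nb + nc)
            )
            new_dist[c] = val
        del clusters[a], clusters[b]
        dist = {
            key: v
            for key, v in dist.items()
            if a not in key and b not in key
        }
        clusters[next_id] = merged
        sizes[next_id] = na + nb
        for c, v in new_dist.items():
            dist[(min(c, next_id), max(c, next_id))] = v
        partitions.append(frozenset(clusters.values()))
        next_id += 1
    return partitions


class TestHierarchicalWard:
    def test_singletons(self):
        d = pairwise(np.random.default_rng(9).random((4, 5)), "euclidean")
        assert hierarchical_ward(d, 5).k == 5

    def test_three_groups_1d(self):
        pts = np.array([[0, 0.1, 5, 5.1, 10, 10.1]])
        d = pairwise(pts, "euclidean")
        a = hierarchical_ward(d, 3)
        assert a.labels.tolist() == [0, 0, 1, 1, 2, 2]

    def test_matches_lance_williams_oracle(self):
        rng = np.random.default_rng(10)
        pts = rng.random((3, 6)) * np.array([[1], [3], [7]])
        d = pairwise(pts, "euclidean")
        oracle = naive_ward(d.d)
        for k in (2, 3, 4, 5):
            ours = hierarchical_ward(d, k).labels
            # the oracle partition after n-k merges
            expect = oracle[6 - k - 1]
            got = {
                frozenset(np.flatnonzero(ours == c).tolist())
                for c in np.unique(ours)
            }
            assert got == set(expect)

    def test_oracle_on_nonmetric_distances(self):
        """Ward via Lance-Williams applies to e.g. Jaccard distances too."""
        rng = np.random.default_rng(11)
        m = (rng.random((40, 7)) < 0.5).astype(float)
        m[0] = 1
        d = pairwise(m, "jaccard")
        oracle = naive_ward(d.d)
        for k in (2, 4):
            ours = hierarchical_ward(d, k).labels
            expect = oracle[7 - k - 1]
            got = {
                frozenset(np.flatnonzero(ours == c).tolist())
                for c in np.unique(ours)
            }
            assert got == set(expect)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            hierarchical_ward(d, 1)


class TestBuildCellGraph:
    def test_complete_at_zero_cutoff(self):
        d = dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        g = build_cell_graph(d, cutoff=0.0)
        assert len(g.edges) == 3

    def test_min_pair_never_edge(self):
        d = dm([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        g = build_cell_graph(d, cutoff=0.01)
        assert (0, 1) not in g.edges  # the scaled-0 pair
        assert len(g.edges) == 2

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(12)
        d = pairwise(rng.random((5, 20)), "euclidean")
        g = build_cell_graph(d, cutoff=0.01)
        assert np.all(g.weights > 0)
        assert np.all(g.weights <= 1)

    def test_degenerate_distances_raise(self):
        d = dm([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            build_cell_graph(d)


def planted_graph(n_a=10, n_b=10, bridge_weight=0.01):
    edges, weights = [], []
    for i in range(n_a):
        for j in range(i + 1, n_a):
            edges.append((i, j))
            weights.append(1.0)
    for i in range(n_b):
        for j in range(i + 1, n_b):
            edges.append((n_a + i, n_a + j))
            weights.append(1.0)
    if bridge_weight:
        edges.append((0, n_a))
        weights.append(bridge_weight)
    return CellGraph(
        n=n_a + n_b, edges=edges, weights=np.array(weights), metric="euclidean"
    )


class TestClusterGraph:
    @pytest.mark.parametrize("algorithm", ["greedy", "louvain"])
    def test_two_cliques(self, algorithm):
        g = planted_graph()
        a = cluster_graph(g, algorithm, seed=0)
        assert a.k == 2
        assert len(set(a.labels[:10])) == 1
        assert len(set(a.labels[10:])) == 1

    @pytest.mark.parametrize("algorithm", ["greedy", "louvain"])
    def test_single_clique(self, algorithm):
        g = planted_graph(n_a=8, n_b=0, bridge_weight=0)
        assert cluster_graph(g, algorithm, seed=0).k == 1

    def test_modularity_beats_trivial_partition(self):
        g = planted_graph()
        a = cluster_graph(g, "louvain", seed=0)
        graph = ig.Graph(n=g.n, edges=g.edges)
        w = list(map(float, g.weights))
        q = graph.modularity(a.labels.tolist(), weights=w)
        q0 = graph.modularity([0] * g.n, weights=w)
        assert q >= q0

    def test_disconnected_components_never_merged(self):
        g = planted_graph(bridge_weight=0)
        for algorithm in ("greedy", "louvain"):
            a = cluster_graph(g, algorithm, seed=0)
            assert set(a.labels[:10]).isdisjoint(set(a.labels[10:]))

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        d = pairwise(rng.random((20, 40)), "euclidean")
        g = build_cell_graph(d)
        a = cluster_graph(g, "louvain", seed=5)
        b = cluster_graph(g, "louvain", seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_empty_graph_raises(self):
        g = CellGraph(n=0, edges=[], weights=np.array([]), metric="euclidean")
        with pytest.raises(ValueError):
            cluster_graph(g, "louvain", 0)


class StubPipeline:
    """Euclidean k-means style pipeline over raw counts, for testing the
    recursion mechanics independent of TF-IDF."""

    def distances(self, m):
        return pairwise(m.to_dense(), "euclidean").d

    def cluster(self, m, seed):
        x = m.to_dense().T
        return kmeans(x, min(2, x.shape[0]), seed).labels

    def fallback_split(self, m):
        d = pairwise(m.to_dense(), "euclidean")
        return hierarchical_ward(d, 2).labels


class TestRecursivePartition:
    @staticmethod
    def _two_group_counts(counts_factory):
        rng = np.random.default_rng(14)
        a = rng.poisson(5, size=(10, 15)) + np.array([20] * 5 + [0] * 5)[:, None]
        b = rng.poisson(5, size=(10, 15)) + np.array([0] * 5 + [20] * 5)[:, None]
        return counts_factory(np.hstack([a, b]))

    def test_identity_when_satisfied(self, counts_factory):
        m = self._two_group_counts(counts_factory)
        base = ClusterAssignment(np.array([0] * 15 + [1] * 15), "base")
        out = recursive_partition(m, StubPipeline(), base, min_k=2)
        assert np.array_equal(out.labels, base.labels)

    def test_merged_types_split(self, counts_factory):
        m = self._two_group_counts(counts_factory)
        base = ClusterAssignment(np.zeros(30, dtype=int), "base")
        out = recursive_partition(m, StubPipeline(), base, min_k=2)
        assert out.k == 2
        assert len(set(out.labels[:15])) == 1
        assert len(set(out.labels[15:])) == 1

    def test_threshold_minus_one_identity(self, counts_factory):
        m = self._two_group_counts(counts_factory)
        base = ClusterAssignment(np.array([0] * 15 + [1] * 15), "base")
        out = recursive_partition(
            m, StubPipeline(), base, min_k=1, silhouette_threshold=-1.0
        )
        assert np.array_equal(out.labels, base.labels)

    def test_never_decreases_k(self, counts_factory):
        m = self._two_group_counts(counts_factory)
        base = ClusterAssignment(np.array([0, 1] * 15), "base")
        out = recursive_partition(m, StubPipeline(), base, min_k=4)
        assert out.k >= base.k

    def test_tiny_cluster_not_split(self, counts_factory):
        m = self._two_group_counts(counts_factory).subset(
            cell_idx=np.arange(2)
        )
        base = ClusterAssignment(np.zeros(2, dtype=int), "base")
        out = recursive_partition(m, StubPipeline(), base, min_k=2)
        assert out.k == 1  # size-2 cluster is never re-partitioned


class TestSilhouette:
    def test_single_cluster_reported_low(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        sil = per_cluster_silhouette(d, np.zeros(2, dtype=int))
        assert sil == {0: -1.0}

    def test_good_split_scores_high(self):
        pts = np.array([[0, 0.1, 10, 10.1]])
        d = pairwise(pts, "euclidean").d
        sil = per_cluster_silhouette(d, np.array([0, 0, 1, 1]))
        assert min(sil.values()) > 0.9
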