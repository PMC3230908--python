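"""Clustering algorithms: worked examples, oracles, and structural invariants."""
import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from ppidenoise.clustering import (
    CMCParams,
    Clustering,
    MCLParams,
    SpectralParams,
    cluster_graph,
    cmc,
    eigengap_k,
    em_cluster,
    find_maximal_cliques,
    interconnectivity,
    kmeans_pp,
    mcl,
    spectral_cluster,
    spectral_embed,
    weighted_density,
)


def clusters_as_sets(c: Clustering) -> set[frozenset[str]]:
    return set(c.clusters)


class TestClusteringContainer:
    def test_singletons_rejected(self):
        with pytest.raises(ValueError):
            Clustering([frozenset({"a"})], overlapping=False)

    def test_disjointness_enforced_when_not_overlapping(self):
        with pytest.raises(ValueError):
            Clustering([frozenset({"a", "b"}), frozenset({"b", "c"})], overlapping=False)


class TestMCL:
    def test_disconnected_triangles_are_separate_clusters(self, triangle_pair):
        result = mcl(triangle_pair)
        assert clusters_as_sets(result) == {
            frozenset({"a", "b", "c"}),
            frozenset({"x", "y", "z"}),
        }

    def test_single_clique_is_one_cluster(self):
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, {i: f"p{i}" for i in range(5)})
        for u, v in g.edges():
            g[u][v]["weight"] = 1.0
        result = mcl(g)
        assert clusters_as_sets(result) == {frozenset(f"p{i}" for i in range(5))}

    def test_weak_bridge_split_matches_numeric_oracle(self, bridged_cliques):
        """Independent straight-line iteration of the expansion/inflation recurrence."""
        nodes = sorted(bridged_cliques.nodes())
        a = nx.to_numpy_array(bridged_cliques, nodelist=nodes, weight="weight")
        np.fill_diagonal(a, a.max(axis=1))
        m = a / a.sum(axis=0)
        for _ in range(200):
            m = np.linalg.matrix_power(m, 2)
            m = m**2.0
            m = m / m.sum(axis=0)
            m[m < 1e-5] = 0.0
            m = m / m.sum(axis=0)
        support = nx.Graph()
        support.add_nodes_from(range(len(nodes)))
        support.add_edges_from(zip(*np.nonzero(m + m.T)))
        oracle = {
            frozenset(nodes[i] for i in comp)
            for comp in nx.connected_components(support)
        }
        result = mcl(bridged_cliques, MCLParams(inflation=2.0))
        assert clusters_as_sets(result) == oracle
        assert clusters_as_sets(result) == {
            frozenset({"a1", "a2", "a3", "a4"}),
            frozenset({"b1", "b2", "b3", "b4"}),
        }

    def test_flow_matrix_stays_column_stochastic(self, bridged_cliques):
        """Every normalization inside the loop restores column sums of 1."""
        from ppidenoise.clustering import _column_normalize

        rng = np.random.default_rng(4)
        m = rng.random((6, 6))
        for _ in range(5):
            m = _column_normalize(np.linalg.matrix_power(_column_normalize(m), 2) ** 2.0)
            assert np.allclose(m.sum(axis=0), 1.0, atol=1e-9)

    def test_unweighted_graph_treated_as_unit_weights(self, triangle_pair):
        bare = nx.Graph(triangle_pair.edges())
        assert clusters_as_sets(mcl(bare)) == clusters_as_sets(mcl(triangle_pair))

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mcl(nx.Graph())

    def test_deterministic(self, bridged_cliques):
        assert clusters_as_sets(mcl(bridged_cliques)) == clusters_as_sets(mcl(bridged_cliques))


class TestMaximalCliques:
    def test_triangle_with_pendant(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        assert set(find_maximal_cliques(g)) == {
            frozenset({"a", "b", "c"}),
            frozenset({"c", "d"}),
        }

    def test_four_clique_reported_once(self):
        g = nx.complete_graph(4)
        assert set(find_maximal_cliques(g)) == {frozenset(range(4))}

    def test_matches_exhaustive_subset_enumeration(self):
        """Brute-force oracle: a maximal clique is a fully connected subset
        such that no strict superset is fully connected."""
        for seed in range(8):
            g = nx.gnp_random_graph(8, 0.5, seed=seed)
            nodes = list(g.nodes())
            is_clique = {}
            for r in range(2, 9):
                for sub in itertools.combinations(nodes, r):
                    is_clique[frozenset(sub)] = all(
                        g.has_edge(u, v) for u, v in itertools.combinations(sub, 2)
                    )
            expected = {
                s
                for s, flag in is_clique.items()
                if flag
                and not any(
                    flag2 and s < s2 for s2, flag2 in is_clique.items()
                )
            }
            assert set(find_maximal_cliques(g, min_size=2)) == expected


class TestCMC:
    def test_disjoint_triangles_kept_unchanged(self, triangle_pair):
        result = cmc(triangle_pair)
        assert clusters_as_sets(result) == {
            frozenset({"a", "b", "c"}),
            frozenset({"x", "y", "z"}),
        }

    def test_duplicate_clique_removed(self, triangle_pair):
        tri = frozenset({"a", "b", "c"})
        result = cmc(triangle_pair, cliques=[tri, tri, frozenset({"x", "y", "z"})])
        assert clusters_as_sets(result) == {tri, frozenset({"x", "y", "z"})}

    def test_heavily_overlapping_cliques_merge(self):
        g = nx.Graph()
        for clique in (("n1", "n2", "n3", "n4"), ("n2", "n3", "n4", "n5")):
            for u, v in itertools.combinations(clique, 2):
                g.add_edge(u, v, weight=1.0)
        # overlap 3/4 >= 0.5 and interconnectivity 3/4 >= 0.25 -> merge
        result = cmc(g)
        assert clusters_as_sets(result) == {frozenset({"n1", "n2", "n3", "n4", "n5"})}

    def test_weakly_interconnected_overlap_discarded(self):
        g = nx.Graph()
        for u, v in itertools.combinations(("n1", "n2", "n3", "n4"), 2):
            g.add_edge(u, v, weight=1.0)
        for u, v in itertools.combinations(("n2", "n3", "n4", "n5"), 2):
            if not g.has_edge(u, v):
                g.add_edge(u, v, weight=0.01)
        result = cmc(g, CMCParams(merge_threshold=0.5))
        assert frozenset({"n1", "n2", "n3", "n4"}) in clusters_as_sets(result)
        assert all("n5" not in c or len(c) < 5 for c in result.clusters)

    def test_interconnectivity_formula(self):
        g = nx.Graph()
        for u, v in itertools.combinations(("n1", "n2", "n3", "n4"), 2):
            g.add_edge(u, v, weight=1.0)
        g.add_edge("n5", "n2", weight=1.0)
        g.add_edge("n5", "n3", weight=0.5)
        cluster = {"n1", "n2", "n3", "n4"}
        assert interconnectivity(g, cluster, {"n5", "n2"}) == pytest.approx(1.5 / 4)

    def test_density_never_above_one(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.5, seed=int(rng.integers(2**31)))
            for u, v in g.edges():
                g[u][v]["weight"] = float(rng.random())
            if g.number_of_edges() == 0:
                continue
            result = cmc(g)
            for cluster in result.clusters:
                assert weighted_density(g, cluster) <= 1.0 + 1e-12

    def test_overlapping_output_allowed(self):
        # two triangles sharing one node: neither reaches the overlap threshold
        g = nx.Graph()
        for tri in (("a", "b", "s"), ("c", "d", "s")):
            for u, v in itertools.combinations(tri, 2):
                g.add_edge(u, v, weight=1.0)
        result = cmc(g)
        assert result.overlapping
        members = [m for c in result.clusters for m in c]
        assert members.count("s") == 2


class TestSpectral:
    def test_zero_eigenvalue_multiplicity_counts_components(self):
        g = nx.disjoint_union_all([nx.complete_graph(4) for _ in range(3)])
        for u, v in g.edges():
            g[u][v]["weight"] = 1.0
        _, eigenvalues, _ = spectral_embed(g)
        assert np.all(np.abs(eigenvalues[:3]) < 1e-8)
        assert eigenvalues[3] > 1e-3

    def test_clique_members_embed_identically(self):
        g = nx.disjoint_union_all([nx.complete_graph(3), nx.complete_graph(3)])
        points, _, nodes = spectral_embed(g)
        coords = {n: tuple(np.round(points[i], 8)) for i, n in enumerate(nodes)}
        assert len(set(coords.values())) == 2

    def test_eigengap_picks_component_count(self):
        g = nx.disjoint_union_all([nx.complete_graph(4), nx.complete_graph(4)])
        lap = nx.normalized_laplacian_matrix(g).toarray()
        eigenvalues = np.linalg.eigvalsh(lap)
        assert eigengap_k(eigenvalues) == 2

    @pytest.mark.parametrize(
        "eigenvalues,expected",
        [((0, 0, 0, 0.9, 1.0, 1.1), 3), ((0, 1, 1, 1), 1)],
    )
    def test_eigengap_worked_examples(self, eigenvalues, expected):
        assert eigengap_k(np.array(eigenvalues, dtype=float)) == expected

    def test_eigengap_needs_two_values(self):
        with pytest.raises(ValueError):
            eigengap_k(np.array([0.0]))

    def test_small_graphs_rejected(self):
        with pytest.raises(ValueError):
            spectral_embed(nx.complete_graph(2))

    @pytest.mark.parametrize("variant", ["kmeanspp", "em"])
    @pytest.mark.parametrize("seed", [0, 17])
    def test_disconnected_cliques_recovered_exactly(self, variant, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 7, size=int(rng.integers(2, 7)))
        g = nx.disjoint_union_all([nx.complete_graph(int(s)) for s in sizes])
        g = nx.relabel_nodes(g, {n: f"p{n}" for n in g.nodes()})
        expected = {frozenset(c) for c in nx.connected_components(g)}
        result = spectral_cluster(g, SpectralParams(variant=variant, seed=seed))
        assert clusters_as_sets(result) == expected


class TestPointClusterers:
    def test_separated_pairs(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        labels, _ = kmeans_pp(pts, 2, restarts=5, seed=1)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_kmeans_deterministic_per_seed(self):
        rng = np.random.default_rng(7)
        pts = rng.random((40, 3))
        a = kmeans_pp(pts, 4, restarts=10, seed=42)
        b = kmeans_pp(pts, 4, restarts=10, seed=42)
        assert np.array_equal(a[0], b[0]) and a[1] == b[1]

    def test_kmeans_returns_best_restart(self):
        rng = np.random.default_rng(3)
        pts = rng.random((60, 2))
        labels, best, sses = kmeans_pp(pts, 5, restarts=12, seed=5, return_sses=True)
        assert len(sses) == 12
        assert best == min(sses)

    def test_k_above_distinct_points_is_error(self):
        pts = np.zeros((5, 2))
        with pytest.raises(ValueError):
            kmeans_pp(pts, 2)

    def test_em_separated_blobs(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal(0, 0.05, size=(30, 2))
        blob2 = rng.normal(5, 0.05, size=(30, 2))
        labels = em_cluster(np.vstack([blob1, blob2]), 2, seed=0)
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[30]

    def test_em_posteriors_normalized_and_loglik_monotone(self):
        """One EM step at a time (warm start): responsibilities sum to one and
        the per-sample average log-likelihood never decreases."""
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(4, 1, (40, 2))])
        gm = GaussianMixture(
            n_components=2, covariance_type="diag", init_params="k-means++",
            reg_covar=1e-6, random_state=0, warm_start=True, max_iter=1,
        )
        trajectory = []
        for _ in range(25):
            gm.fit(pts)
            trajectory.append(gm.lower_bound_)
            post = gm.predict_proba(pts)
            assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        diffs = np.diff(np.array(trajectory))
        assert np.all(diffs >= -1e-9)


class TestDispatcher:
    def test_unknown_algorithm_rejected(self, triangle_pair):
        with pytest.raises(ValueError):
            cluster_graph(triangle_pair, "quasi-clique")

    @pytest.mark.parametrize("algo", ["mcl", "cmc", "spectral-kmeanspp", "spectral-em"])
    def test_nonoverlapping_algorithms_partition(self, algo, triangle_pair):
        result = cluster_graph(triangle_pair, algo)
        members = [m for c in result.clusters for m in c]
        if not result.overlapping:
            assert len(members) == len(set(members))
        assert set(members) <= set(triangle_pair.nodes())
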