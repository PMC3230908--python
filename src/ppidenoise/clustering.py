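"""Weighted-graph clustering algorithms for candidate complex discovery.

Four clusterers that honor edge weights are implemented:

* :func:`mcl` — Markov clustering: simulates random walks on the weighted
  graph, alternating *expansion* (matrix squaring, which extends walks) and
  *inflation* (entrywise powering + column renormalization, which sharpens
  intra-cluster walk probabilities) until the flow matrix converges to a set
  of attractor systems, read off as non-overlapping clusters.
* :func:`cmc` — clustering on maximal cliques: enumerates the maximal
  cliques, ranks them by weighted density, and resolves highly overlapping
  cliques by merging (when well interconnected) or discarding; clusters may
  overlap.
* :func:`spectral_cluster` — the Ng-Jordan-Weiss spectral embedding (row
  normalized eigenvectors of the symmetric normalized Laplacian, the
  dimension chosen by the eigengap heuristic), followed by either k-means++
  with restarts or a diagonal Gaussian-mixture EM with hard assignment.

All clusterers drop singleton clusters and, for the non-overlapping ones,
produce pairwise-disjoint clusters. Randomized steps are reproducible from a
single integer seed (default 17).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

DEFAULT_SEED = 17

ALGORITHMS = ("mcl", "cmc", "spectral-kmeanspp", "spectral-em")


@dataclass
class Clustering:
    """A set of candidate complexes (protein sets).

    Singletons are never emitted. ``overlapping`` records whether the
    producing algorithm may assign a protein to several clusters; when it is
    False the clusters are pairwise disjoint. ``meta`` carries run
    diagnostics (e.g. convergence flags, dropped-singleton counts).
    """

    clusters: list[frozenset[str]]
    overlapping: bool
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(len(c) < 2 for c in self.clusters):
            raise ValueError("clusters must have >= 2 members")
        if not self.overlapping:
            seen: set[str] = set()
            for c in self.clusters:
                if seen & c:
                    raise ValueError("non-overlapping clustering has overlapping clusters")
                seen |= c

    def as_sets(self) -> list[frozenset[str]]:
        return list(self.clusters)


def _finalize_clusters(raw: list[set[str]], overlapping: bool, **meta) -> Clustering:
    kept = [frozenset(c) for c in raw if len(c) >= 2]
    n_singletons = len(raw) - len(kept)
    if n_singletons:
        logger.info("dropped %d singleton cluster(s)", n_singletons)
    kept.sort(key=lambda c: sorted(c))
    return Clustering(kept, overlapping, meta={"n_singletons_dropped": n_singletons, **meta})


# ---------------------------------------------------------------------------
# Markov clustering


@dataclass(frozen=True)
class MCLParams:
    """MCL controls. ``inflation`` > 1 sharpens cluster boundaries (higher ->
    finer clusters); ``self_loop_weight`` None means each node gets a loop
    equal to its maximum incident weight, which stabilizes the attractors."""

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iters: int = 100
    tol: float = 1e-6
    self_loop_weight: float | None = None

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion power must be >= 2")


def _column_normalize(m: np.ndarray) -> np.ndarray:
    col = m.sum(axis=0)
    col[col == 0] = 1.0
    return m / col


def mcl(graph: nx.Graph, params: MCLParams = MCLParams()) -> Clustering:
    """Markov clustering of a weighted graph.

    Builds the column-stochastic flow matrix from the edge weights plus
    self-loops, then alternates expansion (matrix power), inflation
    (entrywise power + column renormalization) and pruning of entries below
    ``prune_threshold`` until the matrix change falls below ``tol``. Clusters
    are the attractor systems of the limit matrix; a node attracted to
    several systems goes to the one receiving the largest incoming mass
    (ties to the lexicographically smallest cluster). Non-convergence within
    ``max_iters`` yields the current clustering with ``meta['converged']``
    False and a warning.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("mcl on an empty graph")
    nodes = sorted(graph.nodes())
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    if params.self_loop_weight is None:
        loops = a.max(axis=1)
        loops[loops == 0] = 1.0  # isolated nodes still need a stochastic column
    else:
        loops = np.full(len(nodes), params.self_loop_weight, dtype=float)
    np.fill_diagonal(a, loops)
    m = _column_normalize(a)
    converged = False
    for _ in range(params.max_iters):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = _column_normalize(m**params.inflation)
        m[m < params.prune_threshold] = 0.0
        m = _column_normalize(m)
        if np.abs(m - prev).max() < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iters; returning current state")
    return _attractor_clusters(m, nodes, converged)


def _attractor_clusters(m: np.ndarray, nodes: list[str], converged: bool) -> Clustering:
    n = len(nodes)
    attractors = [i for i in range(n) if m[i, i] > 0]
    if not attractors:  # degenerate non-converged state: treat nonzero rows as attractors
        attractors = [i for i in range(n) if m[i].any()]
    # attractor systems: connected components of the attractor-attractor support
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    for i, j in combinations(attractors, 2):
        if m[i, j] > 0 or m[j, i] > 0:
            sys_graph.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    systems.sort(key=lambda s: [nodes[i] for i in s])
    raw: list[set[str]] = [set() for _ in systems]
    for j in range(n):
        masses = [sum(m[i, j] for i in s) for s in systems]
        best = max(masses, default=0.0)
        if best <= 0:
            continue  # node with no attractor mass: left unclustered
        raw[masses.index(best)].add(nodes[j])  # index() takes the first = smallest system
    return _finalize_clusters(raw, overlapping=False, converged=converged, algorithm="mcl")


# ---------------------------------------------------------------------------
# Clustering on maximal cliques


@dataclass(frozen=True)
class CMCParams:
    """CMC controls: cliques below ``min_clique_size`` are ignored; a clique
    overlapping a kept cluster by at least ``overlap_threshold`` (as a
    fraction of the clique) is merged into it when their interconnectivity
    reaches ``merge_threshold``, and discarded otherwise."""

    min_clique_size: int = 2
    overlap_threshold: float = 0.5
    merge_threshold: float = 0.25

    def __post_init__(self) -> None:
        if self.min_clique_size < 2:
            raise ValueError("min_clique_size must be >= 2")
        for t in (self.overlap_threshold, self.merge_threshold):
            if not 0 < t <= 1:
                raise ValueError("thresholds must lie in (0, 1]")


def find_maximal_cliques(graph: nx.Graph, min_size: int = 2) -> list[frozenset[str]]:
    """All maximal cliques with at least ``min_size`` nodes.

    Adjacency alone defines cliques; weights play no role here. Backed by
    networkx's Bron-Kerbosch enumeration.
    """
    return [frozenset(c) for c in nx.find_cliques(graph) if len(c) >= min_size]


def _edge_weight(graph: nx.Graph, u: str, v: str) -> float:
    return graph[u][v].get("weight", 1.0) if graph.has_edge(u, v) else 0.0


def weighted_density(graph: nx.Graph, cluster: frozenset[str] | set[str]) -> float:
    """Sum of internal edge weights over the number of possible pairs."""
    members = sorted(cluster)
    n = len(members)
    if n < 2:
        return 0.0
    total = sum(_edge_weight(graph, u, v) for u, v in combinations(members, 2))
    return total / (n * (n - 1) / 2)


def interconnectivity(graph: nx.Graph, cluster: set[str], clique: set[str]) -> float:
    """Mean weight of the edges between ``clique - cluster`` and ``cluster``.

    Normalized by the number of possible cross pairs, so a fully connected
    unit-weight boundary scores 1. Zero when the clique is contained in the
    cluster.
    """
    outside = clique - cluster
    if not outside or not cluster:
        return 0.0
    total = sum(_edge_weight(graph, x, y) for x in outside for y in cluster)
    return total / (len(outside) * len(cluster))


def cmc(
    graph: nx.Graph,
    params: CMCParams = CMCParams(),
    cliques: list[frozenset[str]] | None = None,
) -> Clustering:
    """Clustering on maximal cliques over a weighted graph.

    Maximal cliques are ranked by weighted density (ties broken by size then
    lexicographically, for determinism). Walking down the ranking, a clique
    whose overlap fraction with an already-kept cluster reaches
    ``overlap_threshold`` is either merged into that cluster (if the
    clique-to-cluster interconnectivity reaches ``merge_threshold``) or
    discarded as redundant; otherwise it founds a new cluster. The output may
    assign proteins to several clusters.

    ``cliques`` overrides the enumeration (e.g. to re-rank an externally
    supplied candidate list).
    """
    if cliques is None:
        cliques = find_maximal_cliques(graph, params.min_clique_size)
    ranked = sorted(
        cliques,
        key=lambda c: (-weighted_density(graph, c), -len(c), sorted(c)),
    )
    kept: list[set[str]] = []
    for clique in ranked:
        cset = set(clique)
        placed = False
        for cluster in kept:
            overlap = len(cluster & cset) / len(cset)
            if overlap < params.overlap_threshold:
                continue
            if cset - cluster and (
                interconnectivity(graph, cluster, cset) >= params.merge_threshold
            ):
                cluster |= cset
            # else: discarded (fully contained, or too weakly interconnected)
            placed = True
            break
        if not placed:
            kept.append(cset)
    return _finalize_clusters(kept, overlapping=True, algorithm="cmc")


# ---------------------------------------------------------------------------
# Spectral clustering (Ng-Jordan-Weiss embedding + kmeans++ or EM)


@dataclass(frozen=True)
class SpectralParams:
    """Spectral pipeline controls. ``k_max`` caps the eigengap search;
    ``restarts`` independent k-means++ runs are scored by within-cluster sum
    of squares and the best kept. ``variant`` picks the point clusterer."""

    k_max: int = 200
    restarts: int = 30
    seed: int = DEFAULT_SEED
    variant: str = "kmeanspp"

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.variant not in ("kmeanspp", "em"):
            raise ValueError("variant must be 'kmeanspp' or 'em'")


def eigengap_k(eigenvalues: np.ndarray, k_max: int = 200) -> int:
    """Number of clusters by the eigengap heuristic.

    For ascending Laplacian eigenvalues, returns the index i (1-based)
    maximizing ``lambda_{i+1} - lambda_i`` over ``1 <= i < min(k_max + 1,
    len)``; ties go to the smallest i. A graph with c well-separated clusters
    has c near-zero eigenvalues followed by a jump, so the largest gap sits
    at i = c.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size < 2:
        raise ValueError("need at least two eigenvalues")
    gaps = np.diff(lam)[: min(k_max, lam.size - 1)]
    return int(np.argmax(gaps)) + 1


def spectral_embed(
    graph: nx.Graph, k_max: int = 200
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Ng-Jordan-Weiss embedding of the weighted graph.

    Forms the symmetric normalized Laplacian ``L = I - D^{-1/2} W D^{-1/2}``
    from the weight matrix, takes the k eigenvectors of smallest eigenvalue
    with k chosen by :func:`eigengap_k`, and normalizes each embedding row to
    unit length (all-zero rows, from isolated nodes, are left at zero).
    Returns ``(points, eigenvalues, nodes)`` with eigenvalues ascending and
    rows of ``points`` ordered like ``nodes``.
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("spectral embedding needs at least 3 nodes")
    nodes = sorted(graph.nodes())
    w = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    deg = w.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    pos = deg > 0
    inv_sqrt[pos] = deg[pos] ** -0.5
    lap = np.eye(n) - (inv_sqrt[:, None] * w * inv_sqrt[None, :])
    eigenvalues, eigenvectors = scipy.linalg.eigh(lap)
    k = eigengap_k(eigenvalues, k_max=min(k_max, n - 1))
    points = eigenvectors[:, :k]
    norms = np.linalg.norm(points, axis=1)
    keep = norms > 0
    points = points.copy()
    points[keep] /= norms[keep, None]
    return points, eigenvalues, nodes


def kmeans_pp(
    points: np.ndarray,
    k: int,
    restarts: int = 30,
    seed: int = DEFAULT_SEED,
    return_sses: bool = False,
):
    """k-means with k-means++ seeding, best of ``restarts`` independent runs.

    Each restart seeds its first center uniformly and subsequent centers with
    probability proportional to the squared distance to the nearest chosen
    center, then runs Lloyd iterations to convergence. The labeling with the
    minimum within-cluster sum of squared errors wins. Deterministic given
    ``seed``. With ``return_sses`` the per-restart SSE list is returned too.
    """
    points = np.asarray(points, dtype=float)
    n_distinct = np.unique(points, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    rng = np.random.default_rng(seed)
    best_labels, best_sse, sses = None, np.inf, []
    for _ in range(restarts):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(points)
        sses.append(float(km.inertia_))
        if km.inertia_ < best_sse:
            best_sse = float(km.inertia_)
            best_labels = km.labels_.copy()
    if return_sses:
        return best_labels, best_sse, sses
    return best_labels, best_sse


def em_cluster(points: np.ndarray, k: int, seed: int = DEFAULT_SEED) -> np.ndarray:
    """Diagonal-covariance Gaussian-mixture EM with hard assignment.

    Fits a k-component mixture (k-means++ initialization, variances floored
    at 1e-6 to survive components of identical points) and assigns each point
    to its maximum-posterior component. Deterministic given ``seed``.
    """
    points = np.asarray(points, dtype=float)
    n_distinct = np.unique(points, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        init_params="k-means++",
        reg_covar=1e-6,
        random_state=seed,
    ).fit(points)
    if not gm.converged_:
        warnings.warn("EM did not fully converge; using current parameters")
    return gm.predict(points)


def spectral_cluster(graph: nx.Graph, params: SpectralParams = SpectralParams()) -> Clustering:
    """Spectral embedding followed by point clustering.

    The cluster count equals the embedding dimension chosen by the eigengap
    heuristic. Nodes are grouped by their point labels; singleton groups are
    dropped.
    """
    points, _, nodes = spectral_embed(graph, k_max=params.k_max)
    k = points.shape[1]
    if params.variant == "kmeanspp":
        labels, _ = kmeans_pp(points, k, restarts=params.restarts, seed=params.seed)
    else:
        labels = em_cluster(points, k, seed=params.seed)
    raw: dict[int, set[str]] = {}
    for node, lab in zip(nodes, labels):
        raw.setdefault(int(lab), set()).add(node)
    return _finalize_clusters(
        list(raw.values()), overlapping=False, algorithm=f"spectral-{params.variant}", k=k
    )


# ---------------------------------------------------------------------------
# dispatcher


def cluster_graph(
    graph: nx.Graph,
    algorithm: str,
    mcl_params: MCLParams = MCLParams(),
    cmc_params: CMCParams = CMCParams(),
    spectral_params: SpectralParams = SpectralParams(),
) -> Clustering:
    """Run one named clustering algorithm on a (weighted) graph."""
    if algorithm == "mcl":
        return mcl(graph, mcl_params)
    if algorithm == "cmc":
        return cmc(graph, cmc_params)
    if algorithm in ("spectral-kmeanspp", "spectral-em"):
        variant = algorithm.split("-", 1)[1]
        sp = SpectralParams(
            k_max=spectral_params.k_max,
            restarts=spectral_params.restarts,
            seed=spectral_params.seed,
            variant=variant,
        )
        return spectral_cluster(graph, sp)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
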