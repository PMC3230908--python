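"""Edge-confidence weighting schemes for protein-interaction graphs.

Reported interactomes are noisy: high-throughput screens (yeast-two-hybrid,
affinity purification / mass spectrometry) cover much of the proteome but
introduce many false-positive edges, while small-scale experiments are
reliable but sparse. Each scheme here maps an edge to a confidence weight in
[0, 1] expressing how likely the interaction is a physiological one.

Two families are implemented:

* **evidence-based** schemes, computed from the aggregated detection evidence
  of an edge — the number of reporting experiments Ne, the plurality of each
  experiment (how many interactions it reports in total; a proxy for
  throughput), and the set of detection-method categories:

  - :func:`mv_weight` — plurality-discounted multi-experiment score,
    ``w = Ne**alpha / (Ne**alpha + A(pluralities) - 1)``;
  - :func:`simple_weight` — a step scheme (0.2 / 0.9 / [0.7, 1.0]) driven by
    a high-throughput plurality cutoff;
  - :func:`etw_weight` — experiment-type weighting by the count of distinct
    detection-method categories (0.2 / 0.6 / 1.0);

* **topology-based** schemes, computed from the graph alone:

  - :func:`cd_distance_weight` — one minus the Czekanowski-Dice distance of
    the closed neighborhoods;
  - :func:`adjust_cd` — the iterated, degree-penalized neighborhood-overlap
    reliability score, which can also propose edges absent from the input.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

from .io_formats import Evidence, Pair

EVIDENCE_SCHEMES = ("mv", "simple", "etw")
TOPOLOGY_SCHEMES = ("cd", "adjustcd")
SCHEMES = EVIDENCE_SCHEMES + TOPOLOGY_SCHEMES


@dataclass(frozen=True)
class MVParams:
    """Parameters of the MV plurality-discounted score.

    ``alpha`` boosts the confidence of edges reported by more than one
    experiment; it has no effect at Ne = 1 (since 1**alpha = 1). The default
    alpha = 2 is the empirically best-performing value on yeast data.
    ``plurality_aggregator`` chooses how the edge's experiment pluralities
    collapse to a single discount term: ``min`` (default — a single
    low-plurality experiment is decisive) or ``mean``.
    """

    alpha: float = 2.0
    plurality_aggregator: str = "min"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.plurality_aggregator not in ("min", "mean"):
            raise ValueError("plurality_aggregator must be 'min' or 'mean'")


@dataclass(frozen=True)
class SimpleParams:
    """Parameters of the naive plurality step scheme.

    An edge seen by one experiment scores 0.2 if that experiment's plurality
    is at or above ``high_plurality_cutoff`` (high-throughput, noise-prone)
    and 0.9 otherwise. Multi-experiment edges land in
    ``multi_experiment_range``, decreasing with their aggregated plurality.
    """

    high_plurality_cutoff: int = 100
    multi_experiment_range: tuple[float, float] = (0.7, 1.0)
    plurality_aggregator: str = "min"

    def __post_init__(self) -> None:
        if self.high_plurality_cutoff < 2:
            raise ValueError("high_plurality_cutoff must be >= 2")
        lo, hi = self.multi_experiment_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("multi_experiment_range must be an increasing pair in [0, 1]")


@dataclass(frozen=True)
class AdjustCDParams:
    """Parameters of the iterated Czekanowski-Dice reliability score.

    ``iterations`` = 1 gives the closed-form degree-penalized overlap score;
    further iterations replace neighbor-set sizes by sums of the previous
    round's weights, letting reliability propagate through the topology.
    ``include_self`` controls whether a node belongs to its own neighbor set
    (the open-neighborhood convention, ``False``, is the default).
    """

    iterations: int = 2
    include_self: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _aggregate_plurality(ev: Evidence, how: str) -> float:
    if how == "min":
        return float(min(ev.pluralities))
    if how == "mean":
        return float(np.mean(ev.pluralities))
    raise ValueError(f"unknown plurality aggregator {how!r}")


def mv_weight(ev: Evidence, params: MVParams = MVParams()) -> float:
    """Confidence of an edge under the MV plurality-discounted score.

    ``w = Ne**alpha / (Ne**alpha + A(pluralities) - 1)`` where Ne is the
    number of reporting experiments and A the plurality aggregator. The score
    is strictly positive, at most 1, increasing in Ne, decreasing in the
    aggregated plurality, and equals 1 exactly when a single-plurality
    experiment dominates (A = 1). At Ne = 1 the result is independent of
    alpha, so the boost only discriminates among multi-experiment edges.
    """
    ne = ev.n_experiments
    if ne == 0:
        raise ValueError("edge without evidence")
    boosted = float(ne) ** params.alpha
    return boosted / (boosted + _aggregate_plurality(ev, params.plurality_aggregator) - 1.0)


def simple_weight(ev: Evidence, params: SimpleParams = SimpleParams()) -> float:
    """Confidence of an edge under the naive plurality step scheme.

    Single-experiment edges get 0.2 (high-throughput reporter) or 0.9
    (small-scale reporter). Multi-experiment edges — statistically the
    strongest sign of a true interaction — score within
    ``multi_experiment_range``, decreasing log-linearly in the aggregated
    plurality: A = 1 maps to the top of the range and A at or above the
    cutoff to the bottom.
    """
    ne = ev.n_experiments
    if ne == 0:
        raise ValueError("edge without evidence")
    agg = _aggregate_plurality(ev, params.plurality_aggregator)
    if ne == 1:
        return 0.2 if agg >= params.high_plurality_cutoff else 0.9
    lo, hi = params.multi_experiment_range
    span = np.log(agg) / np.log(params.high_plurality_cutoff)
    return float(hi - (hi - lo) * min(1.0, max(0.0, span)))


def etw_weight(ev: Evidence) -> float:
    """Experiment-type weighting by count of distinct detection-method categories.

    Each detection technology has characteristic biases (yeast-two-hybrid
    favors nuclear interactions, purified-complex methods a different
    subset), so agreement across method categories is strong evidence that an
    edge is real: one category scores 0.2, two score 0.6, and three or more
    score 1.0.
    """
    k = len(ev.method_types)
    if k == 0:
        raise ValueError("edge without a detection-method category")
    if k == 1:
        return 0.2
    if k == 2:
        return 0.6
    return 1.0


def cd_distance_weight(graph: nx.Graph, edge: Pair) -> float:
    """One minus the Czekanowski-Dice distance of the closed neighborhoods.

    With ``Int(x) = {x} | neighbors(x)``, the distance is
    ``(|Int(u)| + |Int(v)| - 2 |Int(u) & Int(v)|) / (|Int(u)| + |Int(v)|)``;
    the weight is its complement, i.e. the Dice coefficient of the closed
    neighborhoods. Symmetric in the endpoints; 1 for an isolated dyad or any
    pair of nodes with identical closed neighborhoods.
    """
    u, v = edge
    if not graph.has_edge(u, v):
        raise ValueError(f"edge {edge!r} not in graph")
    iu = set(graph[u]) | {u}
    iv = set(graph[v]) | {v}
    total = len(iu) + len(iv)
    return 1.0 - (total - 2 * len(iu & iv)) / total


def adjust_cd(
    graph: nx.Graph,
    params: AdjustCDParams = AdjustCDParams(),
    include_predicted: bool = False,
) -> nx.Graph:
    """Iterated degree-penalized neighborhood-overlap reliability weights.

    The first iteration scores every node pair as
    ``w1(u, v) = 2 |N_u & N_v| / (|N_u| + lam_u + |N_v| + lam_v)`` with the
    degree penalty ``lam_x = max(0, n_avg - |N_x|)``, where ``n_avg`` is the
    mean neighbor-set size; the penalty damps scores involving poorly
    characterized (low-degree) proteins. Iteration k > 1 replaces set sizes
    by sums of the previous round's weights over the same (original) neighbor
    sets, with the penalties recomputed from weighted degrees.

    Because the score is defined on any pair sharing a neighbor, it can
    propose interactions absent from the input graph; those are emitted with
    an ``predicted=True`` edge attribute only when ``include_predicted`` is
    set, otherwise the output is restricted to the input edge set. Pairs with
    zero weight are omitted either way.
    """
    n = graph.number_of_nodes()
    if n == 0:
        raise ValueError("adjust_cd on an empty graph")
    nodes = sorted(graph.nodes())
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    if params.include_self:
        np.fill_diagonal(adj, 1.0)
    w = adj.copy()
    for _ in range(params.iterations):
        m = adj * w  # previous weights restricted to the (fixed) neighbor sets
        num = m @ adj.T + adj @ m.T
        s = m.sum(axis=1)
        b = np.maximum(s, s.mean())  # s_x + max(0, avg - s_x)
        den = b[:, None] + b[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(den > 0, num / den, 0.0)
        np.clip(w, 0.0, 1.0, out=w)
    out = nx.Graph()
    out.add_nodes_from(nodes)
    iu, iv = np.nonzero(np.triu(w, k=1))
    for i, j in zip(iu.tolist(), iv.tolist()):
        u, v = nodes[i], nodes[j]
        original = graph.has_edge(u, v)
        if original:
            out.add_edge(u, v, weight=float(w[i, j]))
        elif include_predicted:
            out.add_edge(u, v, weight=float(w[i, j]), predicted=True)
    return out


def weight_graph(
    graph: nx.Graph,
    scheme: str,
    evidence: Mapping[Pair, Evidence] | None = None,
    mv_params: MVParams = MVParams(),
    simple_params: SimpleParams = SimpleParams(),
    adjustcd_params: AdjustCDParams = AdjustCDParams(),
    include_predicted: bool = False,
) -> nx.Graph:
    """Apply one named weighting scheme to a whole graph.

    Evidence-based schemes (``mv``, ``simple``, ``etw``) require an evidence
    mapping covering every edge; topology schemes (``cd``, ``adjustcd``) use
    the graph alone. Returns a new weighted graph over the same nodes.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}; choose from {SCHEMES}")
    if scheme == "adjustcd":
        return adjust_cd(graph, adjustcd_params, include_predicted=include_predicted)
    out = nx.Graph()
    out.add_nodes_from(graph.nodes())
    for u, v in graph.edges():
        pair = (u, v) if u <= v else (v, u)
        if scheme == "cd":
            w = cd_distance_weight(graph, pair)
        else:
            if evidence is None or pair not in evidence:
                raise ValueError(f"no evidence for edge {pair!r}")
            ev = evidence[pair]
            if scheme == "mv":
                w = mv_weight(ev, mv_params)
            elif scheme == "simple":
                w = simple_weight(ev, simple_params)
            else:
                w = etw_weight(ev)
        out.add_edge(u, v, weight=w)
    return out
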