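"""Scoring predicted clusterings against a reference complex catalog.

The metrics follow the standard complex-prediction evaluation framework
built on the complex-by-cluster overlap (contingency) matrix
``T[i, j] = |complex_i & cluster_j|``:

* **Sensitivity** ``Sn = sum_i max_j T_ij / sum_i N_i`` — the complex-weighted
  fraction of each reference complex recovered by its best-covering cluster;
  high Sn means every protein of a confirmed complex appears in a matching
  predicted one.
* **Positive predictive value** ``PPV = sum_j max_i T_ij / sum_j T_.j`` — the
  cluster-weighted purity of the predictions; high PPV means predicted
  clusters carry no proteins foreign to their best-matching complex.
* **Accuracy** — the geometric mean ``sqrt(Sn * PPV)``.
* **Prediction rate** — the fraction of predicted clusters matching some
  reference complex under the neighborhood-affinity overlap score
  ``omega(P, C) = |P & C|**2 / (|P| * |C|)``.

Predicted clusters sharing no protein with the catalog would not appear in
the raw PPV denominator at all; by default they are charged with weight
``|cluster|`` and zero numerator, so junk clusters cost precision
(``junk_clusters='ignore'`` disables this for sensitivity analyses).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .clustering import Clustering


@dataclass
class ContingencyMatrix:
    """Overlap counts between reference complexes (rows) and clusters (columns)."""

    table: np.ndarray  # shape (n_complexes, n_clusters), integer overlaps
    complex_ids: list[str]
    complex_sizes: np.ndarray  # N_i, full reference complex sizes
    cluster_sizes: np.ndarray  # |cluster_j|

    @property
    def column_sums(self) -> np.ndarray:
        return self.table.sum(axis=0)


@dataclass
class EvalReport:
    sensitivity: float
    ppv: float
    accuracy: float
    prediction_rate: float
    n_predicted: int
    n_matched: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "accuracy": self.accuracy,
            "prediction_rate": self.prediction_rate,
            "n_predicted": self.n_predicted,
            "n_matched": self.n_matched,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.as_dict(), indent=indent)

    def as_table(self) -> str:
        rows = [
            ("sensitivity", f"{self.sensitivity:.4f}"),
            ("ppv", f"{self.ppv:.4f}"),
            ("accuracy", f"{self.accuracy:.4f}"),
            ("prediction_rate", f"{self.prediction_rate:.4f}"),
            ("n_predicted", str(self.n_predicted)),
            ("n_matched", str(self.n_matched)),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def _cluster_list(predicted: Clustering | Iterable[Iterable[str]]) -> list[frozenset[str]]:
    if isinstance(predicted, Clustering):
        clusters = predicted.as_sets()
    else:
        clusters = [frozenset(c) for c in predicted]
    clusters = [c for c in clusters if len(c) >= 2]
    if not clusters:
        raise ValueError("no predicted clusters of size >= 2 to evaluate")
    return clusters


def _catalog_list(reference: Mapping[str, Iterable[str]]) -> tuple[list[str], list[frozenset[str]]]:
    items = [(cid, frozenset(m)) for cid, m in sorted(reference.items()) if len(set(m)) >= 2]
    if not items:
        raise ValueError("reference catalog has no complexes of size >= 2")
    return [cid for cid, _ in items], [m for _, m in items]


def contingency(
    predicted: Clustering | Iterable[Iterable[str]],
    reference: Mapping[str, Iterable[str]],
) -> ContingencyMatrix:
    """Complex-by-cluster overlap matrix; memberships are taken as-is."""
    clusters = _cluster_list(predicted)
    ids, complexes = _catalog_list(reference)
    table = np.zeros((len(complexes), len(clusters)), dtype=int)
    for i, comp in enumerate(complexes):
        for j, clu in enumerate(clusters):
            table[i, j] = len(comp & clu)
    return ContingencyMatrix(
        table=table,
        complex_ids=ids,
        complex_sizes=np.array([len(c) for c in complexes]),
        cluster_sizes=np.array([len(c) for c in clusters]),
    )


def sensitivity(cm: ContingencyMatrix) -> float:
    """Complex-weighted coverage: Sn = sum_i max_j T_ij / sum_i N_i."""
    return float(cm.table.max(axis=1).sum() / cm.complex_sizes.sum())


def ppv(cm: ContingencyMatrix, junk_clusters: str = "penalize") -> float:
    """Cluster-weighted purity.

    ``PPV = sum_j max_i T_ij / sum_j T_.j`` where clusters with an all-zero
    column either contribute their size to the denominator
    (``junk_clusters='penalize'``, the default) or are skipped
    (``'ignore'``).
    """
    if junk_clusters not in ("penalize", "ignore"):
        raise ValueError("junk_clusters must be 'penalize' or 'ignore'")
    col = cm.column_sums
    numer = cm.table.max(axis=0).astype(float)
    denom = col.astype(float)
    if junk_clusters == "penalize":
        empty = col == 0
        denom = np.where(empty, cm.cluster_sizes, denom)
    else:
        keep = col > 0
        numer, denom = numer[keep], denom[keep]
    total = denom.sum()
    if total == 0:
        return 0.0
    return float(numer.sum() / total)


def accuracy(sn: float, ppv_value: float) -> float:
    """Geometric mean of sensitivity and positive predictive value."""
    return math.sqrt(sn * ppv_value)


def overlap_score(cluster: frozenset[str], complex_: frozenset[str]) -> float:
    """Neighborhood-affinity overlap: |P & C|^2 / (|P| * |C|)."""
    inter = len(cluster & complex_)
    return inter * inter / (len(cluster) * len(complex_))


def prediction_rate(
    predicted: Clustering | Iterable[Iterable[str]],
    reference: Mapping[str, Iterable[str]],
    omega_threshold: float = 0.2,
) -> float:
    """Fraction of predicted clusters matching some reference complex.

    A cluster P matches complex C when ``overlap_score(P, C) >=
    omega_threshold`` (default 0.2, the conventional matching criterion).
    """
    clusters = _cluster_list(predicted)
    _, complexes = _catalog_list(reference)
    matched = sum(
        1
        for clu in clusters
        if any(overlap_score(clu, comp) >= omega_threshold for comp in complexes)
    )
    return matched / len(clusters)


def evaluate_all(
    predicted: Clustering | Iterable[Iterable[str]],
    reference: Mapping[str, Iterable[str]],
    omega_threshold: float = 0.2,
    junk_clusters: str = "penalize",
) -> EvalReport:
    """Full report: sensitivity, PPV, accuracy and prediction rate."""
    clusters = _cluster_list(predicted)
    cm = contingency(clusters, reference)
    sn = sensitivity(cm)
    pv = ppv(cm, junk_clusters=junk_clusters)
    _, complexes = _catalog_list(reference)
    n_matched = sum(
        1
        for clu in clusters
        if any(overlap_score(clu, comp) >= omega_threshold for comp in complexes)
    )
    return EvalReport(
        sensitivity=sn,
        ppv=pv,
        accuracy=accuracy(sn, pv),
        prediction_rate=n_matched / len(clusters),
        n_predicted=len(clusters),
        n_matched=n_matched,
    )
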