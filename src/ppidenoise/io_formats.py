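"""Readers, writers and evidence aggregation for protein-interaction data.

Three plain-text formats are supported, all UTF-8 and tab-separated, with
``#`` marking comment/header lines:

* **evidence files** (MITAB-like): one interaction-detection record per line,
  with configurable column positions for the two interactors, the experiment
  identifier and the detection-method category;
* **weighted edge lists**: ``protein_a<TAB>protein_b<TAB>weight``;
* **complex catalogs** (MIPS-style): ``complex_id<TAB>member_id``.

Raw records are aggregated per unordered protein pair into :class:`Evidence`,
the input of the evidence-based weighting schemes. The *plurality* of an
experiment is the number of distinct interactions it reports across the whole
dataset; high plurality marks high-throughput (and typically noisier)
detection experiments.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

import networkx as nx

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


class FormatError(ValueError):
    """A line of an input file violates the expected format."""


@dataclass(frozen=True)
class ColumnConfig:
    """Zero-based column positions of the four evidence fields.

    ``plurality`` may point at a column carrying a precomputed experiment
    plurality (as exported from aggregated interaction databases); when it is
    None, pluralities are recomputed from the record set itself.
    """

    protein_a: int = 0
    protein_b: int = 1
    experiment_id: int = 2
    method_type: int = 3
    plurality: int | None = None

    def required_columns(self) -> int:
        cols = [self.protein_a, self.protein_b, self.experiment_id, self.method_type]
        if self.plurality is not None:
            cols.append(self.plurality)
        return max(cols) + 1


@dataclass(frozen=True)
class InteractionRecord:
    """One evidence line: a protein pair observed in one detection experiment."""

    protein_a: str
    protein_b: str
    experiment_id: str
    method_type: str
    plurality: int | None = None

    @property
    def pair(self) -> Pair:
        """The unordered protein pair, canonically sorted."""
        a, b = self.protein_a, self.protein_b
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class Evidence:
    """Aggregated evidence for one unordered protein pair.

    ``pluralities`` holds one entry per distinct reporting experiment, so the
    number of experiments Ne equals ``len(pluralities)``.
    """

    pluralities: tuple[int, ...]
    method_types: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.pluralities) == 0:
            raise ValueError("evidence must carry at least one experiment")
        if any(p < 1 for p in self.pluralities):
            raise ValueError("experiment pluralities must be >= 1")
        if not 1 <= len(self.method_types) <= len(self.pluralities):
            raise ValueError(
                "method-type count must lie between 1 and the number of experiments"
            )

    @property
    def n_experiments(self) -> int:
        return len(self.pluralities)


@dataclass
class ParseResult:
    """Parsed records plus the counts of lines that were dropped."""

    records: list[InteractionRecord]
    n_malformed: int = 0
    n_self_interactions: int = 0


def parse_interaction_records(
    stream: Iterable[str],
    columns: ColumnConfig = ColumnConfig(),
    id_mapping: Mapping[str, str] | None = None,
) -> ParseResult:
    """Parse an evidence file into interaction records, in file order.

    Identifiers are canonicalized by whitespace trimming only; an optional
    ``id_mapping`` (e.g. ORF -> UniProtKB) is applied as a pre-pass.
    Self-interactions are dropped (the downstream clustering formulations
    assume simple graphs) and malformed lines are skipped; both are counted
    and logged rather than raised.
    """
    need = columns.required_columns()
    result = ParseResult(records=[])
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < need:
            logger.warning("line %d: expected >= %d columns, got %d", lineno, need, len(fields))
            result.n_malformed += 1
            continue
        a = fields[columns.protein_a].strip()
        b = fields[columns.protein_b].strip()
        exp = fields[columns.experiment_id].strip()
        method = fields[columns.method_type].strip()
        if not (a and b and exp and method):
            logger.warning("line %d: empty field", lineno)
            result.n_malformed += 1
            continue
        plurality: int | None = None
        if columns.plurality is not None:
            try:
                plurality = int(fields[columns.plurality])
                if plurality < 1:
                    raise ValueError
            except ValueError:
                logger.warning("line %d: bad plurality value %r", lineno, fields[columns.plurality])
                result.n_malformed += 1
                continue
        if id_mapping is not None:
            a = id_mapping.get(a, a)
            b = id_mapping.get(b, b)
        if a == b:
            result.n_self_interactions += 1
            continue
        result.records.append(InteractionRecord(a, b, exp, method, plurality))
    if result.n_self_interactions:
        logger.info("dropped %d self-interaction record(s)", result.n_self_interactions)
    if result.n_malformed:
        logger.info("skipped %d malformed line(s)", result.n_malformed)
    return result


def aggregate_evidence(records: Iterable[InteractionRecord]) -> dict[Pair, Evidence]:
    """Collapse raw records into per-pair evidence.

    The plurality of experiment *e* is the number of distinct unordered pairs
    with at least one record from *e*, computed over the full input (unless
    records carry precomputed pluralities, in which case those are trusted).
    Duplicate (pair, experiment) records count once.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot aggregate an empty record set")
    pairs_of_exp: dict[str, set[Pair]] = defaultdict(set)
    exps_of_pair: dict[Pair, set[str]] = defaultdict(set)
    methods_of_pair: dict[Pair, set[str]] = defaultdict(set)
    given_plurality: dict[str, int] = {}
    for rec in records:
        pair = rec.pair
        pairs_of_exp[rec.experiment_id].add(pair)
        exps_of_pair[pair].add(rec.experiment_id)
        methods_of_pair[pair].add(rec.method_type)
        if rec.plurality is not None:
            prev = given_plurality.get(rec.experiment_id)
            given_plurality[rec.experiment_id] = (
                rec.plurality if prev is None else max(prev, rec.plurality)
            )

    def plurality(exp: str) -> int:
        if exp in given_plurality:
            return given_plurality[exp]
        return len(pairs_of_exp[exp])

    out: dict[Pair, Evidence] = {}
    for pair, exps in exps_of_pair.items():
        plur = tuple(sorted(plurality(e) for e in exps))
        out[pair] = Evidence(pluralities=plur, method_types=frozenset(methods_of_pair[pair]))
    return out


def evidence_graph(evidence: Mapping[Pair, Evidence]) -> nx.Graph:
    """The unweighted simple graph spanned by the evidenced pairs."""
    g = nx.Graph()
    g.add_edges_from(evidence.keys())
    return g


def read_complex_catalog(stream: Iterable[str]) -> dict[str, frozenset[str]]:
    """Read a MIPS-style catalog of reference complexes.

    Complexes with fewer than two members are dropped with a warning (a
    one-protein "complex" cannot be matched by any clustering); duplicate
    membership lines are idempotent. An empty resulting catalog is an error,
    because evaluating against it would be meaningless.
    """
    members: dict[str, set[str]] = defaultdict(set)
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise FormatError(f"line {lineno}: expected 'complex_id<TAB>member_id'")
        members[fields[0].strip()].add(fields[1].strip())
    catalog = {}
    for cid, mem in members.items():
        if len(mem) < 2:
            logger.warning("complex %s has < 2 members; dropped", cid)
            continue
        catalog[cid] = frozenset(mem)
    if not catalog:
        raise FormatError("complex catalog is empty after filtering")
    return catalog


def write_complex_catalog(catalog: Mapping[str, Iterable[str]], stream: TextIO) -> None:
    for cid in sorted(catalog):
        for member in sorted(catalog[cid]):
            stream.write(f"{cid}\t{member}\n")


def write_weighted_edges(graph: nx.Graph, stream: TextIO) -> None:
    """Write ``a<TAB>b<TAB>weight`` lines, weights to 6 decimals.

    Edges without a ``weight`` attribute are written with weight 1.
    """
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges()):
        w = graph[u][v].get("weight", 1.0)
        stream.write(f"{u}\t{v}\t{w:.6f}\n")


def read_weighted_edges(stream: Iterable[str]) -> nx.Graph:
    """Read a weighted edge list; weights must lie in [0, 1]."""
    g = nx.Graph()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected 'a<TAB>b<TAB>weight'")
        a, b = fields[0].strip(), fields[1].strip()
        try:
            w = float(fields[2])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: weight {fields[2]!r} is not a number") from exc
        if not 0.0 <= w <= 1.0:
            raise FormatError(f"line {lineno}: weight {w} outside [0, 1]")
        if a == b:
            logger.warning("line %d: self-loop dropped", lineno)
            continue
        g.add_edge(a, b, weight=w)
    return g


def write_interaction_records(records: Iterable[InteractionRecord], stream: TextIO) -> None:
    """Write evidence records in the default column layout."""
    stream.write("#protein_a\tprotein_b\texperiment_id\tmethod_type\n")
    for rec in records:
        stream.write(f"{rec.protein_a}\t{rec.protein_b}\t{rec.experiment_id}\t{rec.method_type}\n")


def write_clusters(clusters: Iterable[Iterable[str]], stream: TextIO) -> None:
    """One line per cluster: ``cluster_id<TAB>member<TAB>member...``."""
    for i, cluster in enumerate(clusters, start=1):
        stream.write("K%d\t%s\n" % (i, "\t".join(sorted(cluster))))


def read_clusters(stream: Iterable[str]) -> list[frozenset[str]]:
    clusters = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f for f in line.split("\t") if f.strip()]
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: cluster line needs an id and >= 1 member")
        clusters.append(frozenset(f.strip() for f in fields[1:]))
    return clusters


def read_id_mapping(stream: Iterable[str]) -> dict[str, str]:
    """Two-column ``from<TAB>to`` identifier mapping (e.g. ORF -> UniProtKB)."""
    mapping = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: expected 'from<TAB>to'")
        mapping[fields[0].strip()] = fields[1].strip()
    return mapping
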