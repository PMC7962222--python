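"""Core data model: graphs with uniquely-labeled vertices, edge ordering, and I/O.

A collection of undirected graphs over a shared, uniquely-labeled vertex set
is represented as a single *edge-attributed summary graph*: the union of all
edges, with each edge carrying the set of member graphs that contain it.
Because vertex labels are unique, a subgraph is identified by its edgeset and
no isomorphism machinery is needed anywhere downstream.

Determinism conventions (they fix the shape of the search tree and make runs
reproducible):

* vertex indices are assigned by ascending lexicographic label order;
* edge ids are 1..|E|, assigned by ascending lexicographic (u, v) order, so
  comparing ids realizes the total edge order;
* graph indices are 1-based in all I/O.
"""

from __future__ import annotations

import logging
import math
import os
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "VertexTable",
    "Edge",
    "GraphSet",
    "SingleGraph",
    "EdgeAttributedDataset",
    "compare_edges",
    "edge_distance",
    "edge_neighborhood",
    "build_summary_graph",
    "load_dataset",
    "write_dataset",
    "load_single_graph",
    "build_coexpression_network",
]


class DataError(ValueError):
    """Raised for malformed input files or inconsistent graph data."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


class VertexTable:
    """Bijection between vertex labels and 0-based integer indices.

    Indices follow ascending lexicographic order of the labels, so the same
    label set always produces the same table.
    """

    __slots__ = ("labels", "index_of")

    def __init__(self, labels: Iterable[str]):
        labels = list(labels)
        if len(set(labels)) != len(labels):
            raise DataError("vertex labels must be unique")
        self.labels: list[str] = sorted(labels)
        self.index_of: dict[str, int] = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return isinstance(other, VertexTable) and self.labels == other.labels

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"VertexTable({len(self)} vertices)"


@dataclass(frozen=True, order=False)
class Edge:
    """An undirected edge (u, v) with u < v and a 1-based id.

    Ids are assigned in ascending lexicographic (u, v) order, so ``id``
    comparison realizes the total edge order: (i, j) precedes (k, l) iff
    i < k, or i = k and j <= l.
    """

    id: int
    u: int
    v: int

    def __post_init__(self):
        if self.u >= self.v:
            raise DataError(f"edge endpoints must satisfy u < v, got ({self.u}, {self.v})")

    def endpoints(self) -> tuple[int, int]:
        return (self.u, self.v)

    def __lt__(self, other: "Edge") -> bool:
        return (self.u, self.v) < (other.u, other.v)


def compare_edges(e1: Edge, e2: Edge) -> int:
    """Total edge order: -1, 0 or 1 as e1 precedes, equals or follows e2."""
    a, b = e1.endpoints(), e2.endpoints()
    if a < b:
        return -1
    if a > b:
        return 1
    return 0


class GraphSet:
    """A subset of the graph universe {1..n}; the support type.

    Backed by an integer bitmask so intersection, subset and cardinality are
    word-parallel regardless of n.
    """

    __slots__ = ("mask", "universe_size")

    def __init__(self, members: Iterable[int], universe_size: int):
        mask = 0
        for m in members:
            if not 1 <= m <= universe_size:
                raise DataError(f"graph index {m} outside universe 1..{universe_size}")
            mask |= 1 << (m - 1)
        self.mask = mask
        self.universe_size = universe_size

    @classmethod
    def _from_mask(cls, mask: int, universe_size: int) -> "GraphSet":
        gs = cls.__new__(cls)
        gs.mask = mask
        gs.universe_size = universe_size
        return gs

    @property
    def members(self) -> tuple[int, ...]:
        return tuple(i + 1 for i in range(self.universe_size) if self.mask >> i & 1)

    def __len__(self) -> int:
        return self.mask.bit_count()

    def __contains__(self, i: int) -> bool:
        return 1 <= i <= self.universe_size and bool(self.mask >> (i - 1) & 1)

    def __and__(self, other: "GraphSet") -> "GraphSet":
        return GraphSet._from_mask(self.mask & other.mask, self.universe_size)

    def issubset(self, other: "GraphSet") -> bool:
        return self.mask & ~other.mask == 0

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GraphSet)
            and self.mask == other.mask
            and self.universe_size == other.universe_size
        )

    def __hash__(self) -> int:
        return hash((self.mask, self.universe_size))

    def __repr__(self) -> str:
        return f"GraphSet({set(self.members)}, n={self.universe_size})"


class SingleGraph:
    """A simple undirected graph: vertex table, ordered edges, adjacency.

    ``edges[k]`` is the edge with id k+1. ``incident[v]`` lists ids of edges
    touching vertex v, ascending.
    """

    def __init__(self, vertices: VertexTable, edge_pairs: Iterable[tuple[int, int]]):
        self.vertices = vertices
        pairs = set()
        for u, v in edge_pairs:
            if u == v:
                raise DataError(f"self-loop on vertex {vertices.labels[u]!r} rejected")
            pairs.add((min(u, v), max(u, v)))
        self.edges: list[Edge] = [
            Edge(i + 1, u, v) for i, (u, v) in enumerate(sorted(pairs))
        ]
        self.incident: list[list[int]] = [[] for _ in range(len(vertices))]
        for e in self.edges:
            self.incident[e.u].append(e.id)
            self.incident[e.v].append(e.id)
        # edge neighborhoods, by id (computed lazily)
        self._nbrs: list[list[int]] | None = None

    @classmethod
    def from_label_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SingleGraph":
        pairs = list(pairs)
        labels = {a for a, _ in pairs} | {b for _, b in pairs}
        vt = VertexTable(labels)
        return cls(vt, [(vt.index_of[a], vt.index_of[b]) for a, b in pairs])

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge(self, edge_id: int) -> Edge:
        return self.edges[edge_id - 1]

    def edge_by_labels(self, a: str, b: str) -> Edge:
        ia, ib = self.vertices.index_of[a], self.vertices.index_of[b]
        u, v = min(ia, ib), max(ia, ib)
        for eid in self.incident[u]:
            e = self.edge(eid)
            if e.endpoints() == (u, v):
                return e
        raise DataError(f"no edge ({a}, {b}) in graph")

    def neighbor_ids(self, edge_id: int) -> list[int]:
        """Ids of edges sharing an endpoint with ``edge_id`` (the edge neighborhood)."""
        if self._nbrs is None:
            self._nbrs = [[] for _ in range(self.n_edges)]
            for e in self.edges:
                seen = {e.id}
                for v in e.endpoints():
                    for x in self.incident[v]:
                        if x not in seen:
                            seen.add(x)
                            self._nbrs[e.id - 1].append(x)
                self._nbrs[e.id - 1].sort()
        return self._nbrs[edge_id - 1]

    def format_edge(self, edge_id: int) -> str:
        e = self.edge(edge_id)
        return f"{self.vertices.labels[e.u]}--{self.vertices.labels[e.v]}"

    def format_edgeset(self, edge_ids: Iterable[int]) -> str:
        return ";".join(self.format_edge(i) for i in sorted(edge_ids))


def edge_neighborhood(e: Edge, graph: SingleGraph) -> set[Edge]:
    """All edges at distance 1 from ``e``: those sharing at least one endpoint."""
    if not (1 <= e.id <= graph.n_edges) or graph.edge(e.id) != e:
        raise DataError(f"edge {e} does not belong to the graph")
    return {graph.edge(i) for i in graph.neighbor_ids(e.id)}


def edge_distance(
    e1: Edge,
    e2: Edge,
    graph: SingleGraph,
    within: Iterable[int] | None = None,
) -> float:
    """Distance between two edges: non-terminal vertices on a shortest edge path.

    Equal edges are at distance 0 and adjacent edges (sharing an endpoint) at
    distance 1; in general the distance is 1 plus the shortest vertex-to-vertex
    path length between the closest pair of endpoints. When ``within`` is
    given, paths may only use edges whose ids are in that set (``e1`` and
    ``e2`` are always usable). Returns ``math.inf`` when no path exists.
    """
    if e1 == e2:
        return 0
    allowed = None if within is None else set(within) | {e1.id, e2.id}
    targets = set(e2.endpoints())
    # multi-source BFS on vertices from e1's endpoints
    dist = {e1.u: 0, e1.v: 0}
    q = deque([e1.u, e1.v])
    while q:
        v = q.popleft()
        if v in targets:
            return 1 + dist[v]
        for eid in graph.incident[v]:
            if allowed is not None and eid not in allowed:
                continue
            e = graph.edge(eid)
            w = e.v if e.u == v else e.u
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return math.inf


class EdgeAttributedDataset:
    """Summary graph G = (V, E, f) of a collection of graphs on shared vertices.

    ``f`` maps each summary-edge id to the :class:`GraphSet` of member graphs
    containing that edge; every edge belongs to at least one graph.
    """

    def __init__(
        self,
        graph: SingleGraph,
        f: Mapping[int, GraphSet],
        graph_names: Sequence[str],
    ):
        if len(set(graph_names)) != len(graph_names):
            raise DataError("graph names must be unique")
        n = len(graph_names)
        self.graph = graph
        self.graph_names = list(graph_names)
        self.f: list[GraphSet] = []
        for e in graph.edges:
            gs = f.get(e.id)
            if gs is None or len(gs) == 0:
                raise DataError(f"edge {graph.format_edge(e.id)} has empty graph set")
            if gs.universe_size != n:
                raise DataError("GraphSet universe does not match the number of graphs")
            self.f.append(gs)

    # convenience accessors -------------------------------------------------
    @property
    def vertices(self) -> VertexTable:
        return self.graph.vertices

    @property
    def edges(self) -> list[Edge]:
        return self.graph.edges

    @property
    def n_graphs(self) -> int:
        return len(self.graph_names)

    def attr(self, edge_id: int) -> GraphSet:
        return self.f[edge_id - 1]

    def edge_ids_of_graph(self, i: int) -> set[int]:
        """The edge-id set E_i of member graph i (1-based)."""
        return {e.id for e in self.edges if i in self.f[e.id - 1]}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, EdgeAttributedDataset)
            and self.graph_names == other.graph_names
            and self.vertices == other.vertices
            and [e.endpoints() for e in self.edges]
            == [e.endpoints() for e in other.edges]
            and self.f == other.f
        )


# ---------------------------------------------------------------------------
# Construction and I/O
# ---------------------------------------------------------------------------


def build_summary_graph(
    per_graph_edge_lists: Sequence[Iterable[tuple[str, str]]],
    graph_names: Sequence[str] | None = None,
) -> EdgeAttributedDataset:
    """Union per-graph edge lists (label pairs) into an edge-attributed dataset."""
    n = len(per_graph_edge_lists)
    if n == 0:
        raise DataError("empty dataset: at least one graph is required")
    if graph_names is None:
        graph_names = [str(i) for i in range(1, n + 1)]
    membership: dict[tuple[str, str], set[int]] = {}
    labels: set[str] = set()
    for gi, pairs in enumerate(per_graph_edge_lists, start=1):
        for a, b in pairs:
            if a == b:
                raise DataError(f"self-loop {a!r}--{b!r} rejected")
            key = (min(a, b), max(a, b))
            labels.update(key)
            membership.setdefault(key, set()).add(gi)
    if not membership:
        raise DataError("empty dataset: no edges in any graph")
    vt = VertexTable(labels)
    graph = SingleGraph(
        vt, [(vt.index_of[a], vt.index_of[b]) for a, b in membership]
    )
    f = {
        graph.edge_by_labels(a, b).id: GraphSet(gs, n)
        for (a, b), gs in membership.items()
    }
    return EdgeAttributedDataset(graph, f, graph_names)


def _parse_edge_line(line: str, path: str, lineno: int, n_fields: int) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < n_fields or any(not p.strip() for p in parts[:n_fields]):
        raise DataError(f"{path}:{lineno}: malformed line {line.rstrip()!r}")
    return [p.strip() for p in parts[:n_fields]]


def load_single_graph(path: str | os.PathLike) -> SingleGraph:
    """Read one graph from a two-column edge-list TSV."""
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            a, b = _parse_edge_line(line, str(path), lineno, 2)
            if a == b:
                raise DataError(f"{path}:{lineno}: self-loop {a!r} rejected")
            pairs.append((a, b))
    if not pairs:
        raise DataError(f"{path}: no edges")
    return SingleGraph.from_label_pairs(pairs)


def load_dataset(path: str | os.PathLike, format: str) -> EdgeAttributedDataset:
    """Load a graph dataset.

    ``format`` is ``"summary-tsv"`` (one file: vertex1, vertex2, comma-separated
    graph names per line) or ``"edgelist-dir"`` (a directory of two-column
    ``*.tsv`` files, one graph per file, graph name = file stem, graph order =
    sorted file names).
    """
    path = Path(path)
    if format == "summary-tsv":
        return _load_summary_tsv(path)
    if format == "edgelist-dir":
        return _load_edgelist_dir(path)
    raise DataError(f"unknown dataset format {format!r}")


def _load_summary_tsv(path: Path) -> EdgeAttributedDataset:
    rows: list[tuple[str, str, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            a, b, names = _parse_edge_line(line, str(path), lineno, 3)
            if a == b:
                raise DataError(f"{path}:{lineno}: self-loop {a!r} rejected")
            gl = [g.strip() for g in names.split(",") if g.strip()]
            if not gl:
                raise DataError(f"{path}:{lineno}: edge with no graphs")
            rows.append((a, b, gl))
    if not rows:
        raise DataError(f"{path}: no edges")
    graph_names = sorted({g for _, _, gl in rows for g in gl})
    name_idx = {g: i + 1 for i, g in enumerate(graph_names)}
    per_graph: list[list[tuple[str, str]]] = [[] for _ in graph_names]
    for a, b, gl in rows:
        for g in gl:
            per_graph[name_idx[g] - 1].append((a, b))
    return build_summary_graph(per_graph, graph_names)


def _load_edgelist_dir(path: Path) -> EdgeAttributedDataset:
    files = sorted(path.glob("*.tsv"))
    if not files:
        raise DataError(f"{path}: no *.tsv files")
    per_graph = []
    for fp in files:
        pairs = []
        with open(fp, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                a, b = _parse_edge_line(line, str(fp), lineno, 2)
                if a == b:
                    raise DataError(f"{fp}:{lineno}: self-loop {a!r} rejected")
                pairs.append((a, b))
        per_graph.append(pairs)
    return build_summary_graph(per_graph, [fp.stem for fp in files])


def write_dataset(
    dataset: EdgeAttributedDataset, path: str | os.PathLike, format: str = "summary-tsv"
) -> None:
    """Write a dataset; inverse of :func:`load_dataset` for both formats."""
    path = Path(path)
    if format == "summary-tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#vertex1\tvertex2\tgraphs\n")
            for e in dataset.edges:
                names = ",".join(
                    dataset.graph_names[i - 1] for i in dataset.attr(e.id).members
                )
                fh.write(
                    f"{dataset.vertices.labels[e.u]}\t{dataset.vertices.labels[e.v]}\t{names}\n"
                )
    elif format == "edgelist-dir":
        path.mkdir(parents=True, exist_ok=True)
        for gi, name in enumerate(dataset.graph_names, start=1):
            with open(path / f"{name}.tsv", "w", encoding="utf-8") as fh:
                for e in dataset.edges:
                    if gi in dataset.attr(e.id):
                        fh.write(
                            f"{dataset.vertices.labels[e.u]}\t{dataset.vertices.labels[e.v]}\n"
                        )
    else:
        raise DataError(f"unknown dataset format {format!r}")


# ---------------------------------------------------------------------------
# Coexpression networks
# ---------------------------------------------------------------------------


def build_coexpression_network(
    expression, pcc_threshold: float = 0.7
) -> list[tuple[str, str]]:
    """Threshold a gene x sample expression matrix into a coexpression edge list.

    An edge joins two genes whose absolute Pearson correlation across samples
    is at least ``pcc_threshold``. ``expression`` is a pandas DataFrame with
    genes as the index and samples as columns (at least 3). Genes with constant
    expression have undefined correlation; they contribute no edges and a
    warning is logged.
    """
    if not 0 < pcc_threshold <= 1:
        raise DataError("pcc_threshold must be in (0, 1]")
    if expression.shape[1] < 3:
        raise DataError("at least 3 samples are required")
    genes = list(expression.index)
    if len(set(genes)) != len(genes):
        raise DataError("gene labels must be unique")
    X = np.asarray(expression, dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        bad = [g for g, c in zip(genes, constant) if c]
        logger.warning(
            "dropping %d constant-expression gene(s) with undefined correlation: %s",
            len(bad), ", ".join(map(str, bad[:10])),
        )
    keep = ~constant
    Xk = X[keep]
    gk = [g for g, k in zip(genes, keep) if k]
    if len(gk) < 2:
        return []
    R = np.corrcoef(Xk)
    edges = []
    for i in range(len(gk)):
        for j in range(i + 1, len(gk)):
            if abs(R[i, j]) >= pcc_threshold - 1e-12:
                a, b = sorted((gk[i], gk[j]))
                edges.append((a, b))
    edges.sort()
    return edges
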