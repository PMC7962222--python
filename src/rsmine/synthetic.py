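"""Seeded generators and brute-force oracles.

Everything here exists so that the enumerator and the miners can be checked
against independent ground truth without any external data: random
edge-attributed datasets, datasets with a planted frequent motif, exhaustive
(2^|E|) reference enumeration, and the hand-transcribed four-graph toy
dataset whose frequent/maximal counts are known.

Generators are pure functions of their configuration (the seed is
mandatory); the oracles use networkx for connectivity so they share no code
with the reverse-search enumerator they check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .graph_core import (
    DataError,
    EdgeAttributedDataset,
    GraphSet,
    SingleGraph,
    build_summary_graph,
)

__all__ = [
    "GeneratorConfig",
    "random_dataset",
    "planted_dataset",
    "brute_force_ceis",
    "brute_force_frequent_and_maximal",
    "toy_fixture",
]

_BRUTE_FORCE_LIMIT = 16


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random-collection generator.

    ``edge_prob`` is the per-vertex-pair probability that an edge exists in
    the summary graph (Erdos-Renyi); ``membership_prob`` the i.i.d.
    probability that an existing edge belongs to each member graph (redrawn
    until nonempty). The seed is mandatory: identical configs give identical
    datasets.
    """

    n_vertices: int
    n_graphs: int
    edge_prob: float
    membership_prob: float
    seed: int

    def validate(self) -> None:
        if self.n_vertices < 2:
            raise DataError("need at least 2 vertices")
        if self.n_graphs < 1:
            raise DataError("need at least 1 graph")
        for p, name in ((self.edge_prob, "edge_prob"), (self.membership_prob, "membership_prob")):
            if not 0 <= p <= 1:
                raise DataError(f"{name} must be in [0, 1]")


def _vertex_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"v{str(i).zfill(width)}" for i in range(n)]


def random_dataset(config: GeneratorConfig) -> EdgeAttributedDataset:
    """An Erdos-Renyi summary graph with i.i.d. per-graph edge membership."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = _vertex_labels(config.n_vertices)
    per_graph: list[list[tuple[str, str]]] = [[] for _ in range(config.n_graphs)]
    n_edges = 0
    for a, b in combinations(labels, 2):
        if rng.random() >= config.edge_prob:
            continue
        n_edges += 1
        while True:
            mem = rng.random(config.n_graphs) < config.membership_prob
            if mem.any():
                break
        for gi in np.flatnonzero(mem):
            per_graph[gi].append((a, b))
    if n_edges == 0:
        # degenerate draw: guarantee a nonempty dataset with one edge
        gi = int(rng.integers(config.n_graphs))
        per_graph[gi].append((labels[0], labels[1]))
    names = [f"g{i}" for i in range(1, config.n_graphs + 1)]
    return build_summary_graph(per_graph, names)


def planted_dataset(
    motif: list[tuple[str, str]],
    s_min: int,
    background: GeneratorConfig,
) -> EdgeAttributedDataset:
    """A dataset with a connected motif planted in exactly ``s_min`` graphs.

    Motif edges all appear in the same seeded choice of ``s_min`` member
    graphs and nowhere else; background edges (drawn like
    :func:`random_dataset`, skipping motif edges) are each constrained to
    appear in fewer than ``s_min`` graphs, so at threshold ``s_min`` the
    motif is frequent and no background edge can join a frequent subgraph.
    """
    background.validate()
    if not motif:
        raise DataError("motif must contain at least one edge")
    if s_min > background.n_graphs:
        raise DataError("s_min cannot exceed the number of graphs")
    g = nx.Graph(motif)
    if not nx.is_connected(g):
        raise DataError("motif must be connected")
    rng = np.random.default_rng(background.seed)
    labels = _vertex_labels(background.n_vertices)
    label_set = set(labels)
    motif_keys = {(min(a, b), max(a, b)) for a, b in motif}
    for a, b in motif_keys:
        if a not in label_set or b not in label_set:
            raise DataError(f"motif vertex outside the generator's vertex set: ({a}, {b})")

    host = sorted(rng.choice(background.n_graphs, size=s_min, replace=False))
    per_graph: list[list[tuple[str, str]]] = [[] for _ in range(background.n_graphs)]
    for gi in host:
        per_graph[gi].extend(sorted(motif_keys))
    max_bg = s_min - 1  # background support must stay below threshold
    if max_bg >= 1:
        for a, b in combinations(labels, 2):
            if (a, b) in motif_keys or rng.random() >= background.edge_prob:
                continue
            k = int(rng.integers(1, max_bg + 1))
            for gi in rng.choice(background.n_graphs, size=k, replace=False):
                per_graph[gi].append((a, b))
    names = [f"g{i}" for i in range(1, background.n_graphs + 1)]
    return build_summary_graph(per_graph, names)


def brute_force_ceis(graph: SingleGraph) -> set[frozenset[int]]:
    """All connected edgesets by exhaustive subset enumeration (oracle).

    Checks each of the 2^|E| - 1 nonempty edge subsets for connectivity of
    its edge-induced subgraph; refuses graphs with more than 16 edges.
    """
    m = graph.n_edges
    if m > _BRUTE_FORCE_LIMIT:
        raise DataError(
            f"{m} edges is too large for exhaustive enumeration; "
            "use the reverse-search enumerator"
        )
    out: set[frozenset[int]] = set()
    for mask in range(1, 1 << m):
        ids = [i + 1 for i in range(m) if mask >> i & 1]
        g = nx.Graph(graph.edge(i).endpoints() for i in ids)
        if nx.is_connected(g):
            out.add(frozenset(ids))
    return out


def brute_force_frequent_and_maximal(
    dataset: EdgeAttributedDataset, s_min: int
) -> tuple[set[frozenset[int]], set[frozenset[int]]]:
    """Reference frequent and maximal-frequent edgesets (oracle).

    Frequent: connected edgesets (exhaustive) whose per-graph containment
    count is at least ``s_min`` — support is recomputed by testing each
    member graph's edge set directly, not by bitset intersection. Maximal:
    frequent edgesets with no frequent proper superset.
    """
    per_graph_edges = [
        dataset.edge_ids_of_graph(i) for i in range(1, dataset.n_graphs + 1)
    ]
    frequent: set[frozenset[int]] = set()
    for S in brute_force_ceis(dataset.graph):
        count = sum(1 for eg in per_graph_edges if S <= eg)
        if count >= s_min:
            frequent.add(S)
    maximal = {S for S in frequent if not any(S < T for T in frequent)}
    return frequent, maximal


# ---------------------------------------------------------------------------
# Toy fixture
# ---------------------------------------------------------------------------

# Four graphs over vertices {A, B, C, D}. The membership table is the unique
# assignment (up to renaming of the member graphs) consistent with all the
# documented constraints checked in _check_toy below.
_TOY_MEMBERSHIP: dict[tuple[str, str], tuple[int, ...]] = {
    ("A", "B"): (1, 2, 3, 4),
    ("A", "C"): (1, 2, 3),
    ("A", "D"): (1, 2, 4),
    ("B", "C"): (1, 2, 3),
    ("B", "D"): (1, 2, 4),
    ("C", "D"): (1, 2, 3),
}


def toy_fixture() -> EdgeAttributedDataset:
    """The four-graph toy dataset over {A, B, C, D}; self-checked on build.

    At minimum support 3 it has exactly 20 frequent connected subgraphs and
    2 maximal ones: the triangle {A, B, D} (graphs {1, 2, 4}) and the
    triangle {A, B, C} plus the pendant edge (C, D) (graphs {1, 2, 3}).
    """
    n = 4
    per_graph: list[list[tuple[str, str]]] = [[] for _ in range(n)]
    for (a, b), graphs in _TOY_MEMBERSHIP.items():
        for gi in graphs:
            per_graph[gi - 1].append((a, b))
    ds = build_summary_graph(per_graph, ["1", "2", "3", "4"])
    _check_toy(ds)
    return ds


def _check_toy(ds: EdgeAttributedDataset) -> None:
    """Verify every documented constraint; a failed transcription is a hard error."""
    from .frequent_miner import support_of

    def eid(a, b):
        return ds.graph.edge_by_labels(a, b).id

    def sup(*pairs):
        return set(support_of([eid(a, b) for a, b in pairs], ds).members)

    ok = (
        sup(("A", "B"), ("A", "C")) == {1, 2, 3}
        and sup(("A", "B"), ("B", "C")) == {1, 2, 3}
        and sup(("A", "B"), ("A", "C"), ("B", "C")) == sup(("A", "B"), ("A", "C"))
        and sup(("A", "B"), ("A", "C"), ("C", "D")) == sup(("A", "B"), ("A", "C"))
        and all(
            ds.attr(eid(a, b)).issubset(ds.attr(eid("A", "B")))
            for a, b in [("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")]
        )
        and sup(("A", "B"), ("B", "D")) <= sup(("A", "B"), ("A", "D"))
    )
    if ok:
        frequent, maximal = brute_force_frequent_and_maximal(ds, s_min=3)
        ok = len(frequent) == 20 and len(maximal) == 2
    if not ok:
        raise RuntimeError("toy fixture failed its self-check: transcription is wrong")
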