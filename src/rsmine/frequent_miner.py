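"""Frequent connected subgraph mining over an edge-attributed dataset.

The reverse-search enumeration of the summary graph is combined with the
anti-monotone support constraint: the support of an edgeset is the
intersection of the per-edge graph sets, so it can only shrink as the edgeset
grows, and a subtree rooted at an infrequent edgeset is never entered.
Support is maintained incrementally — one bitset intersection per extension,
undone on backtrack.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .ceis_enum import SearchState, _Frame
from .graph_core import DataError, Edge, EdgeAttributedDataset, GraphSet

__all__ = [
    "MiningParams",
    "SubgraphRecord",
    "MiningStats",
    "support_of",
    "enumerate_frequent",
]


@dataclass
class MiningParams:
    """Knobs shared by frequent and maximal mining.

    ``min_support`` is the minimum number of member graphs a reported
    subgraph must appear in (1 <= S_min <= n). The three ``rule*`` flags
    toggle the maximal-mining pruning rules individually; they do not affect
    plain frequent mining. ``min_report_edges`` filters summary statistics
    only, never the mining itself.
    """

    min_support: int
    rule1: bool = True
    rule2: bool = True
    rule3: bool = True
    min_report_edges: int = 3
    emission: str = "preorder"

    def validate(self, n_graphs: int) -> None:
        if self.min_support < 1:
            raise DataError("min_support must be a positive integer")
        # min_support > n_graphs is allowed: mining then returns nothing


@dataclass
class SubgraphRecord:
    """An emitted connected subgraph: edges, supporting graphs, maximal flag."""

    edges: tuple[Edge, ...]
    support: GraphSet
    is_maximal: bool = False

    @property
    def edge_ids(self) -> frozenset[int]:
        return frozenset(e.id for e in self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_vertices(self) -> int:
        return len({v for e in self.edges for v in e.endpoints()})


@dataclass
class MiningStats:
    """Traversal diagnostics. Label-dependent: counts vary with the (fixed)
    deterministic edge numbering and are not part of the mining result."""

    nodes_explored: int = 0
    frequency_checks: int = 0
    pruned_by_rule: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    emitted: int = 0

    def as_rows(self) -> list[tuple[str, int]]:
        return [
            ("nodes_explored", self.nodes_explored),
            ("frequency_checks", self.frequency_checks),
            ("pruned_by_rule1", self.pruned_by_rule[1]),
            ("pruned_by_rule2", self.pruned_by_rule[2]),
            ("pruned_by_rule3", self.pruned_by_rule[3]),
            ("emitted", self.emitted),
        ]


def support_of(
    edgeset: Iterable[Edge | int], dataset: EdgeAttributedDataset
) -> GraphSet:
    """Supporting graphs of an edgeset: the intersection of per-edge graph sets."""
    ids = [e.id if isinstance(e, Edge) else e for e in edgeset]
    if not ids:
        raise DataError("support of the empty edgeset is undefined")
    sup = dataset.attr(ids[0])
    for i in ids[1:]:
        sup = sup & dataset.attr(i)
    return sup


def enumerate_frequent(
    dataset: EdgeAttributedDataset,
    params: MiningParams,
    stats: MiningStats | None = None,
) -> Iterator[SubgraphRecord]:
    """Stream every frequent connected edgeset of the dataset exactly once.

    Traverses the reverse-search tree of the summary graph, rooted at the
    frequent edges only, descending only into frequent valid children.
    Each record carries the exact supporting graph set.
    """
    params.validate(dataset.n_graphs)
    smin = params.min_support
    if stats is None:
        stats = MiningStats()
    if smin > dataset.n_graphs:
        import logging

        logging.getLogger(__name__).warning(
            "min_support %d exceeds the number of graphs %d: no frequent subgraphs",
            smin, dataset.n_graphs,
        )
        return
    graph = dataset.graph
    state = SearchState(graph)

    def record() -> SubgraphRecord:
        stats.emitted += 1
        return SubgraphRecord(
            tuple(graph.edge(i) for i in state.edgeset), sup_stack[-1]
        )

    pre = params.emission == "preorder"
    if params.emission not in ("preorder", "alternating"):
        raise DataError(f"unknown emission mode {params.emission!r}")

    for s in range(1, graph.n_edges + 1):
        if len(dataset.attr(s)) < smin:
            continue
        state.init_root(s)
        sup_stack: list[GraphSet] = [dataset.attr(s)]
        stats.nodes_explored += 1
        yield record()  # depth 1 is odd: up-front in both emission modes
        stack = [_Frame(state.valid_candidates())]
        while stack:
            fr = stack[-1]
            advanced = False
            while fr.idx < len(fr.valid):
                e_j = fr.valid[fr.idx]
                fr.idx += 1
                child_sup = sup_stack[-1] & dataset.attr(e_j)
                stats.frequency_checks += 1
                if len(child_sup) < smin:
                    continue  # downward closure: subtree cannot be frequent
                state.push(e_j)
                sup_stack.append(child_sup)
                stats.nodes_explored += 1
                if pre or state.depth() % 2 == 1:
                    yield record()
                stack.append(_Frame(state.valid_candidates()))
                advanced = True
                break
            if not advanced:
                stack.pop()
                if not pre and state.depth() % 2 == 0:
                    yield record()
                if state.depth() > 1:
                    state.pop()
                    sup_stack.pop()
        state.reset()
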