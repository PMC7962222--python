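"""Maximal frequent connected subgraph mining with local maximality testing.

A frequent subgraph is maximal when it has no frequent proper frequent
supergraph. Because any frequent proper connected supergraph of an edgeset S
contains a frequent one-edge extension of S, and the maintained candidate
list is exactly N(S), maximality can be decided *locally*: scan every
candidate — valid or invalid, including edges ordered below the anchor — and
check whether adding it keeps the support above threshold. No global store
of discovered maximal subgraphs is needed.

Three pruning rules cut search branches that provably contain no maximal
subgraph (toggleable for verification; results are identical either way):

1. *Consumed by a sibling* — a frequent child whose support is a subset of an
   earlier-processed (closer-to-anchor) accepted sibling's support is
   skipped: any maximal supergraph in its branch could absorb the sibling
   edge, contradicting maximality.
2. *Identical to parent* — once a child with support equal to the parent's
   has been explored, every later valid candidate at this node is skipped
   (each is consumed by that child, by rule 1).
3. *Level-one* — a frequent root edge adjacent to a smaller edge whose graph
   set contains its own is never the anchor of a maximal subgraph; its whole
   tree is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .ceis_enum import SearchState
from .frequent_miner import MiningParams, MiningStats, SubgraphRecord
from .graph_core import DataError, Edge, EdgeAttributedDataset, GraphSet

__all__ = [
    "sibling_covered",
    "identical_parent_shortcut",
    "level_one_roots",
    "local_maximality",
    "mine_maximal",
    "MiningSummary",
    "summarize_results",
]


def sibling_covered(
    child_support: GraphSet, accepted_sibling_supports: Sequence[GraphSet]
) -> bool:
    """Pruning rule 1: is this child's support contained in an accepted sibling's?

    ``accepted_sibling_supports`` are the child supports of valid candidates
    already recursed into at this node (all closer to the anchor). Checking
    against all of them is transitively sufficient: chains of subset
    relations collapse onto an accepted sibling.
    """
    return any(child_support.issubset(s) for s in accepted_sibling_supports)


def identical_parent_shortcut(
    parent_support: GraphSet, child_support: GraphSet
) -> bool:
    """Pruning rule 2 trigger: the child kept the parent's entire support."""
    return child_support == parent_support


def level_one_roots(
    dataset: EdgeAttributedDataset, params: MiningParams
) -> list[Edge]:
    """Frequent root edges surviving pruning rule 3, ascending by id.

    A frequent edge e_j is dropped when some adjacent smaller edge e_i has
    f(e_j) ⊆ f(e_i): every subgraph anchored at e_j could absorb e_i without
    losing support, so none is maximal.
    """
    smin = params.min_support
    roots = []
    for e in dataset.edges:
        fj = dataset.attr(e.id)
        if len(fj) < smin:
            continue
        if params.rule3 and any(
            i < e.id and fj.issubset(dataset.attr(i))
            for i in dataset.graph.neighbor_ids(e.id)
        ):
            continue
        roots.append(e)
    return roots


def local_maximality(
    state: SearchState,
    support: GraphSet,
    dataset: EdgeAttributedDataset,
    params: MiningParams,
    stats: MiningStats | None = None,
) -> bool:
    """Is the state's (frequent) edgeset maximal?

    True iff no candidate in the full candidate list — valid or invalid,
    including below-anchor edges — yields a frequent one-edge extension.
    """
    smin = params.min_support
    maximal = True
    for e, _d in state.candidate_items():
        if stats is not None:
            stats.frequency_checks += 1
        if len(support & dataset.attr(e)) >= smin:
            maximal = False
            if stats is None:
                break  # counting mode scans everything; decision mode can stop
    return maximal


class _MaxFrame:
    __slots__ = ("valid", "idx", "maximal", "sup", "accepted")

    def __init__(self, valid, maximal, sup):
        self.valid = valid  # [(edge id, child support)] in closest-first order
        self.idx = 0
        self.maximal = maximal
        self.sup = sup
        self.accepted: list[GraphSet] = []  # supports of children recursed into


def mine_maximal(
    dataset: EdgeAttributedDataset,
    params: MiningParams,
    stats: MiningStats | None = None,
) -> list[SubgraphRecord]:
    """All maximal frequent connected subgraphs of the dataset.

    Walks the frequent-subgraph search tree; at each node the full candidate
    list is scanned once to (a) decide local maximality and (b) precompute
    child supports, then valid candidates are processed closest-first with
    pruning rules 1 and 2. Roots come from :func:`level_one_roots` (rule 3).
    """
    params.validate(dataset.n_graphs)
    smin = params.min_support
    if stats is None:
        stats = MiningStats()
    results: list[SubgraphRecord] = []
    if smin > dataset.n_graphs:
        return results
    graph = dataset.graph
    state = SearchState(graph)

    def open_frame(sup: GraphSet) -> _MaxFrame:
        stats.nodes_explored += 1
        maximal = True
        child_sup: dict[int, GraphSet] = {}
        for e, _d in state.candidate_items():
            cs = sup & dataset.attr(e)
            stats.frequency_checks += 1
            child_sup[e] = cs
            if len(cs) >= smin:
                maximal = False
        valid = [(e, child_sup[e]) for e in state.valid_candidates()]
        return _MaxFrame(valid, maximal, sup)

    def close_frame(fr: _MaxFrame) -> None:
        if fr.maximal:
            stats.emitted += 1
            results.append(
                SubgraphRecord(
                    tuple(graph.edge(i) for i in state.edgeset), fr.sup, is_maximal=True
                )
            )

    all_roots = {e.id for e in dataset.edges if len(dataset.attr(e.id)) >= smin}
    kept_roots = level_one_roots(dataset, params)
    stats.pruned_by_rule[3] += len(all_roots) - len(kept_roots)

    for root in kept_roots:
        state.init_root(root.id)
        stack = [open_frame(dataset.attr(root.id))]
        while stack:
            fr = stack[-1]
            advanced = False
            while fr.idx < len(fr.valid):
                e_j, cs = fr.valid[fr.idx]
                fr.idx += 1
                if len(cs) < smin:
                    continue
                if params.rule1 and sibling_covered(cs, fr.accepted):
                    stats.pruned_by_rule[1] += 1
                    continue
                fr.accepted.append(cs)
                if params.rule2 and identical_parent_shortcut(fr.sup, cs):
                    # explore this child, then skip every later valid candidate
                    stats.pruned_by_rule[2] += len(fr.valid) - fr.idx
                    fr.idx = len(fr.valid)
                state.push(e_j)
                stack.append(open_frame(cs))
                advanced = True
                break
            if not advanced:
                close_frame(stack.pop())
                if state.depth() > 1:
                    state.pop()
        state.reset()
    return results


@dataclass
class MiningSummary:
    """Aggregate shape statistics of a mined subgraph collection.

    ``n_filtered`` counts records with at least ``min_edges`` edges; the
    means are over those records only. Density of a subgraph with vertex set
    V_s and edge set E_s is 2|E_s| / (|V_s| (|V_s| - 1)).
    """

    n_records: int
    min_edges: int
    n_filtered: int
    mean_edges: float
    mean_vertices: float
    mean_density: float

    def as_rows(self) -> list[tuple[str, float]]:
        return [
            ("n_subgraphs", self.n_records),
            (f"n_subgraphs_ge_{self.min_edges}_edges", self.n_filtered),
            ("mean_edges", round(self.mean_edges, 4)),
            ("mean_vertices", round(self.mean_vertices, 4)),
            ("mean_density", round(self.mean_density, 4)),
        ]


def summarize_results(
    records: Sequence[SubgraphRecord], min_edges: int = 3
) -> MiningSummary:
    """Table-style summary of mined subgraphs with >= ``min_edges`` edges."""
    if min_edges < 1:
        raise DataError("min_edges must be at least 1")
    kept = [r for r in records if r.n_edges >= min_edges]
    if not kept:
        return MiningSummary(len(records), min_edges, 0, 0.0, 0.0, 0.0)
    dens = [
        2 * r.n_edges / (r.n_vertices * (r.n_vertices - 1)) for r in kept
    ]
    return MiningSummary(
        n_records=len(records),
        min_edges=min_edges,
        n_filtered=len(kept),
        mean_edges=sum(r.n_edges for r in kept) / len(kept),
        mean_vertices=sum(r.n_vertices for r in kept) / len(kept),
        mean_density=sum(dens) / len(dens),
    )
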