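"""Reverse-search enumeration of connected edge-induced subgraphs.

Every connected edgeset of a graph is arranged in a forest: the root of each
tree is a single edge (the *anchor*, the minimum edge of every edgeset in its
subtree) and the unique parent of a multi-edge edgeset is obtained by removing
its *utmost* edge — the edge farthest from the anchor, ties broken toward the
larger edge. Removing the utmost edge always keeps the edgeset connected, so
the parent is well defined, and inverting the operation (the valid-children
rule) yields a duplicate-free depth-first traversal with no visited set.

Distances of candidate edges to the anchor are recorded *branch-relatively*:
when a candidate first becomes reachable it is stamped with the distance of
the edge that exposed it plus one, which equals its edge distance to the
anchor measured inside the current edgeset plus itself. This makes the
validity test O(1) and the state three flat arrays of size |E|, restored by
undo on backtrack rather than copied.

The traversal is iterative (explicit stack), so deep search trees on large
graphs do not hit the interpreter recursion limit.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Literal

from .graph_core import DataError, Edge, SingleGraph, edge_distance

__all__ = [
    "SearchState",
    "anchor_of",
    "utmost_of",
    "parent_of",
    "is_valid_extension",
    "enumerate_ceis",
]

EmissionMode = Literal["preorder", "alternating"]


def anchor_of(edgeset: Iterable[Edge]) -> Edge:
    """The minimum edge of a nonempty edgeset under the total edge order."""
    edges = list(edgeset)
    if not edges:
        raise DataError("anchor of an empty edgeset is undefined")
    return min(edges, key=lambda e: e.id)


def utmost_of(edgeset: Iterable[Edge], graph: SingleGraph) -> Edge:
    """The edge farthest from the anchor, ties broken toward the larger edge.

    Distances are measured within the edgeset itself. For a singleton edgeset
    the anchor itself is returned (distance 0 by convention).
    """
    edges = list(edgeset)
    s = anchor_of(edges)
    if len(edges) == 1:
        return s
    ids = [e.id for e in edges]
    return max(
        (e for e in edges if e.id != s.id),
        key=lambda e: (edge_distance(s, e, graph, within=ids), e.id),
    )


def parent_of(edgeset: Iterable[Edge], graph: SingleGraph) -> set[Edge]:
    """The unique search-tree parent: the edgeset minus its utmost edge.

    The result is guaranteed connected for any connected input with at least
    two edges; singletons are roots and have no parent.
    """
    edges = set(edgeset)
    if len(edges) < 2:
        raise DataError("singleton edgesets are enumeration roots and have no parent")
    edges.discard(utmost_of(edges, graph))
    return edges


class SearchState:
    """One node of the enumeration tree, with O(|E|) undo-able state.

    Maintains the current edgeset (insertion order; the first entry is the
    anchor and the last the utmost), the candidate list N(edgeset) with each
    candidate's recorded distance to the anchor, and membership flags.
    Candidates ordered below the anchor are retained — they are never valid
    extensions, but maximal-frequent mining needs them for its maximality
    test.
    """

    def __init__(self, graph: SingleGraph):
        self.graph = graph
        m = graph.n_edges
        self.in_edgeset = bytearray(m + 1)
        self.in_candidates = bytearray(m + 1)
        self.dist = [0] * (m + 1)
        self.edgeset: list[int] = []
        self.candidates: list[int] = []
        self._added: list[int] = []  # candidates appended per push, for undo

    # -- properties ---------------------------------------------------------
    @property
    def anchor(self) -> int:
        return self.edgeset[0]

    @property
    def utmost(self) -> int:
        """Last edge appended; the anchor itself for a singleton state."""
        return self.edgeset[-1]

    @property
    def utmost_distance(self) -> int:
        return self.dist[self.utmost]

    def depth(self) -> int:
        return len(self.edgeset)

    # -- lifecycle ----------------------------------------------------------
    def init_root(self, s: int) -> None:
        """Start a fresh singleton state {s}; candidates are N(s) at distance 1."""
        if self.edgeset:
            raise DataError("state already initialized; reset() first")
        self.in_edgeset[s] = 1
        self.dist[s] = 0
        self.edgeset.append(s)
        added = 0
        for x in self.graph.neighbor_ids(s):
            self.in_candidates[x] = 1
            self.dist[x] = 1
            self.candidates.append(x)
            added += 1
        self._added.append(added)

    def push(self, e_j: int) -> None:
        """Append candidate ``e_j`` to the edgeset and update the candidate set.

        Neighbors of ``e_j`` not already candidates (or members) are appended
        with recorded distance ``dist(e_j) + 1``; existing candidates keep
        their recorded distances (first insertion wins).
        """
        if not self.in_candidates[e_j]:
            raise DataError(f"edge {e_j} is not a candidate of the current edgeset")
        self.in_candidates[e_j] = 0
        self.in_edgeset[e_j] = 1
        self.edgeset.append(e_j)
        added = 0
        d = self.dist[e_j] + 1
        for x in self.graph.neighbor_ids(e_j):
            if not self.in_edgeset[x] and not self.in_candidates[x]:
                self.in_candidates[x] = 1
                self.dist[x] = d
                self.candidates.append(x)
                added += 1
        self._added.append(added)

    def pop(self) -> None:
        """Undo the most recent :meth:`push` (or root initialization)."""
        if not self.edgeset:
            raise DataError("nothing to pop")
        for _ in range(self._added.pop()):
            x = self.candidates.pop()
            self.in_candidates[x] = 0
        e = self.edgeset.pop()
        self.in_edgeset[e] = 0
        if self.edgeset:  # e returns to candidate status unless it was the root
            self.in_candidates[e] = 1

    def reset(self) -> None:
        while self.edgeset:
            self.pop()

    # -- queries ------------------------------------------------------------
    def candidate_items(self) -> list[tuple[int, int]]:
        """Current candidates as (edge id, recorded distance), insertion order."""
        return [(x, self.dist[x]) for x in self.candidates if self.in_candidates[x]]

    def is_valid(self, e_j: int) -> bool:
        """Valid-children rule: does extending by candidate ``e_j`` yield a child?

        True iff ``e_j`` is above the anchor and its recorded distance/order
        pair strictly exceeds the utmost's. For a singleton state every
        above-anchor candidate qualifies (all are at distance 1 > 0).
        """
        if not self.in_candidates[e_j]:
            raise DataError(f"edge {e_j} is not a candidate of the current edgeset")
        if e_j < self.anchor:
            return False
        u = self.utmost
        return (self.dist[e_j], e_j) > (self.dist[u], 0 if u == self.anchor else u)

    def valid_candidates(self) -> list[int]:
        """Valid extensions sorted by (recorded distance, id) — closest first."""
        out = [x for x in self.candidates if self.in_candidates[x] and self.is_valid(x)]
        out.sort(key=lambda x: (self.dist[x], x))
        return out


def is_valid_extension(state: SearchState, e_prime: Edge | int) -> bool:
    """Functional wrapper around :meth:`SearchState.is_valid`."""
    e_id = e_prime.id if isinstance(e_prime, Edge) else e_prime
    return state.is_valid(e_id)


def update_candidates(state: SearchState, e_j: Edge | int) -> SearchState:
    """Grow the state by candidate ``e_j`` in place; returns the same state."""
    state.push(e_j.id if isinstance(e_j, Edge) else e_j)
    return state


class _Frame:
    __slots__ = ("valid", "idx")

    def __init__(self, valid: list[int]):
        self.valid = valid
        self.idx = 0


def enumerate_ceis(
    graph: SingleGraph,
    emission: EmissionMode = "preorder",
    max_size: int | None = None,
) -> Iterator[tuple[int, ...]]:
    """Stream every connected edgeset of ``graph`` exactly once.

    Yields tuples of edge ids in insertion order (first element = anchor).
    For each root edge s in ascending id order, the subtree of all edgesets
    anchored at s is traversed depth-first.

    ``emission`` controls output placement only — the emitted *set* is
    identical: "preorder" emits a node before its children; "alternating"
    emits before the children at odd depth and after them at even depth,
    which bounds the gap between consecutive outputs by one level of work
    (linear delay).

    ``max_size`` optionally caps the number of edges per emitted edgeset.
    """
    if emission not in ("preorder", "alternating"):
        raise DataError(f"unknown emission mode {emission!r}")
    if max_size is not None and max_size < 1:
        return
    state = SearchState(graph)
    for s in range(1, graph.n_edges + 1):
        state.init_root(s)
        yield (s,)  # depth 1 is odd: emitted up front in both modes
        stack = [_Frame(state.valid_candidates() if max_size is None or max_size > 1 else [])]
        while stack:
            fr = stack[-1]
            if fr.idx < len(fr.valid):
                e_j = fr.valid[fr.idx]
                fr.idx += 1
                state.push(e_j)
                depth = state.depth()
                if emission == "preorder" or depth % 2 == 1:
                    yield tuple(state.edgeset)
                expandable = max_size is None or depth < max_size
                stack.append(_Frame(state.valid_candidates() if expandable else []))
            else:
                stack.pop()
                if emission == "alternating" and state.depth() % 2 == 0:
                    yield tuple(state.edgeset)
                if state.depth() > 1:
                    state.pop()
        state.reset()
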