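# Methods

## Model and definitions

All graphs are simple and undirected over one shared vertex set with unique
labels. Vertices get 0-based indices by ascending lexicographic label order;
an edge is the pair (u, v) with u < v, and edges get ids 1..|E| by ascending
lexicographic (u, v), so id comparison realizes the total edge order
(i, j) ≼ (k, l) ⇔ i < k, or i = k and j ≤ l. These assignments are the only
arbitrary choices in the system; they fix the shape of the search tree, so
runs are bit-reproducible. The *mining results* — which edgesets are
frequent or maximal, and their supports — are invariant to the labeling;
traversal diagnostics (nodes explored, prune counts) are not, and are
reported only as diagnostics.

The distance between two edges is the number of junction vertices on a
shortest edge path between them: 0 for the same edge, 1 for edges sharing an
endpoint, in general 1 plus the shortest vertex-path length between the
closest pair of endpoints, computed by BFS and optionally restricted to a
given edge subset. Disconnection is represented as infinity rather than an
error, so callers can treat reachability and distance uniformly.

A collection of n graphs is stored as the edge-attributed summary graph
G = (V, E, f): E is the union of the per-graph edge sets and f(e) is the set
of member graphs containing e, held as an integer bitmask (`GraphSet`).
Support of an edgeset S is ∩_{e∈S} f(e); all mining maintains it
incrementally, one AND per extension, undone on backtrack.

## Reverse-search enumeration

Connected edgesets are arranged in a forest. The anchor of an edgeset is its
minimum edge; the utmost edge is the non-anchor edge maximizing (distance to
anchor, id). Deleting the utmost edge keeps the edgeset connected — if every
shortest path from the anchor to some edge ran through the utmost edge, that
edge would be farther than the utmost, a contradiction — so "delete the
utmost" is a well-defined parent operation and each edgeset has a unique
parent. The children of a state are its candidate edges e′ (neighbors of the
edgeset) with anchor ≼ e′ whose (recorded distance, id) strictly exceeds the
current utmost's; growing only through valid children visits every edgeset
exactly once, with no visited set.

Numerical/bookkeeping choices:

* **Branch-relative distances.** The recorded distance of a candidate is the
  recorded distance of the edge that first exposed it plus one, which equals
  its edge distance to the anchor measured inside edgeset ∪ {candidate}.
  First insertion wins; distances are never recomputed. This is O(1) per
  candidate, and it is the semantics under which the parent operation and
  the validity test are mutually consistent (a property test checks the
  recorded value against a restricted BFS from scratch).
* **Singleton convention.** The utmost of {s} is s itself at distance 0, so
  every above-anchor neighbor (distance 1 > 0) is a valid first extension.
  The utmost is otherwise defined only for ≥2 edges, and this convention is
  the unique one consistent with the rest of the traversal. Candidates below
  the anchor are *invalid at every level*, including level one: that reading
  is the only one under which each edgeset's generating sequence exists and
  is unique.
* **Below-anchor candidates are retained** in the candidate list (never as
  extensions): maximal mining must see them when testing maximality, since a
  leaf whose below-anchor neighbor is frequent is not maximal.
* **Explicit stack.** The traversal is iterative; state is three flat arrays
  (membership flags, candidate flags, distances) plus the candidate and
  edgeset lists, restored by undo on backtrack, so space is O(|E|) and deep
  trees cannot overflow the interpreter stack.
* **Emission modes.** "preorder" (default) emits a node before its children.
  "alternating" emits before the children at odd depth and after them at
  even depth, which bounds the work between consecutive outputs by one tree
  level (linear delay); both modes emit the same set, checked by test.
* Valid candidates are always iterated in ascending (recorded distance, id)
  — closest-to-anchor first. Plain enumeration does not need this order, but
  the maximal-mining pruning rules do, and using it everywhere keeps one
  code path.

## Frequent and maximal mining

Frequent mining roots the traversal at the frequent edges only and descends
only into frequent valid children (anti-monotonicity of support). Each
emitted record carries its exact support.

Maximal mining decides maximality locally: an edgeset is maximal iff no
candidate — valid or invalid — keeps support ≥ S_min when added. This is
sound and complete for global maximality because any frequent proper
connected supergraph contains a frequent one-edge extension, and the
candidate list is exactly the edge neighborhood. The full candidate scan at
each node doubles as the precomputation of child supports for the recursion
loop. Three pruning rules skip branches that provably contain no maximal
subgraph; all three preserve the result exactly (verified against the
subset-lattice oracle with every on/off combination):

1. *Consumed by a sibling*: a frequent child whose support is contained in
   the support of an already-recursed (closer-to-anchor) sibling is skipped.
   Comparing against all previously accepted siblings is transitively
   sufficient — if the covering sibling was itself skipped, its own cover is
   accepted and contains the new child's support too.
2. *Identical to parent*: processed in closest-first order, once a child
   retains the parent's entire support, every later valid candidate is
   skipped (each is consumed by that child). The skip is applied after the
   child's branch returns.
3. *Level-one*: a frequent edge adjacent to a smaller edge whose graph set
   contains its own is removed from the root list before traversal.

Single- and two-edge maximal subgraphs are reported; the ≥3-edge filter is
applied only by `summarize_results` (mean edges, vertices and density
2|E_s|/(|V_s|(|V_s|−1)) over the filtered records), mirroring how summary
tables of module shape are usually restricted to non-trivial modules.

`MiningStats` counts recursion nodes, support intersections and per-rule
prunes. Unpruned maximal mining performs more frequency checks than plain
frequent mining over the same tree — maximality testing scans all
candidates, not just valid ones — which is why the pruning rules, not the
enumeration, carry the performance of maximal mining.

## Coexpression networks

`build_coexpression_network` thresholds a genes × samples matrix: edge
(g₁, g₂) iff |Pearson r| ≥ threshold (default 0.7, the conventional cutoff
for calling a gene pair coexpressed; at least 3 samples required). Genes
with zero variance have undefined correlation and are dropped with a logged
warning. Differential-expression filtering upstream of network construction
is out of scope — the function takes whatever gene panel it is given.

## Synthetic data and oracles

The generators exist to make every claim testable without external data:

* `random_dataset`: Erdős–Rényi summary graph (default edge probability 0.3
  on 10 vertices, 5 graphs), each edge's membership drawn i.i.d. per graph
  (default probability 0.5), redrawn if empty. Sizes are chosen so that the
  exhaustive 2^|E| oracle stays instant while still producing non-trivial
  support lattices; the defaults describe a small dense multi-condition
  collection, not any particular biological dataset.
* `planted_dataset`: a connected motif placed in exactly s_min seeded
  member graphs; background edges are each assigned to fewer than s_min
  graphs, so the motif is exactly recoverable — this isolates the recovery
  contract from threshold effects.
* `brute_force_ceis` / `brute_force_frequent_and_maximal`: exhaustive subset
  enumeration with networkx connectivity checks and per-graph containment
  counting — deliberately sharing no code or data structures with the
  reverse-search path they verify. Hard-capped at 16 edges.
* `toy_fixture`: the four-graph reference dataset over {A, B, C, D}. Its
  membership table is validated at construction against every documented
  constraint (pairwise supports, subset relations between edge attributes,
  and the 20-frequent / 2-maximal counts at S_min = 3); a wrong
  transcription raises instead of silently skewing tests.

What passing these tests shows — and does not. The generators produce
uniform random and planted structure over small universes; real
coexpression networks are larger, sparser, degree-heterogeneous and
edge-correlated across conditions. Exactness of enumeration and mining is a
combinatorial property checked exhaustively at small scale and carries over
to large inputs by construction (the algorithms never sample or
approximate), but runtime behavior on realistic network collections is not
established by this suite.

## Problem sizes used in verification

Enumeration equivalence runs on 200+ random graphs of ≤12 edges in both
emission modes; mining equivalence on 100+ random datasets (≤10 vertices,
2–5 graphs) across all thresholds and all 8 pruning-flag combinations;
motif recovery on 50 seeds. These sizes keep the exhaustive oracles exact
and the full suite fast while covering the combinatorics densely.

## Known limitations

* Weighted edges, directed graphs, per-graph vertex sets and repeated
  labels are out of scope by design.
* The number of frequent subgraphs is exponential in the worst case;
  `enumerate_frequent` streams and `--count-only` avoids materialization,
  but downstream code that collects the stream must budget for |ℱ|.
* `GraphSet` assumes the number of member graphs is at most a few thousand
  (one Python int bitmask per edge).
* Traversal-order diagnostics (`nodes_explored`, prune counters) depend on
  the deterministic edge numbering and should not be compared across
  differently-labeled encodings of the same data.
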