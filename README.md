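# rsmine

Reverse-search mining of frequent and maximal frequent subgraphs in
collections of graphs with uniquely-labeled vertices.

## The problem

Gene coexpression networks built from different experiments, tissues or
disease stages all live on the same set of genes. A subnetwork that recurs
across many of these networks — a set of gene–gene links present together in
many conditions — is a strong candidate for a functional module, and far
more trustworthy than structure seen in a single noisy network. Formally:
given a collection 𝒢 = {G₁, …, Gₙ} of undirected graphs over one shared
vertex set and a support threshold S_min, a connected subgraph G_s is
**frequent** when |sup(G_s)| = |{i : G_s ⊆ G_i}| ≥ S_min, and **maximal
frequent** when no frequent proper supergraph exists. The maximal set ℳ is
the concise summary of the (often astronomically larger) frequent set ℱ.

Because every vertex label is unique, no subgraph isomorphism is involved: a
connected subgraph *is* its edgeset, and the collection is stored as a
single **edge-attributed summary graph** G = (V, E, f) where f maps each
edge to the set of member graphs containing it. The support of an edgeset is
then just the intersection ∩ₑ f(e), computed incrementally with bitsets.

## The algorithm

The engine is a reverse-search enumerator of **connected edge-induced
subgraphs** (connected edgesets) of a single graph. All edgesets are
arranged in a forest: the *anchor* of an edgeset is its minimum edge under
the lexicographic edge order, and the unique parent of a multi-edge edgeset
is obtained by deleting its *utmost* edge — the edge with the longest edge
distance to the anchor (distance = number of junction vertices on a shortest
edge path; adjacent edges are at distance 1), ties broken toward the larger
edge. Deleting the utmost edge provably keeps the edgeset connected, and
inverting the deletion (the valid-children rule) gives a duplicate-free
depth-first traversal with O(|E|) state and linear delay between outputs —
no global visited set, no isomorphism checks.

Frequent mining runs the same traversal on the summary graph and prunes any
child whose support drops below S_min (anti-monotonicity). Maximal mining
additionally decides maximality *locally* — an edgeset is maximal iff no
candidate extension (valid or not) stays frequent — and prunes search
branches that provably contain no maximal subgraph:

1. **consumed by a sibling** — a frequent child whose support is contained
   in an earlier sibling's support is skipped;
2. **identical to parent** — after a child that keeps the parent's entire
   support, all later siblings are skipped;
3. **level-one** — a frequent root edge covered by a smaller adjacent edge
   is never an anchor of a maximal subgraph.

The pruned and unpruned runs return the same maximal set; the rules only
shrink the explored tree (each is toggleable for verification).

## Worked example

```python
import rsmine as rm

toy = rm.toy_fixture()          # 4 graphs over vertices {A, B, C, D}
params = rm.MiningParams(min_support=3)
print(len(list(rm.enumerate_frequent(toy, params))))   # 20
for r in rm.mine_maximal(toy, params):
    print(toy.graph.format_edgeset(sorted(e.id for e in r.edges)),
          set(r.support.members))
```

prints

```
20
A--B;A--C;B--C;C--D {1, 2, 3}
A--B;A--D;B--D {1, 2, 4}
```

Of the 20 frequent connected subgraphs at S_min = 3, only two are maximal:
a triangle plus pendant edge supported by graphs {1, 2, 3} and a triangle
supported by {1, 2, 4}; every other frequent subgraph is contained in one of
them. The same run from the shell:

```bash
rsmine maximal --dataset toy_dir/ --format edgelist-dir --min-support 3
```

See `examples/` for narrative scripts: plain enumeration, toy mining,
planted-motif recovery, and a full coexpression workflow (expression
matrices → per-condition networks at |PCC| ≥ 0.7 → recurrent modules).

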