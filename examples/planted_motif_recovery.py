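"""Recover a planted frequent motif from a noisy synthetic graph collection.

A connected 4-edge motif is planted into exactly 3 of 6 member graphs;
background edges each appear in fewer than 3 graphs, so at minimum support 3
the motif is the only frequent structure. Maximal mining should report it
with exactly its host graphs as support.
"""

import rsmine as rm

motif = [("v0", "v1"), ("v1", "v2"), ("v2", "v3"), ("v1", "v3")]
cfg = rm.GeneratorConfig(
    n_vertices=9, n_graphs=6, edge_prob=0.3, membership_prob=0.5, seed=42
)
ds = rm.planted_dataset(motif, s_min=3, background=cfg)
print(
    f"dataset: {ds.n_graphs} graphs, {ds.graph.n_edges} summary edges "
    f"({len(motif)} of them planted)"
)

records = rm.mine_maximal(ds, rm.MiningParams(min_support=3))
motif_ids = frozenset(ds.graph.edge_by_labels(a, b).id for a, b in motif)
for r in records:
    mark = " <- planted motif" if motif_ids <= r.edge_ids else ""
    ids = sorted(e.id for e in r.edges)
    print(
        f"  maximal: {ds.graph.format_edgeset(ids)} "
        f"support={set(r.support.members)}{mark}"
    )
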