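"""Community structure of the published 11-gene IBS-D active module.

Loads the curated module graph (11 genes, 10 edges) reported for the
IBS-D colonic-biopsy cohort, runs walk-trap community detection, and
evaluates the Newman-Girvan modularity of the partition.  The three
communities separate a DUOX2/CA4/LRP6 axis, a solute-carrier/AKAP1 group,
and a Wnt-related SFRP1/FZD1 group; Q = 0.455 indicates clear community
structure for a graph this small.
"""

from activesem import hypergeom_enrich, modularity, walktrap
from activesem.data_io import GeneSetCollection
from activesem.datasets import ibsd_module_communities, ibsd_module_graph

graph = ibsd_module_graph()
partition = walktrap(graph, steps=4)
print(f"walk-trap found {partition.n_communities} communities, "
      f"modularity Q = {partition.modularity:.3f}")
for cid in range(1, partition.n_communities + 1):
    print(f"  community {cid}: {', '.join(partition.members(cid))}")

reported = ibsd_module_communities()
reported_sets = {
    frozenset(g for g, c in reported.items() if c == cid) for cid in set(reported.values())
}
print(f"matches the reported memberships: {set(partition.as_sets()) == reported_sets}")
print(f"modularity of the reported partition: {modularity(graph, reported):.3f}")

# toy over-representation analysis of the communities against two gene sets
sets = GeneSetCollection({
    "solute_transport": ["MGAM", "SLC5A1", "SLC9B1", "SCNN1G", "AKAP1"],
    "wnt_signaling": ["SFRP1", "FZD1", "LRP6", "UBC"],
})
res = hypergeom_enrich(
    {c: partition.members(c) for c in range(1, 4)}, sets, background=sorted(graph.nodes)
)
print("\nenrichment (hypergeometric + BH):")
print(res.table[["community", "set", "overlap", "adj_p"]].round(4).to_string(index=False))
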