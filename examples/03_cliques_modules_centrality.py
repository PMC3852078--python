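"""Clique-derived complexes, MCL modules and gene ranking on a network.

Two 5-cliques sharing two genes are planted in a sparse background; the
clique-5 subnetwork, the MCL partition and the betweenness ranking each
recover a different view of that structure.
"""

import networkx as nx

from crossnet import clique_k_subnetwork, mcl, score_and_rank

g = nx.Graph()
a = ["CD4", "FCGR3A", "ZAP70", "LCK", "PTPRC"]
b = ["LCK", "PTPRC", "SYK", "SIRPB1", "RARA"]
for clique in (a, b):
    g.add_edges_from((x, y) for i, x in enumerate(clique) for y in clique[i + 1:])
g.add_edges_from([("RARA", "ESR1"), ("ESR1", "PARP1")])  # a tail of weaker context

c5 = clique_k_subnetwork(g, 5)
print(f"clique-5s found: {len(c5.cliques)}; subnetwork: "
      f"{len(c5.subnetwork_nodes)} genes, {len(c5.subnetwork_edges)} interactions")

clusters = mcl(g, inflation=2.0)
print("MCL modules:", [sorted(c) for c in clusters.clusters])

ranking = score_and_rank(g)
top = ranking.iloc[0]
print(f"highest betweenness: {top['node']} ({top['betweenness']:.1f} shortest-path pairs)")
# Genes bridging the two cliques (LCK, PTPRC) carry the flow between the
# modules and therefore rank highest.
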