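"""Pathway enrichment, complex matching and drug-target mapping.

A pathway catalog with one planted set, a complex catalog containing a
clique's genes, and a small drug-target table are joined against query
genes, reporting hypergeometric p-values with BH FDR control.
"""

import networkx as nx

from crossnet import (
    DrugTargetTable, gen_catalog, gene_universe,
    hypergeom_enrich, map_drugs, match_complexes,
)
from crossnet.topology import clique_k_subnetwork

universe = gene_universe(500)
query = universe[40:70]
catalog, _ = gen_catalog(universe, 25, (15, 40), planted=[("PLANTED", query[:20])], seed=3)

enr = hypergeom_enrich(query, catalog, universe)
best = enr.iloc[0]
print(f"top enriched set: {best['set_id']} "
      f"(overlap {best['overlap']}/{best['set_size']}, p={best['p_value']:.2e}, "
      f"q={best['q_value']:.2e}) of {len(enr)} sets tested")

clique_genes = ["CD4", "FCGR3A", "ZAP70", "LCK", "PTPRC"]
g = nx.complete_graph(len(clique_genes))
g = nx.relabel_nodes(g, dict(enumerate(clique_genes)))
complexes, _ = gen_catalog(universe + clique_genes, 10, (3, 8),
                           planted=[("TCR_COMPLEX", clique_genes[:4])], seed=4)
matches = match_complexes(clique_k_subnetwork(g, 5), complexes, universe + clique_genes)
print(f"best complex match: {matches.iloc[0]['set_id']} "
      f"(overlap coefficient {matches.iloc[0]['overlap_coefficient']:.2f})")

drugs = DrugTargetTable.from_rows([
    ("DB00002", "FCGR3A", "Cetuximab", "Immune"),
    ("DB01254", "LCK", "Dasatinib", "Tyrosine kinase inhibitor"),
    ("DB02010", "LCK", "Indolocarbazole", "Protein kinase C inhibitor"),
    ("DB02010", "ZAP70", "Indolocarbazole", "Protein kinase C inhibitor"),
])
mapped = map_drugs(set(clique_genes), drugs)
print("drug hits:")
print(mapped.to_string(index=False))
# Indolocarbazole matches two clique genes, so it sorts first: drugs hitting
# several genes of one candidate complex are the most interesting leads.
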