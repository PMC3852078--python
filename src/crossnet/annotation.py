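"""Gene-set cross-referencing: suppressor overlap, complex matching, drug mapping.

Three join-style stages sit downstream of the network analysis: intersecting
candidate gene lists with a reference catalog (e.g. tumor-suppressor genes),
matching clique-derived candidate complexes against a complex catalog by
hypergeometric overlap, and mapping network/clique genes to drug targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .catalogs import AnnotationCatalog, DrugTargetTable
from .interactome import QueryNetwork
from .significance import benjamini_hochberg, hypergeom_pvalue
from .topology import CliqueSet


@dataclass
class OverlapReport:
    """Intersections of labelled gene lists with a reference set.

    Fractions are percentages of the reference size; ``union_*`` fields
    describe the overlap of the union of all lists with the reference.
    """

    reference_size: int
    per_list: dict[str, dict] = field(default_factory=dict)
    union_overlap_count: int = 0
    union_overlap_genes: list[str] = field(default_factory=list)
    union_fraction_of_reference: float = 0.0


def gene_set_overlap(reference: Iterable[str], lists: Mapping[str, Iterable[str]]) -> OverlapReport:
    """Exact intersections of each labelled list (and their union) with ``reference``."""
    reference = set(reference)
    ref_n = len(reference)
    report = OverlapReport(reference_size=ref_n)
    union: set[str] = set()
    for label, genes in lists.items():
        genes = set(genes)
        union |= genes
        inter = sorted(reference & genes)
        report.per_list[label] = {
            "list_size": len(genes),
            "overlap_count": len(inter),
            "overlap_genes": inter,
            "overlap_fraction_of_reference": (100.0 * len(inter) / ref_n) if ref_n else 0.0,
        }
    u_inter = sorted(reference & union)
    report.union_overlap_count = len(u_inter)
    report.union_overlap_genes = u_inter
    report.union_fraction_of_reference = (100.0 * len(u_inter) / ref_n) if ref_n else 0.0
    return report


def match_complexes(
    cliques: CliqueSet,
    catalog: AnnotationCatalog,
    universe: Iterable[str],
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Rank catalog complexes against each clique by hypergeometric overlap.

    Matching is scored, not exact-containment: a catalog complex counts as a
    match when it shares at least ``min_overlap`` genes with the clique.
    Each (clique, complex) pair gets a one-sided hypergeometric p and the
    overlap coefficient |clique ∩ complex| / |clique|; BH correction runs
    across all reported pairs.  Rows are sorted per clique by (p, set id).
    """
    universe = set(universe)
    rows = []
    for clique in cliques.cliques:
        cset = set(clique) & universe
        for set_id in sorted(catalog.entries):
            genes = catalog.genes(set_id) & universe
            inter = sorted(cset & genes)
            if len(inter) < min_overlap:
                continue
            rows.append(
                {
                    "clique": ",".join(clique),
                    "set_id": set_id,
                    "description": catalog.description(set_id),
                    "set_size": len(genes),
                    "overlap": len(inter),
                    "overlap_genes": ",".join(inter),
                    "overlap_coefficient": len(inter) / len(clique),
                    "p_value": hypergeom_pvalue(len(inter), len(universe), len(genes), len(cset)),
                }
            )
    cols = [
        "clique", "set_id", "description", "set_size", "overlap",
        "overlap_genes", "overlap_coefficient", "p_value",
    ]
    tbl = pd.DataFrame(rows, columns=cols)
    if len(tbl):
        tbl["q_value"] = benjamini_hochberg(tbl["p_value"].tolist())
        tbl = tbl.sort_values(["clique", "p_value", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        tbl["q_value"] = []
    return tbl


def map_drugs(network: QueryNetwork | CliqueSet | Iterable[str], drugs: DrugTargetTable) -> pd.DataFrame:
    """Join network/clique genes to drug targets, grouped by drug.

    Returns one row per drug with its matched genes (always a subset of the
    input gene set), sorted by number of matched genes descending then drug
    id.  The drug-class vocabulary is free text from the input table.
    """
    if isinstance(network, QueryNetwork):
        genes = network.nodes
    elif isinstance(network, CliqueSet):
        genes = set(network.subnetwork_nodes)
    else:
        genes = set(network)
    hits = drugs.table[drugs.table["gene"].isin(genes)]
    if hits.empty:
        return pd.DataFrame(columns=["drug_id", "drug_name", "drug_class", "n_genes", "genes"])
    grouped = (
        hits.groupby(["drug_id", "drug_name", "drug_class"], sort=False)["gene"]
        .apply(lambda s: sorted(set(s)))
        .reset_index()
        .rename(columns={"gene": "genes"})
    )
    grouped["n_genes"] = grouped["genes"].str.len()
    grouped["genes"] = grouped["genes"].str.join(",")
    grouped = grouped.sort_values(
        ["n_genes", "drug_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return grouped[["drug_id", "drug_name", "drug_class", "n_genes", "genes"]]
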