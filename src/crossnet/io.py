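"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: expression TSV (first column probe id, header row of sample ids)
plus a two-column sample->group TSV; edge-list TSV / SIF; GMT (set id, TAB,
description, TAB, genes...); four-column drug-target TSV; one-symbol-per-line
universe files; candidate-gene TSV; query-network edge + node-attribute TSV;
JSON for ground truth and null-test reports.
"""

from __future__ import annotations

import json
from typing import Iterable

import pandas as pd

from .catalogs import AnnotationCatalog, DrugTargetTable, DRUG_COLUMNS
from .errors import ParseError
from .expression import CandidateGeneSet, ExpressionMatrix
from .interactome import Interactome, QueryNetwork
from .significance import NullTestResult
from .synthetic import GroundTruth

# -- expression ---------------------------------------------------------------


def write_expression(expr: ExpressionMatrix, expr_path, groups_path) -> None:
    df = pd.DataFrame(expr.values, index=expr.probe_ids, columns=expr.sample_ids)
    df.index.name = "probe"
    df.to_csv(expr_path, sep="\t", float_format="%.6g")
    with open(groups_path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.groups[s]}\n")


def read_expression(expr_path, groups_path, gene_of_probe: dict[str, str] | None = None) -> ExpressionMatrix:
    df = pd.read_csv(expr_path, sep="\t", index_col=0)
    groups: dict[str, str] = {}
    with open(groups_path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or (lineno == 1 and line.lower().startswith("sample")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError("expected 'sample<TAB>group'", groups_path, lineno)
            groups[parts[0]] = parts[1]
    return ExpressionMatrix(
        probe_ids=[str(p) for p in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        groups=groups,
        gene_of_probe=gene_of_probe or {},
    )


# -- gene sets / candidate sets ----------------------------------------------


def write_candidate_set(cs: CandidateGeneSet, path) -> None:
    """3-column TSV: gene, direction, provenance (label:direction;...)."""
    with open(path, "w") as fh:
        fh.write("gene\tdirection\tprovenance\n")
        for gene in sorted(cs.members):
            prov = ";".join(f"{lab}:{d}" for lab, d in cs.provenance.get(gene, []))
            fh.write(f"{gene}\t{cs.members[gene]}\t{prov}\n")


def read_candidate_set(path, label: str = "loaded", disease: str = "other") -> CandidateGeneSet:
    members: dict[str, str] = {}
    provenance: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("gene\t")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected gene<TAB>direction[<TAB>provenance]", path, lineno)
            gene, direction = parts[0], parts[1]
            members[gene] = direction
            if len(parts) > 2 and parts[2]:
                provenance[gene] = [
                    tuple(item.split(":", 1)) for item in parts[2].split(";") if ":" in item
                ]
    return CandidateGeneSet(label=label, disease=disease, members=members, provenance=provenance)


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(f"{g}\n")


def read_gene_list(path) -> list[str]:
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# -- GMT ----------------------------------------------------------------------


def write_gmt(catalog: AnnotationCatalog, path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(catalog.entries):
            desc, genes = catalog.entries[set_id]
            fh.write("\t".join([set_id, desc, *sorted(genes)]) + "\n")


def read_gmt(path) -> AnnotationCatalog:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs set id, description, >=1 gene", path, lineno)
            sets[parts[0]] = [g for g in parts[2:] if g]
            descriptions[parts[0]] = parts[1]
    return AnnotationCatalog.from_sets(sets, descriptions)


# -- interactome / networks ---------------------------------------------------


def write_interactome(net: Interactome, path, dialect: str = "tsv") -> None:
    with open(path, "w") as fh:
        if dialect == "sif":
            for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
                fh.write(f"{a}\tinteracts\t{b}\n")
            for v in sorted(net.nodes):
                if net.graph.degree(v) == 0:
                    fh.write(f"{v}\n")
        else:
            for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
                fh.write(f"{a}\t{b}\n")


def write_query_network(qn: QueryNetwork, edges_path, nodes_path) -> None:
    """Edge TSV plus node-attribute TSV (node, role, disease, direction)."""
    with open(edges_path, "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in sorted(tuple(sorted(e)) for e in qn.graph.edges):
            fh.write(f"{a}\t{b}\n")
    with open(nodes_path, "w") as fh:
        fh.write("node\trole\tdisease\tdirection\n")
        for v in sorted(qn.nodes):
            ann = qn.annotations.get(v, {})
            fh.write(
                f"{v}\t{qn.role_of_node(v)}\t{ann.get('disease', '')}\t{ann.get('direction', '')}\n"
            )


# -- drug tables --------------------------------------------------------------


def write_drug_table(drugs: DrugTargetTable, path) -> None:
    drugs.table.to_csv(path, sep="\t", index=False)


def read_drug_table(path) -> DrugTargetTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != DRUG_COLUMNS:
        # accept header-style variants ("Drug ID", "Gene Name", ...)
        if len(df.columns) == 4:
            df.columns = DRUG_COLUMNS
        else:
            raise ParseError(f"expected 4 columns {DRUG_COLUMNS}, got {list(df.columns)}", path)
    return DrugTargetTable(df)


# -- JSON reports -------------------------------------------------------------


def write_ground_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def null_result_to_dict(res: NullTestResult) -> dict:
    def stat(s):
        return {
            "observed": s.observed,
            "null_mean": s.null_mean,
            "null_sd": s.null_sd,
            "percentile_top": s.percentile_top,
            "p_empirical": s.p_empirical,
        }

    return {
        "subgraphs": stat(res.subgraphs),
        "qqppi_edges": stat(res.qqppi_edges),
        "n_draws": res.n_draws,
        "n_query": res.n_query,
        "seed": res.seed,
        "min_component_size": res.min_component_size,
    }


def write_null_result(res: NullTestResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(null_result_to_dict(res), fh, indent=2, sort_keys=True)
        fh.write("\n")
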