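"""End-to-end orchestration: config validation, stage execution, manifest.

The pipeline runs the full workflow from a single YAML config: DE selection
on two expression datasets (p-threshold for the first, top-fraction for the
second) -> merged candidate list -> QQPPI/L1PPI networks -> mediator overlap
-> centralities + MCL modules -> clique-k subnetworks + complex matching ->
connectivity null -> pathway enrichment with BH -> tumor-suppressor overlap
-> drug mapping.  Every stage's parameters and output checksums land in a
machine-readable run manifest; a rerun with the same config is bit-identical.

One base seed is declared in the config and split per stage by hashing the
stage name, so reordering stages cannot silently change results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as cio
from .annotation import gene_set_overlap, map_drugs, match_complexes
from .errors import ConfigError
from .expression import merge_gene_sets, select_by_pvalue, select_top_fraction
from .interactome import assemble_networks, load_interactome, mediator_overlap
from .significance import connectivity_null, hypergeom_enrich
from .topology import clique_k_subnetwork, connected_subgraphs, mcl, score_and_rank

REQUIRED_PATHS = ["expr1", "groups1", "expr2", "groups2", "interactome", "universe", "pathways_gmt"]
OPTIONAL_PATHS = ["complexes_gmt", "tsg_gmt", "drug_table"]
DEFAULTS = {
    "alpha": 0.05,
    "top_fraction": 0.01,
    "clique_k": [4, 5],
    "mcl_inflation": 2.0,
    "null_draws": 5000,
    "seed": 0,
    "outdir": "crossnet_out",
    "disease1": "schizophrenia",
    "disease2": "cancer",
}


@dataclass
class PipelineConfig:
    paths: dict[str, str]
    alpha: float = 0.05
    top_fraction: float = 0.01
    clique_k: list[int] = field(default_factory=lambda: [4, 5])
    mcl_inflation: float = 2.0
    null_draws: int = 5000
    seed: int = 0
    outdir: str = "crossnet_out"
    disease1: str = "schizophrenia"
    disease2: str = "cancer"


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2^31) from the base seed and stage name."""
    digest = hashlib.blake2s(f"{base_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML config, reporting all violations at once."""
    problems: list[str] = []
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError:
        raise ConfigError([f"config file not found: {path}"])
    except yaml.YAMLError as e:
        raise ConfigError([f"config is not valid YAML: {e}"])
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping of keys to values"])

    base = Path(path).parent
    paths: dict[str, str] = {}
    for key in REQUIRED_PATHS + OPTIONAL_PATHS:
        value = raw.pop(key, None)
        if value is None:
            if key in REQUIRED_PATHS:
                problems.append(f"missing required path: {key}")
            continue
        p = Path(value)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            problems.append(f"{key}: file does not exist: {p}")
        paths[key] = str(p)

    params = dict(DEFAULTS)
    params.pop("outdir")
    outdir = raw.pop("outdir", DEFAULTS["outdir"])
    for key in list(params):
        if key in raw:
            params[key] = raw.pop(key)
    for key in raw:
        problems.append(f"unknown config key: {key}")

    if not (isinstance(params["alpha"], (int, float)) and 0 < params["alpha"] < 1):
        problems.append(f"alpha must be in (0,1), got {params['alpha']!r}")
    if not (isinstance(params["top_fraction"], (int, float)) and 0 < params["top_fraction"] <= 0.5):
        problems.append(f"top_fraction must be in (0,0.5], got {params['top_fraction']!r}")
    ks = params["clique_k"]
    if not (isinstance(ks, list) and ks and all(isinstance(k, int) and k >= 3 for k in ks)):
        problems.append(f"clique_k must be a non-empty list of integers >= 3, got {ks!r}")
    if not (isinstance(params["mcl_inflation"], (int, float)) and params["mcl_inflation"] > 1):
        problems.append(f"mcl_inflation must be > 1, got {params['mcl_inflation']!r}")
    if not (isinstance(params["null_draws"], int) and params["null_draws"] >= 1):
        problems.append(f"null_draws must be a positive integer, got {params['null_draws']!r}")
    if not isinstance(params["seed"], int):
        problems.append(f"seed must be an integer, got {params['seed']!r}")

    if problems:
        raise ConfigError(problems)
    return PipelineConfig(paths=paths, outdir=str(outdir), **params)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the run manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = {"seed": stage_seed(config.seed, stage), **info}

    # 1-2: DE selection, one rule per dataset
    expr1 = cio.read_expression(config.paths["expr1"], config.paths["groups1"])
    set1 = select_by_pvalue(expr1, alpha=config.alpha, label="de_pvalue", disease=config.disease1)
    cio.write_candidate_set(set1, out / "candidates_disease1.tsv")
    record("de_pvalue", alpha=config.alpha, n_selected=len(set1))

    expr2 = cio.read_expression(config.paths["expr2"], config.paths["groups2"])
    set2 = select_top_fraction(
        expr2, fraction=config.top_fraction, label="de_top", disease=config.disease2
    )
    cio.write_candidate_set(set2, out / "candidates_disease2.tsv")
    record("de_top_fraction", fraction=config.top_fraction, n_selected=len(set2))

    # 3: merge into the combined candidate list
    merged = merge_gene_sets([set1, set2], label="combined", disease="combined")
    cio.write_candidate_set(merged, out / "candidates_combined.tsv")
    record("merge", n_genes=len(merged))

    # 4: QQPPI / L1PPI construction
    net = load_interactome(config.paths["interactome"], uppercase=False)
    qq, l1 = assemble_networks(net, merged)
    cio.write_query_network(qq, out / "qqppi_edges.tsv", out / "qqppi_nodes.tsv")
    cio.write_query_network(l1, out / "l1ppi_edges.tsv", out / "l1ppi_nodes.tsv")
    n_sub, _ = connected_subgraphs(qq.graph)
    record(
        "networks",
        qqppi_nodes=len(qq.nodes), qqppi_edges=qq.graph.number_of_edges(),
        qqppi_subgraphs=n_sub,
        l1ppi_nodes=len(l1.nodes), l1ppi_edges=l1.graph.number_of_edges(),
        n_mediators=len(l1.mediators),
    )

    # 5: mediator overlap between the two disease query lists
    ov = mediator_overlap(net, [set1.genes(), set2.genes()], labels=[set1.label, set2.label])
    (out / "mediator_overlap.json").write_text(json.dumps({
        "list_labels": ov.list_labels,
        "interactor_counts": ov.interactor_counts,
        "common_all": ov.common_all,
        "common_any_two": ov.common_any_two,
        "shared_percentages": ov.shared_percentages,
    }, indent=2) + "\n")
    record("mediators", common_all=ov.common_all, common_any_two=ov.common_any_two)

    # 6: centralities + MCL modules on the QQPPI
    scores = {g: 1.0 for g in qq.nodes}
    ranking = score_and_rank(qq.graph, scores=scores)
    ranking.to_csv(out / "centrality.tsv", sep="\t", index=False)
    clusters = mcl(qq.graph, inflation=config.mcl_inflation)
    with open(out / "mcl_clusters.gmt", "w") as fh:
        for i, cluster in enumerate(clusters.clusters, 1):
            fh.write("\t".join([f"MCL{i:04d}", "mcl_module", *sorted(cluster)]) + "\n")
    record("topology", n_clusters=len(clusters.clusters), mcl_converged=clusters.converged)

    # 7: clique-k subnetworks on the L1PPI (+ complex matching)
    universe_syms = set(cio.read_gene_list(config.paths["universe"]))
    clique_sets = {}
    for k in config.clique_k:
        cs = clique_k_subnetwork(l1.graph, k)
        clique_sets[k] = cs
        with open(out / f"clique{k}.gmt", "w") as fh:
            for i, c in enumerate(cs.cliques, 1):
                fh.write("\t".join([f"CLIQUE{k}_{i:04d}", f"clique-{k}", *c]) + "\n")
        record(f"clique{k}", n_cliques=len(cs.cliques),
               subnetwork_nodes=len(cs.subnetwork_nodes),
               subnetwork_edges=len(cs.subnetwork_edges))
    if "complexes_gmt" in config.paths and clique_sets:
        complexes = cio.read_gmt(config.paths["complexes_gmt"])
        kmin = min(clique_sets)
        matches = match_complexes(
            clique_sets[kmin], complexes,
            universe=(complexes.all_genes() | net.nodes) & universe_syms or universe_syms,
        )
        matches.to_csv(out / "complex_matches.tsv", sep="\t", index=False)
        record("complexes", n_matches=len(matches))

    # 8: connectivity null for the first disease's query set
    null_res = connectivity_null(
        net,
        universe=sorted(universe_syms),
        n_query=len(set1),
        observed_queries=set1.genes(),
        n_draws=config.null_draws,
        seed=stage_seed(config.seed, "null"),
    )
    cio.write_null_result(null_res, out / "connectivity_null.json")
    record("null", n_draws=config.null_draws,
           percentile_top_edges=null_res.qqppi_edges.percentile_top)

    # 9: pathway enrichment of the L1PPI gene set
    pathways = cio.read_gmt(config.paths["pathways_gmt"])
    enrich_universe = (pathways.all_genes() | net.nodes) & universe_syms or universe_syms
    enr = hypergeom_enrich(l1.nodes, pathways, enrich_universe)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    record("enrichment", n_sets=len(enr),
           n_significant_q05=int((enr["q_value"] < 0.05).sum()) if len(enr) else 0)

    # 10: tumor-suppressor overlap (optional)
    if "tsg_gmt" in config.paths:
        tsg = cio.read_gmt(config.paths["tsg_gmt"])
        reference = tsg.all_genes()
        report = gene_set_overlap(reference, {set1.label: set1.genes(), set2.label: set2.genes()})
        (out / "tsg_overlap.json").write_text(json.dumps({
            "reference_size": report.reference_size,
            "per_list": report.per_list,
            "union_overlap_count": report.union_overlap_count,
            "union_fraction_of_reference": report.union_fraction_of_reference,
        }, indent=2) + "\n")
        record("tsg_overlap", union_overlap=report.union_overlap_count)

    # 11: drug mapping from the largest-k clique subnetwork (optional)
    if "drug_table" in config.paths and clique_sets:
        drugs = cio.read_drug_table(config.paths["drug_table"])
        kmax = max(clique_sets)
        mapped = map_drugs(clique_sets[kmax], drugs)
        mapped.to_csv(out / "drug_map.tsv", sep="\t", index=False)
        record("drugs", n_drugs=len(mapped))

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
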