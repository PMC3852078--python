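"""Ready-made synthetic input bundles for the full pipeline.

``simulate_bundle`` writes every input file the pipeline needs (two
expression datasets, an interactome, a symbol universe, pathway/complex/
tumor-suppressor catalogs, a drug-target table) plus a ready-to-run
``run.yaml``, and returns the paths.

The ``paper-shaped`` preset is sized like a two-disease microarray study:
a 23-vs-19 sample brain dataset over 2000 genes whose p<0.05 selection
yields roughly 470 candidates (~60% planted signal at d=2, the rest type-I
calls), a 225-vs-220 tumor/normal dataset over 12624 genes from which the
top-1% rule takes 126+126 candidates, a ~3000-node interactome with planted
cliques, and a 32560-symbol universe for the connectivity null.  The
``smoke`` preset is a miniature of the same design for fast tests.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .errors import ParameterError
from .synthetic import (
    ExpressionSimSpec,
    InteractomeSimSpec,
    gen_catalog,
    gen_drug_table,
    gen_expression,
    gen_interactome,
    gene_universe,
)

PRESETS = {
    "paper-shaped": {
        "universe_size": 32560,
        "expr1": dict(n_genes=2000, n_case=23, n_control=19,
                      frac_over=0.06, frac_under=0.135, effect_size=2.0),
        "expr2": dict(n_genes=12624, n_case=225, n_control=220,
                      frac_over=0.02, frac_under=0.02, effect_size=1.5),
        "interactome_nodes": 3000,
        "edge_p": 0.0023,
        "n_planted_cliques": (2, 3),  # (5-cliques, 4-cliques)
        "n_pathways": 40,
        "pathway_size": (10, 50),
        "n_complexes": 20,
        "complex_size": (3, 8),
        "tsg_size": 716,
        "n_drugs": 50,
        "null_draws": 5000,
    },
    "smoke": {
        "universe_size": 800,
        "expr1": dict(n_genes=300, n_case=10, n_control=10,
                      frac_over=0.1, frac_under=0.1, effect_size=2.5),
        "expr2": dict(n_genes=600, n_case=15, n_control=15,
                      frac_over=0.05, frac_under=0.05, effect_size=2.5),
        "interactome_nodes": 300,
        "edge_p": 0.02,
        "n_planted_cliques": (1, 2),
        "n_pathways": 10,
        "pathway_size": (5, 20),
        "n_complexes": 8,
        "complex_size": (3, 6),
        "tsg_size": 60,
        "n_drugs": 15,
        "null_draws": 200,
    },
}

DRUG_CLASSES = ["Immune", "Retinoids", "Sex hormone", "Anti-cancer",
                "Tyrosine kinase inhibitor", "Thyroid hormone"]


def simulate_bundle(outdir, preset: str = "paper-shaped", seed: int = 0) -> dict[str, str]:
    """Write a complete synthetic input bundle and run.yaml; return the paths."""
    if preset not in PRESETS:
        raise ParameterError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    universe = gene_universe(cfg["universe_size"])
    cio.write_gene_list(universe, out / "universe.txt")

    expr1, truth1 = gen_expression(
        ExpressionSimSpec(seed=int(rng.integers(2**31)), **cfg["expr1"])
    )
    cio.write_expression(expr1, out / "expr1.tsv", out / "groups1.tsv")
    cio.write_ground_truth(truth1, out / "truth_expr1.json")

    expr2, truth2 = gen_expression(
        ExpressionSimSpec(seed=int(rng.integers(2**31)), **cfg["expr2"])
    )
    cio.write_expression(expr2, out / "expr2.tsv", out / "groups2.tsv")
    cio.write_ground_truth(truth2, out / "truth_expr2.json")

    n_nodes = cfg["interactome_nodes"]
    nodes = universe[:n_nodes]
    n5, n4 = cfg["n_planted_cliques"]
    planted = []
    for size in [5] * n5 + [4] * n4:
        members = [nodes[i] for i in rng.choice(n_nodes // 2, size=size, replace=False)]
        planted.append(tuple(members))
    net, truth_net = gen_interactome(
        InteractomeSimSpec(
            n_nodes=n_nodes, model="erdos_renyi", density_param=cfg["edge_p"],
            planted_cliques=tuple(planted), seed=int(rng.integers(2**31)),
        ),
        node_labels=nodes,
    )
    cio.write_interactome(net, out / "interactome.tsv")
    cio.write_ground_truth(truth_net, out / "truth_interactome.json")

    lo, hi = cfg["pathway_size"]
    planted_pathway = [universe[i] for i in rng.choice(n_nodes // 3, size=min(30, lo + 10), replace=False)]
    pathways, truth_pw = gen_catalog(
        universe, cfg["n_pathways"], (lo, hi),
        planted=[("PATH_PLANTED", planted_pathway)],
        seed=int(rng.integers(2**31)), prefix="PATH",
    )
    cio.write_gmt(pathways, out / "pathways.gmt")

    complexes, _ = gen_catalog(
        universe, cfg["n_complexes"], cfg["complex_size"],
        planted=[(f"CPLX_PLANTED{i+1}", sorted(c)) for i, c in enumerate(truth_net.planted_cliques)],
        seed=int(rng.integers(2**31)), prefix="CPLX",
    )
    cio.write_gmt(complexes, out / "complexes.gmt")

    tsg, _ = gen_catalog(
        universe, 0, (cfg["tsg_size"], cfg["tsg_size"]),
        planted=[("TSG", [universe[i] for i in rng.choice(len(universe), size=cfg["tsg_size"], replace=False)])],
        seed=int(rng.integers(2**31)), prefix="TSG",
    )
    cio.write_gmt(tsg, out / "tsg.gmt")

    # drug targets: bias half the drugs toward planted-clique genes so the
    # clique->drug join has hits
    clique_genes = sorted({g for c in truth_net.planted_cliques for g in c})
    rows = []
    for d in range(cfg["n_drugs"]):
        drug_id = f"DB{d + 1:05d}"
        name = f"Drug{d + 1}"
        klass = DRUG_CLASSES[int(rng.integers(len(DRUG_CLASSES)))]
        if clique_genes and d % 2 == 0:
            gene = clique_genes[int(rng.integers(len(clique_genes)))]
        else:
            gene = nodes[int(rng.integers(n_nodes))]
        rows.append((drug_id, gene, name, klass))
    cio.write_drug_table(gen_drug_table(rows), out / "drugs.tsv")

    config = {
        "expr1": "expr1.tsv", "groups1": "groups1.tsv",
        "expr2": "expr2.tsv", "groups2": "groups2.tsv",
        "interactome": "interactome.tsv", "universe": "universe.txt",
        "pathways_gmt": "pathways.gmt", "complexes_gmt": "complexes.gmt",
        "tsg_gmt": "tsg.gmt", "drug_table": "drugs.tsv",
        "null_draws": cfg["null_draws"],
        "seed": seed,
        "outdir": str(out / "results"),
    }
    with open(out / "run.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return {k: str(out / v) if isinstance(v, str) and not str(v).startswith(str(out)) else v
            for k, v in config.items()} | {"config": str(out / "run.yaml")}
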