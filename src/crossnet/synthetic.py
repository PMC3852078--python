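"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis consumes can be simulated here: a two-group
Gaussian expression matrix with planted over/under-expressed genes, a sparse
interactome with planted cliques, gene-set catalogs with planted enriched
sets, a drug-target table, and a symbol universe for null draws.  All
generators are deterministic for a fixed seed and record their planted
structure in a :class:`GroundTruth` so recovery can be tested.

Expression values are Gaussian on a log-intensity-like scale: null genes are
i.i.d. Normal(baseline, noise_sd^2) in both groups, and a planted gene's
case mean is shifted by ±effect_size·noise_sd (a standardized Cohen's d
shift).  This matches the t-test's assumptions, so selection power and
type-I calibration have closed-form oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .catalogs import AnnotationCatalog, DrugTargetTable
from .errors import ParameterError
from .expression import ExpressionMatrix
from .interactome import Interactome


def gene_universe(n: int, prefix: str = "G") -> list[str]:
    """Synthetic gene-symbol universe: G000001 … G<n>."""
    if n < 0:
        raise ParameterError("universe size must be non-negative")
    return [f"{prefix}{i + 1:06d}" for i in range(n)]


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Two-group Gaussian expression simulation parameters.

    effect_size is a standardized mean shift (Cohen's d); noise_sd the
    within-group standard deviation on the log-intensity scale; baseline the
    grand mean of null genes.  probes_per_gene > 1 emits multiple probes per
    gene to exercise probe aggregation.
    """

    n_genes: int = 1000
    n_case: int = 23
    n_control: int = 19
    frac_over: float = 0.05
    frac_under: float = 0.05
    effect_size: float = 2.0
    noise_sd: float = 1.0
    baseline: float = 8.0
    probes_per_gene: int = 1
    seed: int | None = None

    def validate(self) -> None:
        if not (0 <= self.frac_over <= 1 and 0 <= self.frac_under <= 1):
            raise ParameterError("frac_over/frac_under must lie in [0,1]")
        if self.frac_over + self.frac_under > 1:
            raise ParameterError("frac_over + frac_under must be <= 1")
        if self.n_case < 2 or self.n_control < 2:
            raise ParameterError("need at least 2 samples per group")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be positive")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.probes_per_gene < 1:
            raise ParameterError("probes_per_gene must be >= 1")


@dataclass(frozen=True)
class InteractomeSimSpec:
    """Random-interactome parameters.

    ``model`` is "erdos_renyi" (density_param = edge probability) or
    "preferential_attachment" (density_param = integer edges per new node).
    ``planted_cliques`` entries are either an int size (members drawn at
    random) or an explicit gene list; planted cliques are fully connected in
    the output.
    """

    n_nodes: int = 1000
    model: str = "erdos_renyi"
    density_param: float = 0.005
    planted_cliques: tuple = ()
    seed: int | None = None

    def validate(self) -> None:
        if self.model not in ("erdos_renyi", "preferential_attachment"):
            raise ParameterError(f"unknown interactome model {self.model!r}")
        if self.model == "erdos_renyi" and not (0.0 <= self.density_param <= 1.0):
            raise ParameterError("edge probability must lie in [0,1]")
        if self.model == "preferential_attachment":
            m = self.density_param
            if m != int(m) or not (1 <= m < self.n_nodes):
                raise ParameterError("edges-per-new-node must be an integer in [1, n_nodes)")
        for c in self.planted_cliques:
            size = c if isinstance(c, int) else len(tuple(c))
            if size > self.n_nodes:
                raise ParameterError(f"planted clique of size {size} exceeds n_nodes={self.n_nodes}")
            if size < 2:
                raise ParameterError("planted cliques need >= 2 members")


@dataclass
class GroundTruth:
    """What was planted: DE genes, cliques, enriched sets."""

    over_genes: set[str] = field(default_factory=set)
    under_genes: set[str] = field(default_factory=set)
    planted_cliques: list[set[str]] = field(default_factory=list)
    enriched_pathways: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "over_genes": sorted(self.over_genes),
            "under_genes": sorted(self.under_genes),
            "planted_cliques": [sorted(c) for c in self.planted_cliques],
            "enriched_pathways": list(self.enriched_pathways),
        }


def gen_expression(spec: ExpressionSimSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a two-group expression matrix with planted DE genes."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = gene_universe(spec.n_genes)
    n_over = int(round(spec.frac_over * spec.n_genes))
    n_under = int(round(spec.frac_under * spec.n_genes))
    planted = rng.choice(spec.n_genes, size=n_over + n_under, replace=False)
    over_idx, under_idx = planted[:n_over], planted[n_over:]

    n_samples = spec.n_case + spec.n_control
    shift = np.zeros(spec.n_genes)
    shift[over_idx] = spec.effect_size * spec.noise_sd
    shift[under_idx] = -spec.effect_size * spec.noise_sd

    k = spec.probes_per_gene
    values = rng.normal(
        loc=spec.baseline, scale=spec.noise_sd, size=(spec.n_genes * k, n_samples)
    )
    # case columns first; planted genes get their case mean shifted on every probe
    values[:, : spec.n_case] += np.repeat(shift, k)[:, None]

    sample_ids = [f"case{i + 1:03d}" for i in range(spec.n_case)] + [
        f"ctrl{i + 1:03d}" for i in range(spec.n_control)
    ]
    groups = {s: ("case" if s.startswith("case") else "control") for s in sample_ids}
    if k == 1:
        probe_ids = list(genes)
        gene_of_probe = {g: g for g in genes}
    else:
        probe_ids = [f"{g}_p{j + 1}" for g in genes for j in range(k)]
        gene_of_probe = {f"{g}_p{j + 1}": g for g in genes for j in range(k)}
    expr = ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        values=values,
        groups=groups,
        gene_of_probe=gene_of_probe,
    )
    truth = GroundTruth(
        over_genes={genes[i] for i in over_idx},
        under_genes={genes[i] for i in under_idx},
    )
    return expr, truth


def gen_interactome(
    spec: InteractomeSimSpec, node_labels: Sequence[str] | None = None
) -> tuple[Interactome, GroundTruth]:
    """Simulate a simple undirected interactome with planted cliques."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = list(node_labels) if node_labels is not None else gene_universe(spec.n_nodes)
    if len(labels) != spec.n_nodes:
        raise ParameterError(f"need {spec.n_nodes} node labels, got {len(labels)}")
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if spec.model == "erdos_renyi":
        g = nx.fast_gnp_random_graph(spec.n_nodes, spec.density_param, seed=nx_seed)
    else:
        g = nx.barabasi_albert_graph(spec.n_nodes, int(spec.density_param), seed=nx_seed)
    g = nx.relabel_nodes(g, dict(enumerate(labels)))
    truth = GroundTruth()
    for c in spec.planted_cliques:
        if isinstance(c, int):
            members = [labels[i] for i in rng.choice(spec.n_nodes, size=c, replace=False)]
        else:
            members = list(c)
            unknown = set(members) - set(labels)
            if unknown:
                raise ParameterError(f"planted clique members not in node set: {sorted(unknown)}")
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                g.add_edge(a, b)
        truth.planted_cliques.append(set(members))
    return Interactome(g), truth


def gen_catalog(
    universe: Sequence[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    planted: Iterable[tuple[str, Iterable[str]]] = (),
    seed: int | None = None,
    prefix: str = "SET",
) -> tuple[AnnotationCatalog, GroundTruth]:
    """Random gene-set catalog with planted sets included verbatim."""
    lo, hi = set_size_range
    if not (1 <= lo <= hi):
        raise ParameterError(f"invalid set_size_range {set_size_range}")
    if hi > len(universe):
        raise ParameterError(f"set_size_range max {hi} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    truth = GroundTruth()
    for set_id, genes in planted:
        genes = list(genes)
        unknown = set(genes) - set(universe)
        if unknown:
            raise ParameterError(f"planted genes outside universe: {sorted(unknown)}")
        sets[set_id] = genes
        truth.enriched_pathways.append(set_id)
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = [universe[j] for j in rng.choice(len(universe), size=size, replace=False)]
        sets[f"{prefix}{i + 1:04d}"] = members
    return AnnotationCatalog.from_sets(sets), truth


def gen_drug_table(
    rows: Iterable[tuple[str, str, str, str]], seed: int | None = None
) -> DrugTargetTable:
    """Well-formed drug-target table; duplicate (drug, gene) pairs collapse."""
    return DrugTargetTable.from_rows(rows)
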