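"""Interactome model and query-network construction.

The interactome is an undirected simple graph whose nodes are gene symbols
and whose edges are protein-protein interactions.  Two query-driven
subnetworks are extracted from it:

* QQPPI (query-query): the induced subgraph on a query gene set — only
  direct interactions among the queries.
* L1PPI (level-one): the queries plus every interactome node directly
  connected to a query, with all edges among that node set.  Non-query
  nodes of an L1PPI network are called mediators (interactors).

Queries absent from the interactome are kept as isolated nodes: they still
count toward query-set size in downstream null tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .errors import ParameterError, ParseError
from .expression import CandidateGeneSet, direction_annotations

logger = logging.getLogger(__name__)


@dataclass
class Interactome:
    """Undirected simple PPI graph over gene symbols (no self-loops)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()) -> "Interactome":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                logger.warning("dropping self-loop on %s", a)
                continue
            g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node)) if node in self.graph else set()


@dataclass
class QueryNetwork:
    """A QQPPI or L1PPI network with per-node roles and annotations."""

    kind: str  # "QQPPI" | "L1PPI"
    queries: set[str]
    graph: nx.Graph
    annotations: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("QQPPI", "L1PPI"):
            raise ParameterError(f"kind must be QQPPI or L1PPI, got {self.kind!r}")
        for node in self.graph.nodes:
            self.graph.nodes[node]["role"] = "query" if node in self.queries else "mediator"
        if self.kind == "QQPPI" and not set(self.graph.nodes) <= self.queries:
            raise ParameterError("QQPPI network contains non-query nodes")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def mediators(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("role") == "mediator"}

    def role_of_node(self, node: str) -> str:
        return self.graph.nodes[node]["role"]


@dataclass
class MediatorOverlap:
    """Overlap statistics for the mediator (interactor) sets of several queries.

    ``shared_percentages[i] = 100 * common_all / interactor_counts[i]``.
    """

    list_labels: list[str]
    interactor_counts: list[int]
    common_all: int
    common_any_two: int
    shared_percentages: list[float] = field(default_factory=list)
    interactor_sets: list[set[str]] | None = None

    def __post_init__(self):
        if not self.shared_percentages:
            self.shared_percentages = [
                (100.0 * self.common_all / c) if c else 0.0 for c in self.interactor_counts
            ]

    @classmethod
    def from_counts(
        cls, interactor_counts: Sequence[int], common_all: int, common_any_two: int = 0,
        labels: Sequence[str] | None = None,
    ) -> "MediatorOverlap":
        """Build the report from already-tabulated counts (no graph needed)."""
        labels = list(labels) if labels else [f"list{i+1}" for i in range(len(interactor_counts))]
        return cls(labels, list(interactor_counts), common_all, common_any_two)


def load_interactome(path, dialect: str = "auto", uppercase: bool = True) -> Interactome:
    """Read an edge list from a 2-column TSV or a SIF file.

    TSV lines are ``a<TAB>b`` (whitespace also accepted); SIF lines are
    ``a interacts b [c …]`` yielding edges a-b, a-c, …  Duplicate edges and
    reversed duplicates collapse; self-loops are dropped with a warning.
    """
    path = str(path)
    if dialect == "auto":
        dialect = "sif" if path.endswith(".sif") else "tsv"
    if dialect not in ("tsv", "sif"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if uppercase:
                fields = [f.upper() for f in fields]
            if dialect == "tsv":
                if len(fields) < 2:
                    raise ParseError("expected two columns", path, lineno)
                pairs = [(fields[0], fields[1])]
            else:
                if len(fields) == 1:
                    g.add_node(fields[0])
                    continue
                if len(fields) < 3:
                    raise ParseError("SIF line needs source, relation, >=1 target", path, lineno)
                pairs = [(fields[0], t) for t in fields[2:]]
            for a, b in pairs:
                if a == b:
                    logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
                    continue
                g.add_edge(a, b)
    return Interactome(g)


def build_qqppi(
    net: Interactome,
    queries: Iterable[str],
    annotations: dict[str, dict[str, str]] | None = None,
) -> QueryNetwork:
    """Induced subgraph on the query set; absent queries become isolated nodes."""
    queries = set(queries)
    g = nx.Graph()
    g.add_nodes_from(queries)
    present = queries & set(net.graph.nodes)
    g.add_edges_from(net.graph.subgraph(present).edges)
    return QueryNetwork("QQPPI", queries, g, annotations or {})


def build_l1ppi(
    net: Interactome,
    queries: Iterable[str],
    annotations: dict[str, dict[str, str]] | None = None,
    mediator_edges: bool = True,
) -> QueryNetwork:
    """Queries plus their direct neighbors, with the edges among them.

    By default the full induced subgraph on queries ∪ neighbors is returned
    (mediator-mediator edges kept); ``mediator_edges=False`` keeps only
    edges incident to a query ("star" variant).
    """
    queries = set(queries)
    present = queries & set(net.graph.nodes)
    mediators = set()
    for q in present:
        mediators |= set(net.graph.neighbors(q))
    mediators -= queries
    node_set = queries | mediators
    g = nx.Graph()
    g.add_nodes_from(node_set)
    induced = net.graph.subgraph(node_set & set(net.graph.nodes))
    if mediator_edges:
        g.add_edges_from(induced.edges)
    else:
        g.add_edges_from((a, b) for a, b in induced.edges if a in queries or b in queries)
    return QueryNetwork("L1PPI", queries, g, annotations or {})


def assemble_networks(
    net: Interactome, shc_gene: CandidateGeneSet, mediator_edges: bool = True
) -> tuple[QueryNetwork, QueryNetwork]:
    """Build the merged-candidate (QQPPI, L1PPI) pair with node annotations."""
    if not shc_gene.members:
        raise ParameterError("candidate gene set is empty")
    ann = {
        gene: {"disease": shc_gene.disease, "direction": direction,
               "sources": ";".join(f"{lab}:{d}" for lab, d in shc_gene.provenance.get(gene, []))}
        for gene, direction in shc_gene.members.items()
    }
    queries = shc_gene.genes()
    return (
        build_qqppi(net, queries, annotations=ann),
        build_l1ppi(net, queries, annotations=ann, mediator_edges=mediator_edges),
    )


def mediator_overlap(
    net: Interactome,
    query_lists: Sequence[Iterable[str]],
    labels: Sequence[str] | None = None,
    include_queries: bool = False,
) -> MediatorOverlap:
    """Overlap of the L1PPI interactor sets induced by several query lists.

    An "interactor" is a mediator (non-query) node of the L1PPI network;
    ``include_queries=True`` instead counts every L1PPI node, the alternative
    reading under which query genes reached by another list also count.
    ``common_all`` is the size of the intersection over all lists;
    ``common_any_two`` the size of the union of pairwise intersections.
    """
    if len(query_lists) < 2:
        raise ParameterError("mediator_overlap needs at least 2 query lists")
    labels = list(labels) if labels else [f"list{i+1}" for i in range(len(query_lists))]
    if len(labels) != len(query_lists):
        raise ParameterError("labels/query_lists length mismatch")
    sets: list[set[str]] = []
    for ql in query_lists:
        l1 = build_l1ppi(net, ql)
        sets.append(l1.nodes if include_queries else l1.mediators)
    common_all = set.intersection(*sets)
    any_two: set[str] = set()
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            any_two |= sets[i] & sets[j]
    return MediatorOverlap(
        list_labels=labels,
        interactor_counts=[len(s) for s in sets],
        common_all=len(common_all),
        common_any_two=len(any_two),
        interactor_sets=sets,
    )
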