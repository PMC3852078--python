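"""Graph analytics for disease networks: components, cliques, centrality, MCL.

Clique-k subnetworks (unions of all complete k-subgraphs) serve as candidate
protein complexes; Markov clustering (MCL) partitions a network into flow
modules; betweenness/closeness centralities rank genes by their mediating
position.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError


@dataclass
class CliqueSet:
    """All complete k-subgraphs of a graph plus their union subnetwork."""

    k: int
    cliques: list[tuple[str, ...]]
    subnetwork_nodes: set[str] = field(default_factory=set)
    subnetwork_edges: set[frozenset] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.cliques)


@dataclass
class ClusterResult:
    clusters: list[set[str]]
    params: dict
    converged: bool = True
    n_iter: int = 0


def connected_subgraphs(g: nx.Graph, min_size: int = 2) -> tuple[int, list[set[str]]]:
    """Connected components; the count includes only components with >= min_size nodes.

    An edgeless gene is not a network, so with the default ``min_size=2``
    isolated nodes do not count as subgraphs; pass ``min_size=1`` to count
    every component.
    """
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return sum(1 for c in comps if len(c) >= min_size), comps


def maximal_cliques(g: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques (Bron-Kerbosch with pivoting), canonically ordered.

    Each clique is a sorted tuple; the list is ordered by size descending,
    then lexicographically, so output is diff-stable.
    """
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g)]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def clique_k_subnetwork(g: nx.Graph, k: int) -> CliqueSet:
    """All k-subsets that are complete in ``g``, with their union subnetwork.

    Enumerated from the maximal cliques of size >= k; the subnetwork is the
    union of clique vertices and within-clique edges.
    """
    if k < 3:
        raise ParameterError(f"clique size k must be >= 3, got {k}")
    seen: set[tuple[str, ...]] = set()
    for mc in maximal_cliques(g):
        if len(mc) < k:
            continue
        for sub in itertools.combinations(mc, k):
            seen.add(sub)  # mc is sorted, so sub is canonical
    cliques = sorted(seen)
    nodes: set[str] = set()
    edges: set[frozenset] = set()
    for c in cliques:
        nodes.update(c)
        edges.update(frozenset(p) for p in itertools.combinations(c, 2))
    return CliqueSet(k=k, cliques=cliques, subnetwork_nodes=nodes, subnetwork_edges=edges)


def centralities(g: nx.Graph, scores: dict[str, float] | None = None) -> pd.DataFrame:
    """Degree, betweenness and closeness per node.

    Betweenness is exact (Brandes), unnormalized pair counts.  Closeness is
    the harmonic variant scaled by 1/(n-1) so it stays in [0, 1] and is well
    defined on disconnected graphs; an isolated node scores 0.
    """
    n = g.number_of_nodes()
    bet = nx.betweenness_centrality(g, normalized=False)
    harm = nx.harmonic_centrality(g)
    denom = max(n - 1, 1)
    rows = [
        {
            "node": v,
            "degree": g.degree(v),
            "betweenness": bet[v],
            "closeness": harm[v] / denom,
            "score": (scores or {}).get(v, np.nan),
        }
        for v in g.nodes
    ]
    return pd.DataFrame(rows).sort_values("node", kind="mergesort").reset_index(drop=True)


def score_and_rank(g: nx.Graph, scores: dict[str, float] | None = None) -> pd.DataFrame:
    """Rank nodes by (betweenness desc, score desc, symbol asc)."""
    tbl = centralities(g, scores=scores)
    tbl["_score"] = tbl["score"].fillna(-np.inf)
    tbl = tbl.sort_values(
        ["betweenness", "_score", "node"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="_score").reset_index(drop=True)
    tbl.insert(0, "rank", np.arange(1, len(tbl) + 1))
    return tbl


def mcl(
    g: nx.Graph,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_threshold: float = 1e-5,
    max_iter: int = 100,
    self_loop_weight: float = 1.0,
    tol: float = 1e-8,
) -> ClusterResult:
    """Markov Cluster algorithm on an unweighted graph.

    The column-stochastic flow matrix (adjacency plus self-loops) is iterated
    by expansion (matrix power) then inflation (entrywise power followed by
    column renormalization), pruning entries below ``prune_threshold``, until
    the matrix change falls below ``tol`` or ``max_iter`` is reached.
    Clusters are read from attractor rows (positive diagonal); every node is
    assigned to exactly one cluster, ties going to the lexicographically
    smallest attractor.
    """
    if inflation <= 1.0:
        raise ParameterError(f"inflation must be > 1, got {inflation}")
    if expansion < 2:
        raise ParameterError(f"expansion must be >= 2, got {expansion}")
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        return ClusterResult([], _mcl_params(inflation, expansion, prune_threshold, max_iter))
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b in g.edges:
        m[idx[a], idx[b]] = 1.0
        m[idx[b], idx[a]] = 1.0
    np.fill_diagonal(m, self_loop_weight)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m ** inflation
        m[m < prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0  # fully pruned column: leave as zeros
        m /= colsum
        if np.max(np.abs(m - prev)) < tol:
            converged = True
            break

    thr = prune_threshold
    attractors = [i for i in range(n) if m[i, i] > thr]
    owner = np.full(n, -1, dtype=int)
    for i in attractors:  # ascending => lexicographically smallest attractor wins ties
        support = np.nonzero(m[i] > thr)[0]
        for j in support:
            if owner[j] == -1:
                owner[j] = i
    for j in range(n):  # unreached nodes: strongest incoming flow, else singleton
        if owner[j] == -1:
            col = m[:, j]
            owner[j] = int(np.argmax(col)) if col.max() > 0 else j
    groups: dict[int, set[str]] = {}
    for j in range(n):
        groups.setdefault(owner[j], set()).add(nodes[j])
    clusters = sorted(groups.values(), key=lambda c: (-len(c), min(c)))
    return ClusterResult(
        clusters=clusters,
        params=_mcl_params(inflation, expansion, prune_threshold, max_iter),
        converged=converged,
        n_iter=it,
    )


def _mcl_params(inflation, expansion, prune_threshold, max_iter) -> dict:
    return {
        "inflation": inflation,
        "expansion": expansion,
        "prune_threshold": prune_threshold,
        "max_iter": max_iter,
    }
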