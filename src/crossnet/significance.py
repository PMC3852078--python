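"""Statistical procedures: connectivity permutation null and set enrichment.

The connectivity null asks whether an observed query gene set is more
interconnected in the interactome than random gene sets of the same size
drawn from a symbol universe (which may include genes absent from the
interactome — those appear as isolated query nodes).  Two statistics are
tracked per draw: the number of connected subgraphs (components with at
least two nodes) and the number of QQPPI edges.

Enrichment is the one-sided hypergeometric over-representation test with
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _cc
from scipy.stats import hypergeom

from .catalogs import AnnotationCatalog
from .errors import ParameterError
from .interactome import Interactome


@dataclass
class NullStat:
    """Empirical null summary for one connectivity statistic."""

    observed: float
    null_mean: float
    null_sd: float
    percentile_top: float  # 100 * fraction of null draws with stat >= observed
    p_empirical: float  # add-one empirical p, (r+1)/(n+1)


@dataclass
class NullTestResult:
    subgraphs: NullStat
    qqppi_edges: NullStat
    n_draws: int
    n_query: int
    seed: int | None
    min_component_size: int = 2

    @property
    def observed(self) -> tuple[float, float]:
        return (self.subgraphs.observed, self.qqppi_edges.observed)


def empirical_percentile_top(null_values: Sequence[float], observed: float) -> float:
    """Percent of null draws with statistic >= observed (the observed 'rank')."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ParameterError("null sample is empty")
    return 100.0 * float(np.count_nonzero(null_values >= observed)) / null_values.size


def _summarize(null_values: np.ndarray, observed: float, n_draws: int) -> NullStat:
    r = int(np.count_nonzero(null_values >= observed))
    return NullStat(
        observed=float(observed),
        null_mean=float(null_values.mean()),
        null_sd=float(null_values.std(ddof=1)) if n_draws > 1 else 0.0,
        percentile_top=100.0 * r / n_draws,
        p_empirical=(r + 1) / (n_draws + 1),
    )


class _QQStats:
    """Fast (subgraph count, edge count) for query sets via a sparse adjacency."""

    def __init__(self, net: Interactome, min_component_size: int = 2):
        self.nodes = sorted(net.graph.nodes)
        self.index = {v: i for i, v in enumerate(self.nodes)}
        self.adj = sparse.csr_matrix(
            nx_adjacency(net, self.nodes), shape=(len(self.nodes), len(self.nodes))
        )
        self.min_size = min_component_size

    def __call__(self, queries: Iterable[str]) -> tuple[int, int]:
        idx = np.array(sorted(self.index[q] for q in queries if q in self.index), dtype=int)
        if idx.size == 0:
            return 0, 0
        sub = self.adj[idx][:, idx]
        n_edges = int(sub.nnz // 2)
        if n_edges == 0:
            return 0, 0
        n_comp, labels = _cc(sub, directed=False)
        counts = np.bincount(labels, minlength=n_comp)
        return int(np.count_nonzero(counts >= self.min_size)), n_edges


def nx_adjacency(net: Interactome, nodes: list[str]) -> sparse.coo_matrix:
    index = {v: i for i, v in enumerate(nodes)}
    rows, cols = [], []
    for a, b in net.graph.edges:
        rows += [index[a], index[b]]
        cols += [index[b], index[a]]
    data = np.ones(len(rows))
    return sparse.coo_matrix((data, (rows, cols)), shape=(len(nodes), len(nodes)))


def connectivity_null(
    net: Interactome,
    universe: Sequence[str],
    n_query: int,
    observed_queries: Iterable[str],
    n_draws: int = 5000,
    seed: int | None = None,
    min_component_size: int = 2,
) -> NullTestResult:
    """Connectivity of an observed query set vs. random same-size gene sets.

    Each draw samples ``n_query`` symbols uniformly without replacement from
    ``universe`` (which may include non-interactome symbols), builds the
    QQPPI, and records (subgraph count, edge count).  ``percentile_top`` is
    the percent of draws at or above the observed value; ``p_empirical`` the
    add-one version (r+1)/(n+1).
    """
    universe = list(universe)
    if n_query > len(universe):
        raise ParameterError(f"n_query {n_query} exceeds universe size {len(universe)}")
    if n_draws < 1:
        raise ParameterError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    stats = _QQStats(net, min_component_size=min_component_size)
    obs_sub, obs_edges = stats(set(observed_queries))
    null = np.empty((n_draws, 2), dtype=float)
    universe_arr = np.asarray(universe, dtype=object)
    for d in range(n_draws):
        draw = universe_arr[rng.choice(len(universe_arr), size=n_query, replace=False)]
        null[d] = stats(draw)
    return NullTestResult(
        subgraphs=_summarize(null[:, 0], obs_sub, n_draws),
        qqppi_edges=_summarize(null[:, 1], obs_edges, n_draws),
        n_draws=n_draws,
        n_query=n_query,
        seed=seed,
        min_component_size=min_component_size,
    )


def hypergeom_pvalue(overlap: int, universe_size: int, set_size: int, query_size: int) -> float:
    """One-sided upper-tail hypergeometric P(X >= overlap)."""
    if universe_size <= 0:
        raise ParameterError("universe must be non-empty")
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def hypergeom_enrich(
    query: Iterable[str],
    catalog: AnnotationCatalog,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each catalog set, BH-corrected.

    Catalog sets and the query are intersected with the universe first;
    query genes outside the universe are dropped.  Returns one row per set,
    sorted by p then set id, with columns set_id, set_size, overlap,
    overlap_genes, p_value, q_value.
    """
    universe = set(universe)
    if not universe:
        raise ParameterError("universe must be non-empty")
    query = set(query) & universe
    rows = []
    for set_id in sorted(catalog.entries):
        genes = catalog.genes(set_id) & universe
        overlap = sorted(query & genes)
        rows.append(
            {
                "set_id": set_id,
                "set_size": len(genes),
                "overlap": len(overlap),
                "overlap_genes": ",".join(overlap),
                "p_value": hypergeom_pvalue(len(overlap), len(universe), len(genes), len(query)),
            }
        )
    tbl = pd.DataFrame(rows, columns=["set_id", "set_size", "overlap", "overlap_genes", "p_value"])
    if len(tbl):
        tbl["q_value"] = benjamini_hochberg(tbl["p_value"].tolist())
        tbl = tbl.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)
    else:
        tbl["q_value"] = []
    return tbl


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values, input order preserved.

    q_(i) = min over j >= i of m * p_(j) / j (in sorted order), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()
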