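"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and the graph library calls) they
check: cliques by exhaustive bitmask subset enumeration, betweenness by
explicit simple-path enumeration, components by flood fill, hypergeometric
tails by draw enumeration, and t-test p-values by numerical quadrature of
the t density.
"""

from __future__ import annotations

import itertools
import math

from scipy.integrate import quad


def exhaustive_maximal_cliques(n: int, edges: set[tuple[int, int]]) -> list[tuple[int, ...]]:
    """All maximal cliques of a graph on nodes 0..n-1 by subset enumeration."""
    adj = [0] * n
    for a, b in edges:
        adj[a] |= 1 << b
        adj[b] |= 1 << a

    def complete(mask: int) -> bool:
        m = mask
        while m:
            v = (m & -m).bit_length() - 1
            m &= m - 1
            if mask & ~(adj[v] | (1 << v)):
                return False
        return True

    cliques = []
    for mask in range(1, 1 << n):
        if not complete(mask):
            continue
        # maximal iff no outside vertex is adjacent to every member
        extendable = False
        for w in range(n):
            if not (mask >> w) & 1 and (adj[w] & mask) == mask:
                extendable = True
                break
        if not extendable:
            members = tuple(v for v in range(n) if (mask >> v) & 1)
            cliques.append(members)
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def path_enumeration_betweenness(n: int, edges: set[tuple[int, int]]) -> dict[int, float]:
    """Unnormalized betweenness by enumerating every simple path per pair."""
    nbrs = {v: set() for v in range(n)}
    for a, b in edges:
        nbrs[a].add(b)
        nbrs[b].add(a)

    def all_simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                yield path
                continue
            for w in nbrs[v]:
                if w not in path:
                    stack.append((w, path + [w]))

    bet = {v: 0.0 for v in range(n)}
    for s, t in itertools.combinations(range(n), 2):
        paths = list(all_simple_paths(s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in sp if v in p)
            bet[v] += through / len(sp)
    return bet


def flood_fill_components(nodes, edges) -> list[set]:
    """Connected components by explicit flood fill."""
    nbrs = {v: set() for v in nodes}
    for a, b in edges:
        nbrs[a].add(b)
        nbrs[b].add(a)
    seen, comps = set(), []
    for v in nodes:
        if v in seen:
            continue
        comp, frontier = {v}, [v]
        while frontier:
            u = frontier.pop()
            for w in nbrs[u]:
                if w not in comp:
                    comp.add(w)
                    frontier.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def hypergeom_tail_by_enumeration(universe: list, annotated: set, n_draw: int, k_min: int) -> float:
    """P(overlap >= k_min) by enumerating every possible draw of size n_draw."""
    total = hits = 0
    for combo in itertools.combinations(universe, n_draw):
        total += 1
        if len(annotated.intersection(combo)) >= k_min:
            hits += 1
    return hits / total


def t_two_sided_p_by_quadrature(t_stat: float, df: int) -> float:
    """Two-sided t-test p by numerical integration of the t density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def density(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = quad(density, abs(t_stat), math.inf)
    return 2 * tail


def pooled_t_statistic(a, b) -> tuple[float, int]:
    """Pooled-variance two-sample t statistic and its degrees of freedom."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return t, df
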