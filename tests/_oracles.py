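"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — no networkx, no statsmodels — so
they stay independent of the code paths they check.
"""

from __future__ import annotations

import itertools
from collections import deque

from scipy import stats


def bh_stepup(pvals):
    """Benjamini–Hochberg step-up adjusted p-values, by the definition:
    q_(i) = min_{j >= i} p_(j) * n / j over the ascending order, capped at 1."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for j_pos in range(rank_pos, n + 1):
            j = order[j_pos - 1]
            candidates.append(pvals[j] * n / j_pos)
        q[i] = min(1.0, min(candidates))
    return q


def welch_p(a, b):
    """Two-sided Welch t-test p-value from the textbook formulas."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0 if ma != mb else 1.0
    t = (ma - mb) / se2 ** 0.5
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * stats.t.sf(abs(t), df)


def bfs_distances(nodes, adj, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _shortest_paths(adj, s, t, max_len):
    """All simple s->t paths of exactly the shortest length (DFS, pruned)."""
    paths = []

    def dfs(node, path):
        if len(path) - 1 > max_len:
            return
        if node == t:
            if len(path) - 1 == max_len:
                paths.append(tuple(path))
            return
        for nxt in adj[node]:
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    dfs(s, [s])
    return paths


def brute_betweenness(nodes, edges):
    """Freeman betweenness by shortest-path enumeration.

    For each unordered pair s != t, enumerate every shortest path and
    credit each interior vertex with its fraction of those paths.
    """
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(sorted(nodes), 2):
        dist = bfs_distances(nodes, adj, s)
        if t not in dist:
            continue
        paths = _shortest_paths(adj, s, t, dist[t])
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    return bc


def brute_farness(nodes, edges):
    """Mean BFS distance to reachable vertices; 0 for isolated vertices."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for v in nodes:
        dist = bfs_distances(nodes, adj, v)
        dist.pop(v)
        out[v] = sum(dist.values()) / len(dist) if dist else 0.0
    return out


def brute_hypergeom_p(universe, gene_set, candidates):
    """Upper-tail over-representation p by exhaustive enumeration of all
    equally likely candidate draws from the universe."""
    universe = sorted(universe)
    k_obs = len(set(gene_set) & set(candidates))
    n_draw = len(candidates)
    hits = total = 0
    marked = set(gene_set)
    for draw in itertools.combinations(universe, n_draw):
        total += 1
        if len(marked.intersection(draw)) >= k_obs:
            hits += 1
    return hits / total


def venn_region_counts(named_sets):
    """Per-gene membership-bitmask counting of Venn region sizes."""
    counts = {}
    union = set().union(*named_sets.values())
    for gene in union:
        key = frozenset(n for n, s in named_sets.items() if gene in s)
        counts[key] = counts.get(key, 0) + 1
    return counts


def reachable_ancestors(parents, term):
    """Transitive closure over child->parent links by BFS."""
    seen = set()
    queue = deque(parents.get(term, ()))
    while queue:
        u = queue.popleft()
        if u in seen:
            continue
        seen.add(u)
        queue.extend(parents.get(u, ()))
    return seen
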