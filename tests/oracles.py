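"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the code paths (and library calls) of the package:
ring membership comes from a hand-rolled BFS, concentric degrees from an
exhaustive edge scan, and betweenness from per-source BFS path counting
combined through the pair-sum definition rather than dependency
accumulation.
"""

from collections import deque


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def adjacency(graph) -> dict:
    adj = {n: set() for n in graph.nodes()}
    for u, v in graph.edges():
        adj[u].add(v)
        adj[v].add(u)
    return adj


def concentric_degree_oracle(graph, node, level: int) -> int:
    """h_level by exhaustive edge scan over BFS distance labels."""
    adj = adjacency(graph)
    dist = bfs_distances(adj, node)
    count = 0
    for u, v in graph.edges():
        du, dv = dist.get(u), dist.get(v)
        if du is None or dv is None:
            continue
        if {du, dv} == {level, level + 1}:
            count += 1
    return count


def concentric_profile_oracle(graph, node, max_level: int) -> list:
    """[h_0, ..., h_max_level] from one BFS labeling and one edge scan."""
    dist = bfs_distances(adjacency(graph), node)
    h = [0] * (max_level + 1)
    for u, v in graph.edges():
        du, dv = dist.get(u), dist.get(v)
        if du is None or dv is None:
            continue
        lo, hi = min(du, dv), max(du, dv)
        if hi == lo + 1 and lo <= max_level:
            h[lo] += 1
    return h


def rings_oracle(graph, node) -> dict:
    """Mapping level -> set of nodes at that BFS distance (level >= 1)."""
    dist = bfs_distances(adjacency(graph), node)
    out: dict = {}
    for n, d in dist.items():
        if d > 0:
            out.setdefault(d, set()).add(n)
    return out


def betweenness_oracle(graph) -> dict:
    """Exact betweenness from the pair-sum over shortest-path counts.

    For every source, BFS yields distances and shortest-path counts sigma.
    The contribution of node v to pair (s, t) is
    sigma(s,v) * sigma(v,t) / sigma(s,t) when v lies on a shortest s-t path.
    Normalization is (n-1)(n-2)/2 with n the size of v's component.
    """
    adj = adjacency(graph)
    nodes = list(graph.nodes())
    dist: dict = {}
    sigma: dict = {}
    for s in nodes:
        d = {s: 0}
        sg = {s: 1}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in d:
                    d[v] = d[u] + 1
                    sg[v] = 0
                    q.append(v)
                if d[v] == d[u] + 1:
                    sg[v] += sg[u]
        dist[s] = d
        sigma[s] = sg

    # component sizes for normalization
    comp_size = {}
    seen = set()
    for s in nodes:
        if s in seen:
            continue
        comp = set(bfs_distances(adj, s))
        seen |= comp
        for n in comp:
            comp_size[n] = len(comp)

    raw = {n: 0.0 for n in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            dst = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or v not in dist[t]:
                    continue
                if dist[s][v] + dist[t][v] == dst:
                    raw[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    out = {}
    for v in nodes:
        n = comp_size[v]
        out[v] = raw[v] / ((n - 1) * (n - 2) / 2) if n >= 3 else 0.0
    return out


def auto_threshold_oracle(values, gene_ids, taus, connect_frac, eps):
    """Exhaustive grid scan re-deriving the stability threshold choice."""
    import numpy as np

    def stats(tau):
        n = len(gene_ids)
        adj = {g: set() for g in gene_ids}
        n_edges = 0
        for i in range(n):
            for j in range(i + 1, n):
                if abs(values[i][j]) >= tau:
                    adj[gene_ids[i]].add(gene_ids[j])
                    adj[gene_ids[j]].add(gene_ids[i])
                    n_edges += 1
        non_iso = [g for g in gene_ids if adj[g]]
        best = 0
        seen = set()
        for g in non_iso:
            if g in seen:
                continue
            comp = set(bfs_distances(adj, g))
            seen |= comp
            best = max(best, len(comp))
        frac = best / len(non_iso) if non_iso else 0.0
        return n_edges, best, frac

    rows = [stats(t) for t in taus]
    rows.append(stats(taus[-1] - (taus[0] - taus[1]) if len(taus) > 1 else taus[-1] / 2))
    for i, tau in enumerate(taus):
        e, g, f = rows[i]
        e2, g2, _ = rows[i + 1]
        if e == 0 or f < connect_frac:
            continue
        if abs(e - e2) / max(e, e2, 1) <= eps and abs(g - g2) / max(g, g2, 1) <= eps:
            return tau
    return None
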