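"""Independent brute-force implementations of the five node metrics.

Deliberately naive and self-contained (no networkx): BFS distances,
exhaustive shortest-path enumeration for betweenness, and direct set
arithmetic for the local metrics.  Only usable for small graphs.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations


def adjacency(nodes: list, edges: list[tuple]) -> dict:
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                queue.append(u)
    return dist


def count_shortest_paths(adj: dict, dist_from_s: dict, s, t) -> int:
    """Number of shortest s-t paths, by exhaustive path enumeration."""
    if t not in dist_from_s:
        return 0
    target_len = dist_from_s[t]

    def extend(v, length):
        if v == t:
            return 1 if length == target_len else 0
        if length >= target_len:
            return 0
        total = 0
        for u in adj[v]:
            # only move strictly away from s, along shortest-path layers
            if dist_from_s.get(u, -1) == length + 1:
                total += extend(u, length + 1)
        return total

    return extend(s, 0)


def count_shortest_paths_through(adj, dist_from_s, dist_from_v, s, t, v) -> int:
    """Number of shortest s-t paths passing through interior node v."""
    if t not in dist_from_s or v not in dist_from_s or t not in dist_from_v:
        return 0
    if dist_from_s[v] + dist_from_v[t] != dist_from_s[t]:
        return 0
    return count_shortest_paths(adj, dist_from_s, s, v) * count_shortest_paths(
        adj, dist_from_v, v, t
    )


def brute_force_metrics(nodes: list, edges: list[tuple]) -> dict:
    """All five metrics for every node; returns genus -> dict of metric values."""
    adj = adjacency(nodes, edges)
    dists = {v: bfs_distances(adj, v) for v in nodes}
    out = {}
    for v in nodes:
        k = len(adj[v])
        # clustering coefficient
        if k < 2:
            cc = 0.0
        else:
            among = sum(
                1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a]
            )
            cc = 2.0 * among / (k * (k - 1))
        # closeness within the connected component
        comp = set(dists[v])
        if len(comp) == 1:
            clo = 0.0
        else:
            clo = (len(comp) - 1) / sum(dists[v][u] for u in comp)
        # betweenness, normalized by (N-1)(N-2)/2 within the component
        n_comp = len(comp)
        if n_comp < 3:
            bet = 0.0
        else:
            total = 0.0
            for s, t in combinations(sorted(comp - {v}), 2):
                sigma = count_shortest_paths(adj, dists[s], s, t)
                if sigma == 0:
                    continue
                through = count_shortest_paths_through(adj, dists[s], dists[v], s, t, v)
                total += through / sigma
            bet = total / ((n_comp - 1) * (n_comp - 2) / 2.0)
        # topological coefficient
        if k <= 1:
            tc = 0.0
        else:
            sharing = {}
            for u in adj[v]:
                for m in adj[u]:
                    if m != v:
                        sharing.setdefault(m, set()).add(u)
            if not sharing:
                tc = 0.0
            else:
                js = [
                    (len(shared) + (1 if m in adj[v] else 0)) / k
                    for m, shared in sharing.items()
                ]
                tc = sum(js) / len(js)
        out[v] = {
            "degree": k,
            "clustering_coefficient": cc,
            "closeness": clo,
            "betweenness": bet,
            "topological_coefficient": tc,
        }
    return out
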