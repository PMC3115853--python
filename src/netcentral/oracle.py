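"""Brute-force centrality oracle for tiny graphs.

Independent of the edge-parallel engine: distances come from a plain
queue-based BFS and geodesics are enumerated exhaustively by depth-first
search constrained to BFS layers. Intended for test verification only;
guarded to n <= 14.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from netcentral.graph import Graph
from netcentral.metrics import CentralityScores

__all__ = ["oracle_centrality", "serial_bfs_distances", "enumerate_geodesics"]

_MAX_N = 14
_INF = -1  # unreachable marker in serial BFS output


def serial_bfs_distances(adj: list[list[int]], source: int) -> list[int]:
    """Textbook queue-based BFS; returns -1 for unreachable nodes."""
    dist = [_INF] * len(adj)
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if dist[w] == _INF:
                dist[w] = dist[u] + 1
                q.append(w)
    return dist


def enumerate_geodesics(
    adj: list[list[int]], s: int, t: int, dist_s: list[int], dist_t: list[int]
) -> list[tuple[int, ...]]:
    """All shortest s-t paths, via layer-constrained DFS.

    A partial path of length k at node u extends only to neighbours w with
    dist_s[w] == k + 1 and dist_s[w] + dist_t[w] == dist_s[t], i.e. w lies
    on some geodesic. Returns [] when t is unreachable.
    """
    if dist_s[t] == _INF:
        return []
    total = dist_s[t]
    out: list[tuple[int, ...]] = []
    stack: list[tuple[int, tuple[int, ...]]] = [(s, (s,))]
    while stack:
        u, path = stack.pop()
        if u == t:
            out.append(path)
            continue
        k = len(path) - 1
        for w in adj[u]:
            if dist_s[w] == k + 1 and dist_t[w] != _INF and dist_s[w] + dist_t[w] == total:
                stack.append((w, path + (w,)))
    return out


def _adjacency(graph: Graph) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(graph.n)]
    for i, j in graph.edge_indices():
        adj[i].append(int(j))
        adj[j].append(int(i))
    return adj


def oracle_centrality(graph: Graph, metric: str) -> CentralityScores:
    """Compute one metric from first principles by exhaustive enumeration.

    Raises ``ValueError`` for graphs with more than 14 nodes.
    """
    metric = metric.upper()
    if metric not in ("BC", "CC", "EC", "SC"):
        raise ValueError(f"unknown metric {metric!r}")
    n = graph.n
    if n > _MAX_N:
        raise ValueError(f"oracle limited to n <= {_MAX_N}, got n={n}")
    adj = _adjacency(graph)
    dist = [serial_bfs_distances(adj, s) for s in range(n)]
    values = np.zeros(n)

    if metric in ("BC", "SC"):
        for s in range(n):
            for t in range(s + 1, n):
                paths = enumerate_geodesics(adj, s, t, dist[s], dist[t])
                if not paths:
                    continue
                through = np.zeros(n)
                for p in paths:
                    for v in p[1:-1]:
                        through[v] += 1
                if metric == "BC":
                    values += through / len(paths)
                else:
                    values += through
    elif metric == "CC":
        for u in range(n):
            reach = [d for v, d in enumerate(dist[u]) if v != u and d != _INF]
            if reach:
                values[u] = len(reach) / sum(reach)
    else:  # EC
        for u in range(n):
            reach = [d for v, d in enumerate(dist[u]) if v != u and d != _INF]
            if reach:
                values[u] = 1.0 / max(reach)

    return CentralityScores(metric=metric, values=values, node_labels=list(graph.node_labels))
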