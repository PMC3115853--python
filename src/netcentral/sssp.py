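"""Edge-parallel, level-synchronous single-source BFS and dependency back-propagation.

The traversal examines every edge slot once per level: a slot (u, v) whose
head u sits on the current frontier discovers v (sets its distance) and then
contributes u's geodesic count to v. Because a node's distance is written
exactly once, per-slot updates within a level are conflict-free and any
evaluation order gives identical results. Two interchangeable engines
implement the same contract:

``ref``
    a literal per-edge-slot loop (compiled with numba), mirroring the
    one-work-item-per-edge kernel formulation;
``vec``
    a vectorized whole-array engine operating on all slots at once.

Shortest-path predecessor structure is kept as one boolean per edge slot
(length l = 2 m) rather than a dense n x n matrix: slot k is flagged iff it
lies on some geodesic from the source, which is all the back-propagation
step needs and keeps per-source memory at O(n + l).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from numba import njit

from netcentral.graph import EdgeArrays

__all__ = [
    "UNREACHABLE",
    "SSSPResult",
    "bfs_edge_parallel",
    "accumulate_dependencies",
    "accumulate_path_counts",
    "apsp",
]

#: Sentinel hop distance for unreached nodes; strictly greater than any
#: attainable hop count and safe under +1 arithmetic in int64.
UNREACHABLE = np.int64(2**31)

_ENGINES = ("ref", "vec")


@dataclass
class SSSPResult:
    """Per-source BFS output.

    ``d``
        hop distance per node (:data:`UNREACHABLE` where unreached);
    ``sigma``
        geodesic count per node, exact for values below 2**53;
    ``pred_flag``
        per-edge-slot boolean, true on slot k iff
        ``d[tail[k]] == d[head[k]] + 1`` (the slot lies on a geodesic);
    ``delta``
        per-node dependency, zero until
        :func:`accumulate_dependencies` fills it. ``delta[source]`` is
        meaningless and ignored by consumers.
    """

    source: int
    d: np.ndarray
    sigma: np.ndarray
    pred_flag: np.ndarray
    delta: np.ndarray

    def max_level(self) -> int:
        """Eccentricity of the source within its component (0 if isolated)."""
        reached = self.d[self.d != UNREACHABLE]
        return int(reached.max()) if reached.size else 0


def _check_engine(engine: str) -> None:
    if engine not in _ENGINES:
        raise ValueError(f"engine must be one of {_ENGINES}, got {engine!r}")


# --- reference engine: literal per-edge-slot loops -------------------------


@njit(cache=True)
def _bfs_ref(head, tail, n, source, unreach):
    l = head.shape[0]
    d = np.full(n, unreach, np.int64)
    sigma = np.zeros(n, np.float64)
    d[source] = 0
    sigma[source] = 1.0
    level = np.int64(0)
    updated = True
    while updated:
        updated = False
        for k in range(l):
            if d[head[k]] == level and d[tail[k]] == unreach:
                d[tail[k]] = level + 1
                updated = True
        for k in range(l):
            if d[head[k]] == level and d[tail[k]] == level + 1:
                sigma[tail[k]] += sigma[head[k]]
        level += 1
    pred = np.zeros(l, np.bool_)
    for k in range(l):
        if d[head[k]] != unreach and d[tail[k]] == d[head[k]] + 1:
            pred[k] = True
    return d, sigma, pred


@njit(cache=True)
def _deps_ref(head, tail, d, sigma, pred, max_level):
    n = d.shape[0]
    l = head.shape[0]
    delta = np.zeros(n, np.float64)
    for level in range(max_level, 0, -1):
        for k in range(l):
            if pred[k] and d[tail[k]] == level:
                delta[head[k]] += sigma[head[k]] / sigma[tail[k]] * (1.0 + delta[tail[k]])
    return delta


@njit(cache=True)
def _paths_ref(head, tail, d, sigma, pred, max_level):
    # g[v] = number of geodesic continuations below v, per unit geodesic
    # reaching v; sigma[v] * g[v] = total geodesics through v from source
    n = d.shape[0]
    l = head.shape[0]
    g = np.zeros(n, np.float64)
    for level in range(max_level, 0, -1):
        for k in range(l):
            if pred[k] and d[tail[k]] == level:
                g[head[k]] += 1.0 + g[tail[k]]
    return sigma * g


# --- vectorized engine: whole-array passes ---------------------------------


def _bfs_vec(head, tail, n, source):
    d = np.full(n, UNREACHABLE, dtype=np.int64)
    sigma = np.zeros(n, dtype=np.float64)
    d[source] = 0
    sigma[source] = 1.0
    level = 0
    while True:
        on_frontier = d[head] == level
        discover = on_frontier & (d[tail] == UNREACHABLE)
        if not discover.any():
            break
        d[tail[discover]] = level + 1
        step = on_frontier & (d[tail] == level + 1)
        np.add.at(sigma, tail[step], sigma[head[step]])
        level += 1
    d_head = d[head]
    pred = (d_head != UNREACHABLE) & (d[tail] == d_head + 1)
    return d, sigma, pred


def _deps_vec(head, tail, d, sigma, pred, max_level):
    delta = np.zeros(d.shape[0], dtype=np.float64)
    d_tail = d[tail]
    for level in range(max_level, 0, -1):
        sel = pred & (d_tail == level)
        h = head[sel]
        t = tail[sel]
        np.add.at(delta, h, sigma[h] / sigma[t] * (1.0 + delta[t]))
    return delta


def _paths_vec(head, tail, d, sigma, pred, max_level):
    g = np.zeros(d.shape[0], dtype=np.float64)
    d_tail = d[tail]
    for level in range(max_level, 0, -1):
        sel = pred & (d_tail == level)
        h = head[sel]
        np.add.at(g, h, 1.0 + g[tail[sel]])
    return sigma * g


# --- public operations -----------------------------------------------------


def bfs_edge_parallel(
    arrays: EdgeArrays, n: int, source: int, engine: str = "vec"
) -> SSSPResult:
    """Level-synchronous BFS from ``source`` over the flat edge arrays.

    Distances, geodesic counts and per-slot predecessor flags are produced;
    ``delta`` comes back zero-initialized.
    """
    _check_engine(engine)
    if n != arrays.n:
        raise ValueError(f"n={n} disagrees with arrays.n={arrays.n}")
    if not 0 <= source < n:
        raise ValueError(f"source {source} out of range [0, {n})")
    if engine == "ref":
        d, sigma, pred = _bfs_ref(arrays.head, arrays.tail, n, source, UNREACHABLE)
    else:
        d, sigma, pred = _bfs_vec(arrays.head, arrays.tail, n, source)
    return SSSPResult(
        source=source, d=d, sigma=sigma, pred_flag=pred, delta=np.zeros(n, dtype=np.float64)
    )


def accumulate_dependencies(
    result: SSSPResult, arrays: EdgeArrays, engine: str = "vec"
) -> SSSPResult:
    """Fill ``result.delta`` by back-propagating over flagged slots.

    Levels are processed in decreasing distance; each flagged slot (u, v)
    contributes ``sigma[u]/sigma[v] * (1 + delta[v])`` to ``delta[u]``.
    Afterwards ``delta[v]`` is the per-source betweenness dependency of v.
    """
    _check_engine(engine)
    if result.delta.any():
        raise ValueError("delta must be zero-initialized before accumulation")
    fn = _deps_ref if engine == "ref" else _deps_vec
    result.delta = fn(
        arrays.head, arrays.tail, result.d, result.sigma, result.pred_flag, result.max_level()
    )
    return result


def accumulate_path_counts(
    result: SSSPResult, arrays: EdgeArrays, engine: str = "vec"
) -> np.ndarray:
    """Per-node count of source-rooted geodesics passing through each node.

    Returns sigma[v] * g[v] where g counts geodesic continuations below v;
    the entry for the source is meaningless. Used by stress centrality.
    """
    _check_engine(engine)
    fn = _paths_ref if engine == "ref" else _paths_vec
    return fn(
        arrays.head, arrays.tail, result.d, result.sigma, result.pred_flag, result.max_level()
    )


def apsp(arrays: EdgeArrays, n: int, engine: str = "vec") -> Iterator[SSSPResult]:
    """Stream one BFS result per source, 0..n-1, without materializing all."""
    _check_engine(engine)
    for source in range(n):
        yield bfs_edge_parallel(arrays, n, source, engine=engine)
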