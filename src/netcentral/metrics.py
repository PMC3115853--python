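"""The four shortest-path centrality metrics, streamed over per-source BFS runs.

Pair-counting convention: accumulation runs over ordered (source, target)
pairs and betweenness/stress are halved afterwards, so every unordered pair
{s, t} counts once. Closeness is the reciprocal of the mean geodesic
distance and eccentricity the reciprocal of the maximum, both taken over
reachable nodes only; nodes with an empty reachable set score 0.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from netcentral.graph import Graph, build_edge_arrays
from netcentral.sssp import (
    UNREACHABLE,
    accumulate_dependencies,
    accumulate_path_counts,
    apsp,
)

__all__ = [
    "METRICS",
    "CentralityScores",
    "betweenness",
    "closeness",
    "eccentricity",
    "stress",
    "compute_all",
    "write_scores",
]

METRICS = ("BC", "CC", "EC", "SC")


@dataclass
class CentralityScores:
    """Per-node scores for one metric, aligned with the input node order."""

    metric: str
    values: np.ndarray
    node_labels: list[str]
    normalized: bool = False
    wall_time: float = field(default=0.0, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {lab: float(v) for lab, v in zip(self.node_labels, self.values)}


def _canon_metrics(metrics: Sequence[str]) -> list[str]:
    out = []
    for m in metrics:
        mu = m.upper()
        if mu not in METRICS:
            raise ValueError(f"unknown metric {m!r}; choose from {METRICS}")
        if mu not in out:
            out.append(mu)
    if not out:
        raise ValueError("at least one metric must be requested")
    return out


def compute_all(
    graph: Graph,
    metrics: Sequence[str] = METRICS,
    normalize: bool = False,
    engine: str = "vec",
) -> list[CentralityScores]:
    """Compute the requested metrics in a single streaming APSP pass.

    Betweenness of u is the sum over unordered pairs {s, t} (s, t != u) of
    the fraction of s-t geodesics through u; stress is the corresponding
    raw count. Both come from per-source dependency back-propagation,
    halved to convert ordered accumulation to unordered pairs. Closeness
    and eccentricity are read off each source's distance vector.

    ``normalize`` divides betweenness by (n-1)(n-2)/2; other metrics are
    unaffected.
    """
    wanted = _canon_metrics(metrics)
    n = graph.n
    arrays = build_edge_arrays(graph)

    t0 = time.perf_counter()
    bc = np.zeros(n)
    sc = np.zeros(n)
    cc = np.zeros(n)
    ec = np.zeros(n)
    need_bc = "BC" in wanted
    need_sc = "SC" in wanted
    need_cc = "CC" in wanted
    need_ec = "EC" in wanted

    for res in apsp(arrays, n, engine=engine):
        s = res.source
        if need_bc:
            accumulate_dependencies(res, arrays, engine=engine)
            contrib = res.delta.copy()
            contrib[s] = 0.0
            bc += contrib
        if need_sc:
            counts = accumulate_path_counts(res, arrays, engine=engine)
            counts[s] = 0.0
            sc += counts
        if need_cc or need_ec:
            reach = res.d != UNREACHABLE
            reach[s] = False
            k = int(reach.sum())
            if k:
                dist = res.d[reach]
                if need_cc:
                    cc[s] = k / float(dist.sum())
                if need_ec:
                    ec[s] = 1.0 / float(dist.max())

    bc /= 2.0
    sc /= 2.0
    if normalize and need_bc and n > 2:
        bc /= (n - 1) * (n - 2) / 2.0
    elapsed = time.perf_counter() - t0

    pool = {"BC": bc, "SC": sc, "CC": cc, "EC": ec}
    return [
        CentralityScores(
            metric=m,
            values=pool[m],
            node_labels=list(graph.node_labels),
            normalized=(normalize and m == "BC"),
            wall_time=elapsed,
        )
        for m in wanted
    ]


def betweenness(graph: Graph, normalize: bool = False, engine: str = "vec") -> CentralityScores:
    """Fraction of geodesics between all other node pairs passing through each node."""
    return compute_all(graph, ["BC"], normalize=normalize, engine=engine)[0]


def stress(graph: Graph, engine: str = "vec") -> CentralityScores:
    """Total count of geodesics between all other node pairs passing through each node."""
    return compute_all(graph, ["SC"], engine=engine)[0]


def closeness(graph: Graph, engine: str = "vec") -> CentralityScores:
    """Reciprocal of the mean geodesic distance to reachable nodes (0 if none)."""
    return compute_all(graph, ["CC"], engine=engine)[0]


def eccentricity(graph: Graph, engine: str = "vec") -> CentralityScores:
    """Reciprocal of the maximum geodesic distance to reachable nodes (0 if none)."""
    return compute_all(graph, ["EC"], engine=engine)[0]


def write_scores(scores: CentralityScores, path: str | Path) -> None:
    """Write a per-node TSV: header comment, then `node<TAB>score` rows.

    Scores use shortest round-trip float formatting (full double precision).
    """
    norm = "true" if scores.normalized else "false"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metric={scores.metric} normalized={norm}\n")
        if scores.metric == "CC":
            fh.write("# convention: reciprocal of mean distance over reachable nodes; 0 if none reachable\n")
        elif scores.metric == "EC":
            fh.write("# convention: reciprocal of max distance over reachable nodes; 0 if none reachable\n")
        for lab, v in zip(scores.node_labels, scores.values):
            fh.write(f"{lab}\t{float(v)!r}\n")
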