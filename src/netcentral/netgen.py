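"""Seeded Barabási–Albert scale-free network generator.

Convention: the process starts from ``beta`` isolated seed nodes; the first
added node attaches to all of them, and every subsequent node attaches to
``beta`` distinct existing nodes sampled proportionally to degree (via a
repeated-endpoints list). This fixes the edge count at exactly
``beta * (n - beta)`` and yields heavy-tailed degree distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netcentral.graph import Graph

__all__ = ["BAParams", "generate_ba"]


@dataclass(frozen=True)
class BAParams:
    """Parameters for preferential-attachment generation.

    ``n`` nodes total, each new node attaching to ``beta`` existing ones;
    ``seed`` fully determines the output graph.
    """

    n: int
    beta: int
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")
        if not 1 <= self.beta < self.n:
            raise ValueError(f"beta must satisfy 1 <= beta < n, got beta={self.beta}, n={self.n}")


def generate_ba(params: BAParams) -> Graph:
    """Generate a seeded scale-free graph with exactly beta*(n-beta) edges.

    Node labels are the decimal indices "0".."n-1" in attachment order.
    The same ``params`` always produce the identical edge list; no
    cross-implementation bit-compatibility is implied.
    """
    n, beta = params.n, params.beta
    rng = np.random.default_rng(params.seed)

    edges: list[tuple[str, str]] = []
    # repeated-endpoints list: each node appears once per incident edge slot,
    # so uniform draws from it are degree-proportional
    repeated: list[int] = []

    # bootstrap: node `beta` attaches to all beta isolated seed nodes
    for t in range(beta):
        edges.append((str(beta), str(t)))
        repeated.append(beta)
        repeated.append(t)

    for v in range(beta + 1, n):
        chosen: list[int] = []
        taken: set[int] = set()
        while len(chosen) < beta:
            t = repeated[int(rng.integers(len(repeated)))]
            if t not in taken:
                taken.add(t)
                chosen.append(t)
        for t in chosen:
            edges.append((str(v), str(t)))
            repeated.append(v)
            repeated.append(t)

    return Graph.from_edges(edges, nodes=[str(i) for i in range(n)])
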