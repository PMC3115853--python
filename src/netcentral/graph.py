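"""Graph construction, validation, edge-list I/O and the flat edge-array form.

Graphs are simple, undirected and unweighted. Node labels are arbitrary
strings mapped to contiguous 0-based indices in first-seen order, which
makes every downstream computation reproducible for a given input file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Graph", "EdgeArrays", "GraphError", "load_edgelist", "write_edgelist", "build_edge_arrays"]


class GraphError(ValueError):
    """Raised when input violates the simple-graph invariants."""


@dataclass
class Graph:
    """Simple undirected graph with stable string labels.

    Parameters
    ----------
    node_labels
        Unique labels in index order (index of ``node_labels[i]`` is ``i``).
    edges
        Unordered label pairs, stored canonically as ``(u, v)`` with
        ``index[u] < index[v]``, in first-seen order.
    """

    node_labels: list[str]
    edges: list[tuple[str, str]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {lab: i for i, lab in enumerate(self.node_labels)}
        if len(self._index) != len(self.node_labels):
            raise GraphError("duplicate node labels")
        seen: set[frozenset[str]] = set()
        canon: list[tuple[str, str]] = []
        for u, v in self.edges:
            if u == v:
                raise GraphError(f"self-loop on node {u!r}")
            if u not in self._index or v not in self._index:
                raise GraphError(f"edge ({u!r}, {v!r}) references unknown node")
            key = frozenset((u, v))
            if key in seen:
                raise GraphError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)
            if self._index[u] > self._index[v]:
                u, v = v, u
            canon.append((u, v))
        self.edges = canon

    @property
    def n(self) -> int:
        return len(self.node_labels)

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def edge_set(self) -> frozenset[frozenset[str]]:
        """Order-free view of the edges, for equality checks."""
        return frozenset(frozenset(e) for e in self.edges)

    def index_of(self, label: str) -> int:
        return self._index[label]

    def edge_indices(self) -> np.ndarray:
        """Edges as an (m, 2) int64 array of node indices, i < j per row."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array(
            [(self._index[u], self._index[v]) for u, v in self.edges], dtype=np.int64
        )

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=np.int64)
        for u, v in self.edges:
            deg[self._index[u]] += 1
            deg[self._index[v]] += 1
        return deg

    @classmethod
    def from_edges(
        cls, pairs: Iterable[tuple[str, str]], nodes: Sequence[str] = ()
    ) -> "Graph":
        """Build a graph from label pairs, indexing nodes in first-seen order.

        ``nodes`` may pre-register labels (e.g. isolated nodes) ahead of the
        pairs. Duplicate pairs collapse silently; self-loops raise.
        """
        labels: list[str] = []
        index: dict[str, int] = {}

        def register(lab: str) -> None:
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)

        for lab in nodes:
            register(lab)
        edges: list[tuple[str, str]] = []
        seen: set[frozenset[str]] = set()
        for u, v in pairs:
            if u == v:
                raise GraphError(f"self-loop on node {u!r}")
            register(u)
            register(v)
            key = frozenset((u, v))
            if key not in seen:
                seen.add(key)
                edges.append((u, v))
        return cls(node_labels=labels, edges=edges)


@dataclass(frozen=True)
class EdgeArrays:
    """Flat two-array edge representation.

    Each undirected edge {i, j} occupies two slots, one per direction:
    slot k encodes the ordered pair ``(head[k], tail[k])``. The arrays have
    length ``l = 2 m`` and every per-edge computation iterates over slots.
    """

    head: np.ndarray
    tail: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.head.shape != self.tail.shape or self.head.ndim != 1:
            raise GraphError("head/tail must be 1-D arrays of equal length")
        if self.l and (self.head.min() < 0 or max(self.head.max(), self.tail.max()) >= self.n):
            raise GraphError("edge endpoint index out of range")

    @property
    def l(self) -> int:  # noqa: E743 - matches the two-array formulation
        return int(self.head.shape[0])


def load_edgelist(path: str | Path, comment_prefix: str = "#") -> Graph:
    """Read a whitespace-separated edge list into a :class:`Graph`.

    Lines starting with ``comment_prefix`` and blank lines are skipped.
    Each remaining line must carry at least two tokens; extras are ignored
    with a warning. Duplicate edges (in either direction) collapse to one.

    Raises
    ------
    GraphError
        On a self-loop line (the message names the 1-based line number) or
        a line with fewer than two tokens.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    labels: list[str] = []
    index: dict[str, int] = {}
    edges: list[tuple[str, str]] = []
    seen: set[frozenset[str]] = set()
    extra_warned = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphError(f"{path}:{lineno}: expected two node labels, got {line!r}")
            if len(tokens) > 2 and not extra_warned:
                warnings.warn(
                    f"{path}:{lineno}: ignoring extra tokens beyond the first two",
                    stacklevel=2,
                )
                extra_warned = True
            u, v = tokens[0], tokens[1]
            if u == v:
                raise GraphError(f"{path}:{lineno}: self-loop on node {u!r}")
            for lab in (u, v):
                if lab not in index:
                    index[lab] = len(labels)
                    labels.append(lab)
            key = frozenset((u, v))
            if key not in seen:
                seen.add(key)
                edges.append((u, v))
    return Graph(node_labels=labels, edges=edges)


def write_edgelist(graph: Graph, path: str | Path) -> None:
    """Write one tab-separated line per undirected edge.

    Round-trips with :func:`load_edgelist` up to node-label and edge sets.
    Isolated nodes are not representable in the format and are dropped.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")


def build_edge_arrays(graph: Graph) -> EdgeArrays:
    """Expand a graph into its flat two-array form (l = 2 m slots)."""
    pairs = graph.edge_indices()
    if pairs.size == 0:
        empty = np.empty(0, dtype=np.int64)
        return EdgeArrays(head=empty, tail=empty.copy(), n=graph.n)
    head = np.concatenate([pairs[:, 0], pairs[:, 1]])
    tail = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return EdgeArrays(head=head, tail=tail, n=graph.n)
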