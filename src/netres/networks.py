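"""In-memory containers for time series, correlation matrices and networks.

Graphs are held as :class:`networkx.Graph` instances together with an
explicit node order (``node_ids``); all matrix views are indexed in that
order, so file order never matters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

NodeId = Hashable


def _check_unique(node_ids: Sequence[NodeId]) -> list[NodeId]:
    ids = list(node_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("node_ids must be unique")
    return ids


@dataclass
class TimeSeriesMatrix:
    """Node x timepoint real matrix (arbitrary units)."""

    values: np.ndarray
    node_ids: Sequence[NodeId]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = _check_unique(self.node_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D nodes x timepoints matrix")
        if self.values.shape[0] != len(self.node_ids):
            raise ValueError("row count must match node_ids")
        if self.values.shape[1] < 3:
            raise ValueError("need at least 3 timepoints")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contain missing/non-finite values")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    node_ids: Sequence[NodeId]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.node_ids = _check_unique(self.node_ids)
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape must match node_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("correlation matrix diagonal must be 1")
        if self.values.min() < -1 - 1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def submatrix(self, keep: Sequence[NodeId]) -> "CorrelationMatrix":
        """Correlation matrix restricted to ``keep`` (original order preserved)."""
        keep_set = set(keep)
        idx = [i for i, nid in enumerate(self.node_ids) if nid in keep_set]
        ids = [self.node_ids[i] for i in idx]
        return CorrelationMatrix(self.values[np.ix_(idx, idx)], ids)


def _as_ordered_graph(graph: nx.Graph, node_ids: Sequence[NodeId] | None) -> tuple[nx.Graph, list[NodeId]]:
    if node_ids is None:
        node_ids = list(graph.nodes())
    node_ids = _check_unique(node_ids)
    if set(node_ids) != set(graph.nodes()):
        raise ValueError("node_ids must match graph nodes")
    if any(graph.has_edge(u, u) for u in graph.nodes()):
        raise ValueError("self-loops are not allowed")
    return graph, node_ids


@dataclass
class BinaryNetwork:
    """Undirected, unweighted simple graph (voxel-scale analyses)."""

    graph: nx.Graph
    node_ids: Sequence[NodeId] = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.graph, self.node_ids = _as_ordered_graph(self.graph, self.node_ids)

    @classmethod
    def from_edges(
        cls,
        node_ids: Sequence[NodeId],
        edges: Iterable[tuple[NodeId, NodeId]],
        meta: dict | None = None,
    ) -> "BinaryNetwork":
        g = nx.Graph()
        g.add_nodes_from(node_ids)
        g.add_edges_from(edges)
        return cls(g, node_ids, meta or {})

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def mean_degree(self) -> float:
        n = self.n_nodes
        return 2.0 * self.n_edges / n if n else 0.0

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2.0) if n > 1 else 0.0

    def adjacency(self) -> np.ndarray:
        """Dense 0/1 adjacency in node_ids order."""
        return nx.to_numpy_array(self.graph, nodelist=self.node_ids, dtype=float)

    def remove_nodes(self, nodes: Iterable[NodeId]) -> "BinaryNetwork":
        drop = set(nodes)
        g = self.graph.copy()
        g.remove_nodes_from(drop)
        ids = [nid for nid in self.node_ids if nid not in drop]
        return BinaryNetwork(g, ids, dict(self.meta))

    def copy(self) -> "BinaryNetwork":
        return BinaryNetwork(self.graph.copy(), list(self.node_ids), dict(self.meta))


@dataclass
class SignedWeightedNetwork:
    """Undirected graph with signed real weights in [-1, 1] \\ {0} (ROI scale)."""

    graph: nx.Graph
    node_ids: Sequence[NodeId] = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.graph, self.node_ids = _as_ordered_graph(self.graph, self.node_ids)
        for u, v, w in self.graph.edges(data="weight"):
            if w is None or w == 0:
                raise ValueError(f"edge ({u}, {v}) must carry a nonzero weight")
            if abs(w) > 1 + 1e-9:
                raise ValueError(f"|weight| must be <= 1 on edge ({u}, {v})")

    @classmethod
    def from_weighted_edges(
        cls,
        node_ids: Sequence[NodeId],
        edges: Iterable[tuple[NodeId, NodeId, float]],
        meta: dict | None = None,
    ) -> "SignedWeightedNetwork":
        g = nx.Graph()
        g.add_nodes_from(node_ids)
        g.add_weighted_edges_from(edges)
        return cls(g, node_ids, meta or {})

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight_matrix(self) -> np.ndarray:
        """Dense signed weight matrix in node_ids order (0 = no link)."""
        return nx.to_numpy_array(self.graph, nodelist=self.node_ids, weight="weight", dtype=float)

    def remove_nodes(self, nodes: Iterable[NodeId]) -> "SignedWeightedNetwork":
        drop = set(nodes)
        g = self.graph.copy()
        g.remove_nodes_from(drop)
        ids = [nid for nid in self.node_ids if nid not in drop]
        return SignedWeightedNetwork(g, ids, dict(self.meta))

    def copy(self) -> "SignedWeightedNetwork":
        return SignedWeightedNetwork(self.graph.copy(), list(self.node_ids), dict(self.meta))
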