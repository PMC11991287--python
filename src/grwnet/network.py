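"""Core in-memory containers: weighted networks, node coordinate tables, layer stacks.

Networks are stored as flat arrays (edge index pairs + weights) rather than as
adjacency dicts: every downstream computation (renormalization, filtering,
disparity, weight statistics) is a vectorized pass over the edge list, and the
largest networks handled here (a few thousand nodes, ~10^5 edges) fit easily.
Node ids are opaque strings mapped to contiguous integer indices; the id↔index
map is persistent so supernode provenance survives relabeling across layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class NetworkError(ValueError):
    """Raised on violated network invariants (self-loops, multi-edges, bad weights)."""


def canonical_edges(edges: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonicalize an undirected edge list: i < j per row, rows sorted lexicographically.

    Rejects self-loops and duplicate undirected edges.
    """
    edges = np.asarray(edges, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    if edges.ndim != 2 or edges.shape[1] != 2:
        raise NetworkError("edge array must have shape (E, 2)")
    if edges.shape[0] != weights.shape[0]:
        raise NetworkError("edges and weights length mismatch")
    if edges.size and np.any(edges[:, 0] == edges[:, 1]):
        raise NetworkError("self-loops are not allowed")
    lo = np.minimum(edges[:, 0], edges[:, 1])
    hi = np.maximum(edges[:, 0], edges[:, 1])
    order = np.lexsort((hi, lo))
    lo, hi, weights = lo[order], hi[order], weights[order]
    if lo.size > 1:
        dup = (lo[1:] == lo[:-1]) & (hi[1:] == hi[:-1])
        if np.any(dup):
            i = int(np.flatnonzero(dup)[0])
            raise NetworkError(f"duplicate undirected edge ({lo[i]}, {hi[i]})")
    return np.column_stack([lo, hi]), weights


@dataclass
class WeightedNetwork:
    """Undirected simple graph with strictly positive real edge weights.

    Attributes
    ----------
    n_nodes : total number of nodes (isolated nodes allowed).
    edges : (E, 2) int array, canonical (i < j, lexsorted).
    weights : (E,) positive float array aligned with ``edges``.
    node_ids : length-n sequence of opaque string ids; defaults to "0".."n-1".
    """

    n_nodes: int
    edges: np.ndarray
    weights: np.ndarray
    node_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.edges, self.weights = canonical_edges(self.edges, self.weights)
        if self.edges.size and int(self.edges.max()) >= self.n_nodes:
            raise NetworkError("edge endpoint out of range")
        if np.any(self.weights <= 0) or not np.all(np.isfinite(self.weights)):
            raise NetworkError("all weights must be finite and strictly positive")
        if not self.node_ids:
            self.node_ids = [str(i) for i in range(self.n_nodes)]
        elif len(self.node_ids) != self.n_nodes:
            raise NetworkError("node_ids length must equal n_nodes")

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def degrees(self) -> np.ndarray:
        k = np.zeros(self.n_nodes, dtype=np.int64)
        if self.n_edges:
            np.add.at(k, self.edges[:, 0], 1)
            np.add.at(k, self.edges[:, 1], 1)
        return k

    def strengths(self) -> np.ndarray:
        s = np.zeros(self.n_nodes, dtype=np.float64)
        if self.n_edges:
            np.add.at(s, self.edges[:, 0], self.weights)
            np.add.at(s, self.edges[:, 1], self.weights)
        return s

    def with_edges(self, keep: np.ndarray) -> "WeightedNetwork":
        """Sub-network with the same node set and a boolean/int edge selection."""
        return WeightedNetwork(
            self.n_nodes, self.edges[keep], self.weights[keep], list(self.node_ids)
        )

    def to_igraph(self, weighted: bool = True):
        import igraph as ig

        g = ig.Graph(n=self.n_nodes, edges=[tuple(e) for e in self.edges.tolist()])
        if weighted:
            g.es["weight"] = self.weights.tolist()
        return g

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_weighted_edges_from(
            (int(i), int(j), float(w)) for (i, j), w in zip(self.edges, self.weights)
        )
        return g

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        if self.n_edges:
            a[self.edges[:, 0], self.edges[:, 1]] = 1
            a[self.edges[:, 1], self.edges[:, 0]] = 1
        return a


@dataclass
class NodeTable:
    """Latent-geometry node attributes for a network of N nodes.

    theta : angular similarity coordinate in [0, 2π), radians.
    kappa : hidden degree (> 0).
    sigma : hidden strength (> 0), tied to kappa through σ = a κ^η.
    xyz   : optional (N, 3) Euclidean positions in mm.
    hemisphere : optional array of "L"/"R" labels.
    """

    theta: np.ndarray
    kappa: np.ndarray
    sigma: np.ndarray
    xyz: np.ndarray | None = None
    hemisphere: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.mod(np.asarray(self.theta, dtype=np.float64), 2.0 * np.pi)
        self.kappa = np.asarray(self.kappa, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if np.any(self.kappa <= 0) or np.any(self.sigma <= 0):
            raise ValueError("kappa and sigma must be strictly positive")
        if not (len(self.theta) == len(self.kappa) == len(self.sigma)):
            raise ValueError("node attribute arrays must share one length")
        if self.xyz is not None:
            self.xyz = np.asarray(self.xyz, dtype=np.float64)
            if self.xyz.shape != (len(self.theta), 3):
                raise ValueError("xyz must have shape (N, 3)")
        if self.hemisphere is not None:
            self.hemisphere = np.asarray(self.hemisphere)
            if len(self.hemisphere) != len(self.theta):
                raise ValueError("hemisphere labels must have length N")

    def __len__(self) -> int:
        return len(self.theta)

    def subset(self, idx: np.ndarray) -> "NodeTable":
        return NodeTable(
            self.theta[idx],
            self.kappa[idx],
            self.sigma[idx],
            None if self.xyz is None else self.xyz[idx],
            None if self.hemisphere is None else self.hemisphere[idx],
        )


def angular_separation(theta_i: np.ndarray, theta_j: np.ndarray) -> np.ndarray:
    """Shorter-arc angular separation Δθ ∈ [0, π]."""
    d = np.abs(np.asarray(theta_i) - np.asarray(theta_j))
    return np.minimum(d, 2.0 * np.pi - d)


@dataclass
class LayerStack:
    """Ordered multiscale sequence of networks; layer 0 is the highest resolution.

    ``maps[l]`` sends each node index of layer l to its supernode index in
    layer l+1 (surjective by construction).
    """

    layers: list[WeightedNetwork]
    maps: list[np.ndarray]
    node_tables: list[NodeTable] | None = None

    def __post_init__(self) -> None:
        if len(self.maps) != len(self.layers) - 1:
            raise ValueError("need exactly one node→supernode map per consecutive layer pair")
        for l, m in enumerate(self.maps):
            if len(m) != self.layers[l].n_nodes:
                raise ValueError(f"map {l} length mismatch")
            n_next = self.layers[l + 1].n_nodes
            if len(np.unique(m)) != n_next:
                raise ValueError(f"map {l} is not surjective onto layer {l + 1}")
        sizes = [g.n_nodes for g in self.layers]
        if any(b > a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("layer node counts must be non-increasing")

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)


@dataclass
class Cohort:
    """Multi-subject collection of networks over one shared node set.

    Edge length proxies are Euclidean distances between the shared node
    positions, hence identical for a given node pair across subjects.
    """

    nodes: NodeTable
    subjects: list[WeightedNetwork]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if any(s.n_nodes != n for s in self.subjects):
            raise ValueError("all subjects must share the cohort node set")
        if self.nodes.xyz is None:
            raise ValueError("cohort nodes need Euclidean positions for length proxies")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def edge_length(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return np.linalg.norm(self.nodes.xyz[i] - self.nodes.xyz[j], axis=-1)
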