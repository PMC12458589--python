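"""Weighted brain graph and its Laplacian.

The four modelled nuclei (STN, GPi, GPe, TH) are nodes of a weighted
undirected graph whose edge weights are ``n_ij / l_ij**2`` — mean axonal
fiber count over mean fiber length squared — as estimated from
tractography.  The graph Laplacian ``L = rho * (D - W)`` (``D`` the
weighted degree matrix, ``rho`` the diffusion coefficient) drives the
inter-regional voltage diffusion term of the regional membrane
equations.

Because real tractography archives are large and external, the module
also ships a seeded synthetic-connectome generator with fiber counts and
lengths drawn from positive distributions of tractography-like
magnitude; the shipped default configurations use a complete 4-node
graph, one node per modelled region.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    DuplicateEdgeError,
    FormatError,
    InvalidEdgeError,
    ParameterError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Fixed region order used throughout the package; region p occupies node p.
REGIONS = ("STN", "GPi", "GPe", "TH")

_EDGE_COLUMNS = ("source", "target", "fiber_count", "fiber_length")
_NODE_COLUMNS = ("node_id", "label")


@dataclass(frozen=True)
class ConnectomeEdge:
    """One undirected fiber bundle between two regions.

    Parameters
    ----------
    source, target : int
        0-based node indices; must differ.
    fiber_count : float
        Mean number of fibers in the bundle (``n_ij``), >= 0.
    fiber_length : float
        Mean fiber length in mm (``l_ij``), > 0.
    """

    source: int
    target: int
    fiber_count: float
    fiber_length: float

    def __post_init__(self):
        if self.source == self.target:
            raise InvalidEdgeError(
                f"self-loop on node {self.source}: edges must join distinct nodes"
            )
        if self.fiber_count < 0:
            raise InvalidEdgeError(f"fiber_count must be >= 0, got {self.fiber_count}")
        if self.fiber_length <= 0:
            raise InvalidEdgeError(f"fiber_length must be > 0, got {self.fiber_length}")

    @property
    def weight(self) -> float:
        """Adjacency weight ``n_ij / l_ij**2`` (count / mm^2)."""
        return self.fiber_count / self.fiber_length**2


def build_adjacency(edges, n_nodes: int) -> np.ndarray:
    """Assemble the symmetric weighted adjacency matrix W.

    ``W[i, j] = n_ij / l_ij**2`` for every listed edge, symmetrized;
    the diagonal is zero and unlisted pairs are zero.

    Raises
    ------
    InvalidEdgeError
        If an index is out of range (edge-level invariants are enforced
        by :class:`ConnectomeEdge` itself).
    DuplicateEdgeError
        If the same undirected pair appears twice.
    """
    if n_nodes < 1:
        raise ParameterError(f"n_nodes must be >= 1, got {n_nodes}")
    W = np.zeros((n_nodes, n_nodes))
    seen: set[tuple[int, int]] = set()
    for e in edges:
        if not (0 <= e.source < n_nodes and 0 <= e.target < n_nodes):
            raise InvalidEdgeError(
                f"edge ({e.source}, {e.target}) out of range for {n_nodes} nodes"
            )
        key = (min(e.source, e.target), max(e.source, e.target))
        if key in seen:
            raise DuplicateEdgeError(f"duplicate edge for node pair {key}")
        seen.add(key)
        W[e.source, e.target] = W[e.target, e.source] = e.weight
    return W


def build_laplacian(W: np.ndarray, rho: float) -> np.ndarray:
    """Weighted graph Laplacian ``L = rho * (D - W)`` with ``D_ii = sum_j W_ij``.

    Every row of L sums to zero, and for symmetric nonnegative W and
    ``rho > 0`` L is positive semidefinite.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError(f"W must be square, got shape {W.shape}")
    if not np.allclose(W, W.T):
        raise ValidationError("W must be symmetric")
    if np.any(W < 0):
        raise ValidationError("W must be nonnegative")
    if rho < 0:
        raise ParameterError(f"diffusion coefficient rho must be >= 0, got {rho}")
    D = np.diag(W.sum(axis=1))
    return rho * (D - W)


class Connectome:
    """A labelled weighted brain graph with its diffusion Laplacian.

    Attributes
    ----------
    node_labels : tuple of str
        Region names; the first four must be STN, GPi, GPe, TH.
    adjacency : (V, V) ndarray
        Symmetric nonnegative weight matrix W with zero diagonal.
    degree : (V, V) ndarray
        Diagonal weighted-degree matrix D.
    laplacian : (V, V) ndarray
        ``rho * (D - W)``.
    diffusion_coefficient : float
        The scalar rho.
    """

    def __init__(
        self, node_labels, adjacency, diffusion_coefficient: float = 1.0, edges=None
    ):
        adjacency = np.asarray(adjacency, dtype=float)
        node_labels = tuple(str(x) for x in node_labels)
        if adjacency.shape != (len(node_labels), len(node_labels)):
            raise ValidationError(
                f"adjacency shape {adjacency.shape} does not match "
                f"{len(node_labels)} node labels"
            )
        if np.any(np.diag(adjacency) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        self.node_labels = node_labels
        self.adjacency = adjacency
        self.diffusion_coefficient = float(diffusion_coefficient)
        # build_laplacian re-validates symmetry/nonnegativity/rho.
        self.laplacian = build_laplacian(adjacency, self.diffusion_coefficient)
        self.degree = np.diag(adjacency.sum(axis=1))
        #: original (fiber_count, fiber_length) edge list when known; None if
        #: the connectome was constructed from a bare adjacency matrix
        self.edges = list(edges) if edges is not None else None

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def region_index(self, region: str) -> int:
        try:
            return self.node_labels.index(region)
        except ValueError:
            raise ParameterError(f"unknown region label {region!r}") from None

    def to_networkx(self) -> nx.Graph:
        """Weighted undirected graph view (for export / inspection)."""
        g = nx.Graph()
        for i, lab in enumerate(self.node_labels):
            g.add_node(i, label=lab)
        V = self.n_nodes
        for i in range(V):
            for j in range(i + 1, V):
                w = self.adjacency[i, j]
                if w > 0:
                    g.add_edge(i, j, weight=float(w))
        return g

    def __eq__(self, other):
        return (
            isinstance(other, Connectome)
            and self.node_labels == other.node_labels
            and np.array_equal(self.adjacency, other.adjacency)
            and self.diffusion_coefficient == other.diffusion_coefficient
        )


def synth_connectome(
    n_nodes: int = 4,
    density: float = 1.0,
    seed: int | None = None,
    rho: float = 1.0,
) -> Connectome:
    """Generate a random connected connectome with tractography-like weights.

    Each of the ``n_nodes * (n_nodes - 1) / 2`` node pairs receives an
    edge with probability ``density``; a random spanning tree is added
    afterwards if the draw left the graph disconnected, so the result is
    always connected.  Fiber counts are log-normal (median ~500 fibers)
    and fiber lengths uniform on 30-120 mm, magnitudes typical of
    inter-nucleus bundles in whole-brain tractography.  The first four
    nodes are labelled STN, GPi, GPe, TH; any further nodes get generic
    labels R5, R6, ...

    Deterministic for a fixed ``seed``.
    """
    if n_nodes < 2:
        raise ParameterError(f"n_nodes must be >= 2, got {n_nodes}")
    if not 0 < density <= 1:
        raise ParameterError(f"density must be in (0, 1], got {density}")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    keep = rng.random(len(pairs)) < density
    chosen = {p for p, k in zip(pairs, keep) if k}
    # splice in a random spanning tree if the Bernoulli draw disconnected the graph
    g = nx.Graph(chosen)
    g.add_nodes_from(range(n_nodes))
    if not nx.is_connected(g):
        order = rng.permutation(n_nodes)
        for a, b in zip(order[:-1], order[1:]):
            chosen.add((min(a, b), max(a, b)))
    edges = []
    for i, j in sorted(chosen):
        count = float(np.round(rng.lognormal(mean=np.log(500.0), sigma=0.6)))
        length = float(rng.uniform(30.0, 120.0))
        edges.append(ConnectomeEdge(int(i), int(j), max(count, 1.0), length))
    labels = [REGIONS[i] if i < 4 else f"R{i + 1}" for i in range(n_nodes)]
    W = build_adjacency(edges, n_nodes)
    return Connectome(labels, W, diffusion_coefficient=rho, edges=edges)


def write_connectome(c: Connectome, node_path, edge_path) -> None:
    """Write node table and edge list as 0-indexed CSV files.

    When the connectome carries its original edge list the fiber counts
    and lengths are written verbatim; otherwise the adjacency is factored
    as ``fiber_count = W_ij``, ``fiber_length = 1`` mm, which reproduces
    W exactly on read.
    """
    nodes = pd.DataFrame(
        {"node_id": range(c.n_nodes), "label": list(c.node_labels)}
    )
    if c.edges is not None:
        rows = [(e.source, e.target, e.fiber_count, e.fiber_length) for e in c.edges]
    else:
        rows = []
        V = c.n_nodes
        for i in range(V):
            for j in range(i + 1, V):
                w = c.adjacency[i, j]
                if w > 0:
                    rows.append((i, j, w, 1.0))
    edges = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
    nodes.to_csv(node_path, index=False)
    edges.to_csv(edge_path, index=False)


def read_connectome(node_path, edge_path, rho: float = 1.0) -> Connectome:
    """Read a connectome from node-table and edge-list CSV files."""
    nodes = pd.read_csv(node_path)
    for col in _NODE_COLUMNS:
        if col not in nodes.columns:
            raise FormatError(f"node table missing column {col!r}")
    # round_trip parsing so write -> read reproduces W bit-exactly
    edges_df = pd.read_csv(edge_path, float_precision="round_trip")
    for col in _EDGE_COLUMNS:
        if col not in edges_df.columns:
            raise FormatError(f"edge list missing column {col!r}")
    labels = nodes.sort_values("node_id")["label"].tolist()
    n = len(labels)
    if len(edges_df) == 0:
        warnings.warn("edge list is empty: connectome has zero adjacency")
        logger.warning("empty edge list read from %s", edge_path)
    bad = set(edges_df["source"]) | set(edges_df["target"])
    if bad - set(range(n)):
        raise FormatError(
            f"edge list references unknown node ids {sorted(bad - set(range(n)))}"
        )
    edges = [
        ConnectomeEdge(
            int(r.source), int(r.target), float(r.fiber_count), float(r.fiber_length)
        )
        for r in edges_df.itertuples()
    ]
    W = build_adjacency(edges, n)
    return Connectome(labels, W, diffusion_coefficient=rho, edges=edges)


def write_graphml(c: Connectome, path) -> None:
    """Export the weighted graph as GraphML for external tools."""
    nx.write_graphml(c.to_networkx(), path)
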