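"""Confidence-weighted undirected interaction networks.

A protein-protein interaction (PPI) network is modelled as an undirected
graph G(V, E) in which each edge carries a reliability weight w(uv) in
(0, 1].  The *weighted degree* of a node,

    W(v) = sum over u in N(v) of w(uv),

is the total reliability of its known interactions and is the quantity all
degree-aware adjustments in this package condition on.

Two normalized operators are derived from the weighted adjacency matrix:

* ``RW`` — the column-stochastic walk matrix P(u, v) = w(uv) / W(v), used
  by the random walk with restarts;
* ``NP`` — the symmetrically normalized propagation matrix
  P(u, v) = w(uv) / sqrt(W(u) W(v)), used by network propagation, whose
  spectral radius is at most 1.

Node ordering is lexicographic on gene identifiers and fixed at load time
so matrix builds are deterministic across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkValidationError",
    "TransitionMatrix",
    "WeightedNetwork",
    "load_network",
    "read_edge_list",
    "write_edge_list",
]


class NetworkValidationError(ValueError):
    """Raised when an edge list violates the network invariants."""


@dataclass(frozen=True)
class TransitionMatrix:
    """A normalized operator over a fixed node ordering.

    Parameters
    ----------
    kind
        ``"RW"`` for the column-stochastic walk matrix or ``"NP"`` for the
        symmetric propagation matrix.
    matrix
        Sparse CSR matrix; ``matrix[i, j]`` is the entry for the node pair
        ``(nodes[i], nodes[j])``.  Zero diagonal.
    nodes
        The lexicographic node ordering the rows/columns refer to.
    """

    kind: str
    matrix: sp.csr_matrix
    nodes: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index_of(self, gene: str) -> int:
        # built lazily to keep the dataclass frozen and hashable
        try:
            return self.nodes.index(gene)
        except ValueError as exc:  # pragma: no cover - defensive
            raise KeyError(gene) from exc


class WeightedNetwork:
    """Undirected gene/protein interaction network with edge reliabilities.

    Construct via :func:`load_network` or :func:`read_edge_list`; direct
    construction from a :class:`networkx.Graph` assumes weights were already
    validated.
    """

    def __init__(self, graph: nx.Graph):
        self._graph = graph
        self._nodes: tuple[str, ...] = tuple(sorted(graph.nodes))
        self._index: dict[str, int] = {g: i for i, g in enumerate(self._nodes)}
        self._wdeg: np.ndarray | None = None

    # -- basic accessors ---------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def nodes(self) -> tuple[str, ...]:
        """Nodes in the fixed lexicographic order used for matrices."""
        return self._nodes

    @property
    def node_index(self) -> dict[str, int]:
        return self._index

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def neighbors(self, gene: str) -> set[str]:
        if gene not in self._index:
            raise KeyError(gene)
        return set(self._graph[gene])

    def weight(self, u: str, v: str) -> float:
        return float(self._graph[u][v]["weight"])

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Canonical edges (lexicographically smaller gene first), sorted."""
        canon = sorted(
            (min(u, v), max(u, v), float(d["weight"]))
            for u, v, d in self._graph.edges(data=True)
        )
        return iter(canon)

    # -- degrees -----------------------------------------------------------

    def weighted_degree(self, gene: str) -> float:
        """W(v): total reliability of v's interactions."""
        if gene not in self._index:
            raise KeyError(gene)
        return float(self.weighted_degrees()[self._index[gene]])

    def weighted_degrees(self) -> np.ndarray:
        """Array of W(v) aligned with :attr:`nodes` (cached)."""
        if self._wdeg is None:
            adj = self.adjacency_matrix()
            self._wdeg = np.asarray(adj.sum(axis=0)).ravel()
        return self._wdeg

    @property
    def mean_weighted_degree(self) -> float:
        """m: the average weighted degree over all genes, the default
        threshold for degree stratification and rank merging."""
        return float(self.weighted_degrees().mean())

    # -- matrices ----------------------------------------------------------

    def adjacency_matrix(self) -> sp.csr_matrix:
        return nx.to_scipy_sparse_array(
            self._graph, nodelist=self._nodes, weight="weight", format="csr"
        )

    def transition_matrix(self, kind: str = "RW") -> TransitionMatrix:
        """Build the ``RW`` (column-stochastic) or ``NP`` (symmetric)
        normalized operator over the fixed node order."""
        adj = self.adjacency_matrix()
        wdeg = self.weighted_degrees()
        if kind == "RW":
            # column v scaled by 1/W(v)
            mat = adj.multiply(1.0 / wdeg[np.newaxis, :]).tocsr()
        elif kind == "NP":
            inv_sqrt = 1.0 / np.sqrt(wdeg)
            mat = adj.multiply(inv_sqrt[np.newaxis, :]).multiply(
                inv_sqrt[:, np.newaxis]
            ).tocsr()
            # make the symmetry exact rather than up-to-rounding
            mat = ((mat + mat.T) * 0.5).tocsr()
        else:
            raise ValueError(f"unknown transition matrix kind: {kind!r}")
        return TransitionMatrix(kind=kind, matrix=mat, nodes=self._nodes)


def load_network(
    edge_records: Iterable[Sequence],
) -> WeightedNetwork:
    """Build a validated :class:`WeightedNetwork` from edge records.

    Each record is ``(gene_a, gene_b, weight)``; a 2-element record is an
    unweighted edge and receives weight 1.0.  Duplicate and reciprocal
    records are collapsed keeping the maximum weight (with a warning);
    self-loops are dropped; nodes left without any edge are absent from the
    node set by construction.

    Raises
    ------
    NetworkValidationError
        On an empty input, a non-numeric weight, or a weight outside (0, 1].
    """
    graph = nx.Graph()
    n_dup = 0
    n_loops = 0
    seen_any = False
    for rec in edge_records:
        if len(rec) == 2:
            a, b = rec
            w = 1.0
        else:
            a, b, w = rec[0], rec[1], rec[2]
        a, b = str(a), str(b)
        try:
            w = float(w)
        except (TypeError, ValueError) as exc:
            raise NetworkValidationError(
                f"non-numeric weight in record ({a}, {b}, {w!r})"
            ) from exc
        if not (0.0 < w <= 1.0):
            raise NetworkValidationError(
                f"weight out of (0, 1] in record ({a}, {b}, {w})"
            )
        seen_any = True
        if a == b:
            n_loops += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            if w > graph[a][b]["weight"]:
                graph[a][b]["weight"] = w
        else:
            graph.add_edge(a, b, weight=w)
    if not seen_any:
        raise NetworkValidationError("empty edge list")
    if n_loops:
        logger.warning("dropped %d self-loop record(s)", n_loops)
    if n_dup:
        logger.warning(
            "collapsed %d duplicate/reciprocal edge record(s), keeping max weight",
            n_dup,
        )
    if graph.number_of_edges() == 0:
        raise NetworkValidationError("no edges remain after validation")
    return WeightedNetwork(graph)


def read_edge_list(path: str | Path) -> WeightedNetwork:
    """Read a TSV edge list (gene_a, gene_b[, weight]); '#' lines ignored."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            records.append(line.split("\t"))
    return load_network(records)


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    """Write canonicalized, sorted TSV edges (smaller gene first)."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, w in net.edges():
            fh.write(f"{u}\t{v}\t{w:.10g}\n")
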