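"""Directed-network data model, degree bookkeeping and file I/O.

A :class:`DirectedNetwork` is an ordered set of opaque string node
identifiers plus a set of directed, optionally weighted edges.  Duplicate
edges collapse to a single edge (the structural matching machinery is
multigraph-agnostic); self-loops are allowed.  Weights default to 1, are
ignored by the matching layer and consumed by the energy layer.

Matrix convention
-----------------
``a_ij != 0`` means there is a link from node *i* to node *j*.  For the
linear dynamics ``x'(t) = A x(t) + B u(t)`` the state equation of node *j*
must receive the influence of node *i*, so the weight of edge ``i -> j`` is
stored at **row j, column i** of the adjacency matrix returned by
:meth:`DirectedNetwork.adjacency_matrix`.  Node identifiers are opaque
strings everywhere except at this matrix boundary, where they map to dense
0-based indices in node insertion order.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "DirectedNetwork",
    "DegreeView",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_adjacency",
    "read_adjacency",
    "write_matrix",
    "read_matrix",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


class DirectedNetwork:
    """A directed, optionally weighted network with ordered string nodes."""

    def __init__(self) -> None:
        self._g = nx.DiGraph()

    # -- construction ----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable[str] = (),
    ) -> "DirectedNetwork":
        """Build a network from ``(u, v)`` or ``(u, v, weight)`` tuples.

        Extra isolated nodes may be supplied through ``nodes``; duplicate
        edges collapse silently (the first weight wins).
        """
        net = cls()
        for u in nodes:
            net.add_node(u)
        for e in edges:
            net.add_edge(*e)
        return net

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DirectedNetwork":
        if not g.is_directed():
            raise ValueError("only directed graphs are supported")
        net = cls()
        for u in g.nodes:
            net.add_node(u)
        for u, v, data in g.edges(data=True):
            net.add_edge(u, v, float(data.get("weight", 1.0)))
        return net

    def add_node(self, u) -> str:
        u = str(u)
        self._g.add_node(u)
        return u

    def add_edge(self, u, v, weight: float = 1.0) -> bool:
        """Add edge ``u -> v``; return False if it already existed."""
        u, v = str(u), str(v)
        if self._g.has_edge(u, v):
            return False
        self._g.add_edge(u, v, weight=float(weight))
        return True

    # -- basic queries ---------------------------------------------------

    @property
    def nodes(self) -> tuple:
        return tuple(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def mean_degree(self) -> float:
        """Mean degree mu = L / N (0 for the empty network)."""
        n = self.n_nodes
        return self.n_edges / n if n else 0.0

    def has_node(self, u) -> bool:
        return str(u) in self._g

    def has_edge(self, u, v) -> bool:
        return self._g.has_edge(str(u), str(v))

    def weight(self, u, v) -> float:
        return self._g.edges[str(u), str(v)]["weight"]

    def successors(self, u) -> tuple:
        return tuple(self._g.successors(str(u)))

    def predecessors(self, u) -> tuple:
        return tuple(self._g.predecessors(str(u)))

    def in_degree(self, u) -> int:
        return self._g.in_degree(str(u))

    def out_degree(self, u) -> int:
        return self._g.out_degree(str(u))

    def edges(self) -> Iterator[tuple]:
        """Iterate ``(u, v, weight)`` in insertion order."""
        for u, v, data in self._g.edges(data=True):
            yield u, v, data["weight"]

    def edge_set(self) -> frozenset:
        return frozenset((u, v) for u, v, _ in self.edges())

    def __contains__(self, u) -> bool:
        return self.has_node(u)

    def __repr__(self) -> str:  # pragma: no cover
        return f"DirectedNetwork(N={self.n_nodes}, L={self.n_edges})"

    # -- matrix boundary -------------------------------------------------

    def node_index(self) -> dict:
        """Map node id -> dense 0-based index in insertion order."""
        return {u: i for i, u in enumerate(self._g.nodes)}

    def adjacency_matrix(self, sparse: bool = False):
        """Weighted adjacency with edge ``i -> j`` at row j, column i."""
        idx = self.node_index()
        n = self.n_nodes
        rows, cols, vals = [], [], []
        for u, v, w in self.edges():
            rows.append(idx[v])
            cols.append(idx[u])
            vals.append(w)
        a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
        return a.tocsr() if sparse else a.toarray()

    def to_networkx(self) -> nx.DiGraph:
        return self._g.copy()


class DegreeView:
    """Degree bookkeeping against a (possibly pruned) adjacency.

    Besides plain in-/out-degrees this exposes the *u-degrees* used by the
    local matching game: the u-output degree of a node is the number of its
    child neighbours that have not yet been matched with a parent, and the
    u-input degree is the number of its parent neighbours not yet matched
    with a child.  ``matched_as_parent`` holds nodes that already own a
    matched child, ``matched_as_child`` nodes that already own a matched
    parent.
    """

    def __init__(
        self,
        net: DirectedNetwork | None = None,
        matched_as_parent: frozenset = frozenset(),
        matched_as_child: frozenset = frozenset(),
        succ: dict | None = None,
        pred: dict | None = None,
    ) -> None:
        if net is not None:
            succ = {u: set(net.successors(u)) for u in net.nodes}
            pred = {u: set(net.predecessors(u)) for u in net.nodes}
        if succ is None or pred is None:
            raise ValueError("provide either a network or succ/pred maps")
        self._succ = succ
        self._pred = pred
        self._mp = frozenset(matched_as_parent)
        self._mc = frozenset(matched_as_child)

    def in_degree(self, u) -> int:
        return len(self._pred[str(u)])

    def out_degree(self, u) -> int:
        return len(self._succ[str(u)])

    def u_in(self, u) -> int:
        """Number of parent neighbours without a matched child."""
        return sum(1 for p in self._pred[str(u)] if p not in self._mp)

    def u_out(self, u) -> int:
        """Number of child neighbours without a matched parent."""
        return sum(1 for c in self._succ[str(u)] if c not in self._mc)


# -- file formats --------------------------------------------------------


def read_edge_list(path, directed: bool = True) -> DirectedNetwork:
    """Read a whitespace-delimited edge list ``source target [weight]``.

    Lines starting with ``#`` are comments.  Node identifiers are kept
    verbatim; duplicate edges collapse to one with a single warning.
    """
    if not directed:
        raise ValueError("undirected networks are not supported")
    net = DirectedNetwork()
    dups = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise EdgeListParseError(
                    f"line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            weight = 1.0
            if len(parts) == 3:
                try:
                    weight = float(parts[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"line {lineno}: non-numeric weight {parts[2]!r}"
                    ) from exc
            if not net.add_edge(parts[0], parts[1], weight):
                dups += 1
    if dups:
        warnings.warn(f"collapsed {dups} duplicate edge(s)", stacklevel=2)
    return net


def write_edge_list(net: DirectedNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, w in net.edges():
            if w == 1.0:
                fh.write(f"{u}\t{v}\n")
            else:
                fh.write(f"{u}\t{v}\t{w:.17g}\n")


def read_graphml(path) -> DirectedNetwork:
    g = nx.read_graphml(path)
    if not g.is_directed():
        raise ValueError("GraphML file does not describe a directed graph")
    return DirectedNetwork.from_networkx(g)


def write_adjacency(net: DirectedNetwork, path) -> None:
    """Write the adjacency matrix in Matrix Market coordinate format."""
    if net.n_nodes == 0:
        raise ValueError("refusing to write an empty network")
    mmwrite(path, sp.coo_matrix(net.adjacency_matrix(sparse=True)))


def read_adjacency(path) -> DirectedNetwork:
    """Read a Matrix Market adjacency back into a network.

    Node identifiers become ``"1" .. "N"`` in matrix index order, so a
    write/read round trip preserves the adjacency matrix exactly (node
    names are a property of the network object, not of the matrix format).
    """
    a = sp.coo_matrix(mmread(path))
    net = DirectedNetwork()
    for i in range(a.shape[0]):
        net.add_node(str(i + 1))
    for j, i, w in zip(a.row, a.col, a.data):
        if w != 0:
            net.add_edge(str(i + 1), str(j + 1), float(w))
    return net


def write_matrix(path, m) -> None:
    """Write a dense or sparse real matrix (e.g. an input matrix B) as .mtx."""
    m = np.asarray(m, dtype=float)
    mmwrite(path, sp.coo_matrix(m))


def read_matrix(path) -> np.ndarray:
    return np.asarray(sp.coo_matrix(mmread(path)).todense(), dtype=float)
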