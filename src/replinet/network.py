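"""Dispersal networks: graph container, prototype topologies, stability bounds.

Nodes are labelled ``1..N``.  The adjacency matrix ``M`` is 0/1 with no
self-loops; ``c(i)`` is the set of neighbors whose state enters node ``i``'s
transport balance.  For directed graphs the default convention is
*incoming-flow*: an arc ``j -> i`` moves density from ``j``'s state into
``i``'s balance, so ``c(i)`` is the in-neighbor set (switchable to
out-neighbors via ``direction="out"``).

The coupling-strength bound for stability is ``nu < 1 / Delta`` with ``Delta``
the maximum degree: 1/2 for the in-line chain and the triangle, 1/3 for the
six-node roundabout.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .games import _as_matrix

__all__ = [
    "NetworkGraph",
    "StabilityCondition",
    "build_single",
    "build_inline",
    "build_triangle",
    "build_roundabout",
    "named_network",
    "check_stability_condition",
]

_EDGE_KEYS = ("nu", "p", "tau")


class NetworkGraph:
    """Node set + adjacency + per-edge transport parameters.

    Parameters
    ----------
    n_nodes
        Number of nodes; labels are ``1..N``.
    edges
        Iterable of ``(src, dst)`` pairs (arcs if ``directed``).
    directed
        Whether edges are one-way arcs.
    direction
        For directed graphs, whether ``c(i)`` collects in-neighbors
        (``"in"``, default) or out-neighbors (``"out"``).
    """

    def __init__(
        self,
        n_nodes: int,
        edges: Iterable[Tuple[int, int]] = (),
        *,
        directed: bool = False,
        direction: str = "in",
    ) -> None:
        if n_nodes < 1:
            raise ValueError("a network needs at least one node")
        if direction not in ("in", "out"):
            raise ValueError("direction must be 'in' or 'out'")
        self.directed = bool(directed)
        self.direction = direction
        self._g = nx.DiGraph() if directed else nx.Graph()
        self._g.add_nodes_from(range(1, n_nodes + 1))
        for i, j in edges:
            self.add_edge(i, j)

    # -- construction -----------------------------------------------------

    def add_edge(self, i: int, j: int, *, nu: Optional[float] = None,
                 p: Optional[float] = None, tau: Optional[float] = None) -> None:
        self._check_node(i)
        self._check_node(j)
        if i == j:
            raise ValueError("self-loops are not allowed")
        self._g.add_edge(i, j, nu=nu, p=p, tau=tau)

    def set_edge_params(self, i: int, j: int, **params) -> None:
        """Attach transport parameters (nu, p, tau) to an existing edge."""
        if not self._g.has_edge(i, j):
            raise KeyError(f"no edge ({i}, {j})")
        for key, value in params.items():
            if key not in _EDGE_KEYS:
                raise KeyError(f"unknown edge parameter {key!r}")
            if value is not None and value < 0:
                raise ValueError(f"edge parameter {key} must be nonnegative")
            self._g.edges[i, j][key] = value

    # -- queries ----------------------------------------------------------

    @property
    def N(self) -> int:
        return self._g.number_of_nodes()

    def _check_node(self, i: int) -> None:
        if not (1 <= i <= self._g.number_of_nodes()):
            raise IndexError(f"node index {i} out of range 1..{self._g.number_of_nodes()}")

    def neighbors(self, i: int) -> set:
        """The transport-relevant neighbor set ``c(i)``."""
        self._check_node(i)
        if not self.directed:
            return set(self._g.neighbors(i))
        if self.direction == "in":
            return set(self._g.predecessors(i))
        return set(self._g.successors(i))

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    def max_degree(self) -> int:
        """``Delta = max_i |c(i)|``."""
        return max(self.degree(i) for i in range(1, self.N + 1))

    def stability_bound(self) -> float:
        """``1 / Delta``; +inf for an edgeless graph (no constraint)."""
        delta = self.max_degree()
        return math.inf if delta == 0 else 1.0 / delta

    def adjacency(self) -> np.ndarray:
        """0/1 adjacency matrix; entry ``[i-1, j-1]`` marks edge i->j (or i-j)."""
        return nx.to_numpy_array(self._g, nodelist=range(1, self.N + 1), weight=None)

    def edges(self):
        """Iterate ``(i, j, params)`` over stored edges/arcs."""
        for i, j, data in self._g.edges(data=True):
            yield i, j, {k: data.get(k) for k in _EDGE_KEYS}

    def edge_param(self, i: int, j: int, key: str):
        """Stored parameter on the edge carrying flow from ``j`` into ``i``
        (``None`` when unset).  For undirected graphs order is irrelevant;
        for directed graphs the arc is looked up per the direction convention."""
        if key not in _EDGE_KEYS:
            raise KeyError(f"unknown edge parameter {key!r}")
        if not self.directed:
            return self._g.edges[i, j].get(key) if self._g.has_edge(i, j) else None
        arc = (j, i) if self.direction == "in" else (i, j)
        return self._g.edges[arc].get(key) if self._g.has_edge(*arc) else None

    # -- I/O ---------------------------------------------------------------

    def to_edgelist_csv(self, path) -> None:
        """Write ``src,dst,nu,p,tau`` rows (1-based node labels)."""
        rows = [
            {"src": i, "dst": j, **params}
            for i, j, params in self.edges()
        ]
        pd.DataFrame(rows, columns=["src", "dst", "nu", "p", "tau"]).to_csv(
            path, index=False
        )

    @classmethod
    def from_edgelist_csv(cls, path, *, directed: bool = False,
                          n_nodes: Optional[int] = None,
                          direction: str = "in") -> "NetworkGraph":
        df = pd.read_csv(path)
        expected = ["src", "dst", "nu", "p", "tau"]
        if list(df.columns) != expected:
            raise ValueError(f"edge list must have columns {expected}, got {list(df.columns)}")
        if n_nodes is None:
            n_nodes = int(max(df["src"].max(), df["dst"].max())) if len(df) else 1
        G = cls(n_nodes, directed=directed, direction=direction)
        for row in df.itertuples(index=False):
            params = {
                k: (None if pd.isna(getattr(row, k)) else float(getattr(row, k)))
                for k in _EDGE_KEYS
            }
            G.add_edge(int(row.src), int(row.dst), **params)
        return G

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return f"NetworkGraph(N={self.N}, {kind}, edges={self._g.number_of_edges()})"


# -- prototype topologies --------------------------------------------------


def build_single() -> NetworkGraph:
    """One isolated node (plain single-patch replicator dynamics)."""
    return NetworkGraph(1)


def build_inline(N: int) -> NetworkGraph:
    """Undirected chain 1-2-...-N."""
    if N < 2:
        raise ValueError("an in-line network needs at least two nodes")
    return NetworkGraph(N, [(i, i + 1) for i in range(1, N)])


def build_triangle(oriented: bool = False) -> NetworkGraph:
    """Three mutually connected nodes; the oriented variant is the directed
    cycle 1->3->2->1, which under the incoming-flow convention couples node 3
    directly to node 1 (so node 3 equilibrates before node 2)."""
    if not oriented:
        return NetworkGraph(3, [(1, 2), (2, 3), (1, 3)])
    return NetworkGraph(3, [(1, 3), (3, 2), (2, 1)], directed=True)


def build_roundabout(oriented: bool = False) -> NetworkGraph:
    """Six nodes: chain ends 1-2 and 5-6 around the quadrangle 2-3-5-4.

    Removing node 3 or node 4 leaves the chain 1-2-4-5-6 (resp. 1-2-3-5-6).
    The oriented variant directs the quadrangle as 2->4->5->3->2 with feeds
    1->2 and 5->6, which makes nodes 3 and 6 share the single upstream
    neighbor 5 (their trajectories then coincide for identical initial data).
    """
    if not oriented:
        return NetworkGraph(6, [(1, 2), (2, 3), (2, 4), (3, 5), (4, 5), (5, 6)])
    return NetworkGraph(
        6, [(1, 2), (3, 2), (2, 4), (4, 5), (5, 3), (5, 6)], directed=True
    )


_NAMED_BUILDERS = {
    "single": lambda **kw: build_single(),
    "inline": lambda **kw: build_inline(kw.get("n_nodes", 3)),
    "triangle": lambda **kw: build_triangle(False),
    "triangle-oriented": lambda **kw: build_triangle(True),
    "roundabout": lambda **kw: build_roundabout(False),
    "roundabout-oriented": lambda **kw: build_roundabout(True),
}


def named_network(name: str, **kwargs) -> NetworkGraph:
    """Build one of the prototype networks by name."""
    try:
        builder = _NAMED_BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown network {name!r}; available: {sorted(_NAMED_BUILDERS)}"
        ) from None
    return builder(**kwargs)


# -- stability condition ---------------------------------------------------


@dataclass(frozen=True)
class StabilityCondition:
    """Per-node margins of the coupled-stability inequality.

    ``margin_i = (x*)^T A x^i - (x^i)^T A x^i - nu |c(i)|``; the coupled
    equilibrium is certified asymptotically stable (via the relative-entropy
    Lyapunov function) when every margin is positive.
    """

    nu: float
    delta: int
    bound: float
    satisfied: bool
    per_node_margins: np.ndarray


def check_stability_condition(G: NetworkGraph, A, xstar, states, nu: float) -> StabilityCondition:
    """Evaluate the per-node stability margins at an ensemble of node states.

    With ``nu = 0`` this reduces to the pointwise ESS inequality
    ``(x*)^T A x > x^T A x``.  Note the inequality fails identically at
    ``x^i = x*`` for ``nu > 0`` (the first two terms cancel); it is a
    sufficient condition on a punctured neighborhood.
    """
    M = _as_matrix(A)
    xs = np.asarray(xstar, dtype=float)
    X = np.asarray(states, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape != (G.N, M.shape[0]):
        raise ValueError(
            f"expected states of shape ({G.N}, {M.shape[0]}), got {X.shape}"
        )
    F = X @ M.T  # row i = A x^i
    margins = F @ xs - np.einsum("ij,ij->i", X, F)
    margins = margins - nu * np.array([G.degree(i) for i in range(1, G.N + 1)])
    delta = G.max_degree()
    return StabilityCondition(
        nu=float(nu),
        delta=delta,
        bound=G.stability_bound(),
        satisfied=bool(np.all(margins > 0)),
        per_node_margins=margins,
    )
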