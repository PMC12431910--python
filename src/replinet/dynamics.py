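"""Full networked right-hand side and runtime monitors.

Each node ``i`` carries a state ``x^i`` on the simplex and evolves by its
local replicator field plus the transport exchange with its neighbors:

    dx^i_k/dt = x^i_k ((A^i x^i)_k - (x^i)^T A^i x^i) + T_k(x^i, ...)

For linear transport every row of the right-hand side sums to zero whenever
all node states are on the simplex, so per-node density is conserved exactly
by the continuous flow (the simplex-invariance mechanism); the integrator
monitors the discrete drift and refuses to continue silently if it grows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Union

import numpy as np

from .games import PayoffMatrix, _as_matrix
from .network import NetworkGraph
from .transport import HistoryBuffer, TransportSpec

__all__ = [
    "EnsembleState",
    "ModelSpec",
    "SimplexDriftError",
    "network_rhs",
    "make_rhs",
    "lyapunov_V",
    "simplex_drift",
]


@dataclass
class EnsembleState:
    """Node-by-species frequencies (N x n) at one instant."""

    values: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        v = np.array(self.values, dtype=float)
        if v.ndim == 1:
            v = v[None, :]
        if v.ndim != 2:
            raise ValueError(f"ensemble state must be 2-D (N x n), got shape {v.shape}")
        self.values = v


class SimplexDriftError(RuntimeError):
    """Raised when integrated states leave the simplex beyond the guard
    tolerance, signalling an integration-parameter problem."""


def _ensure_array(x) -> np.ndarray:
    if isinstance(x, EnsembleState):
        return x.values
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


class ModelSpec:
    """Network + per-node games + transport: the complete model definition.

    ``payoffs`` is a single shared :class:`PayoffMatrix` (or array) or a
    sequence of ``N`` of them with a common species count.
    """

    def __init__(
        self,
        graph: NetworkGraph,
        payoffs: Union[PayoffMatrix, np.ndarray, Sequence],
        transport: Optional[TransportSpec] = None,
    ) -> None:
        self.graph = graph
        self.transport = transport or TransportSpec()
        if isinstance(payoffs, PayoffMatrix):
            mats = [payoffs.entries]
        else:
            try:
                arr = np.asarray(payoffs, dtype=float)
            except (TypeError, ValueError):
                arr = None
            if arr is not None and arr.ndim == 2:
                mats = [_as_matrix(arr)]
            else:
                mats = [_as_matrix(p) for p in payoffs]
        if len(mats) not in (1, graph.N):
            raise ValueError(
                f"need 1 or {graph.N} payoff matrices, got {len(mats)}"
            )
        n = mats[0].shape[0]
        if any(m.shape != (n, n) for m in mats):
            raise ValueError("all payoff matrices must share one species count")
        self.shared_payoff = len(mats) == 1
        self._A = mats[0] if self.shared_payoff else np.stack(mats)
        self.n_species = n
        self._compile_transport()

    @property
    def N(self) -> int:
        return self.graph.N

    def payoff(self, i: int) -> np.ndarray:
        """Payoff matrix at node ``i`` (1-based)."""
        return self._A if self.shared_payoff else self._A[i - 1]

    # -- compiled operators -------------------------------------------------

    def _compile_transport(self) -> None:
        G, spec = self.graph, self.transport
        N = G.N
        self._W = None          # linear: rhs += W @ X
        self._E = None          # delayed: rhs += E @ X(t) - sum_d coeff_d * X(t - d)
        self._delay_groups: List = []
        if spec.kind == "linear":
            W = np.zeros((N, N))
            for i in range(1, N + 1):
                for j in G.neighbors(i):
                    v = spec.edge_value(G, i, j, "nu")
                    if v < 0:
                        raise ValueError(f"negative nu on edge ({i}, {j})")
                    W[i - 1, j - 1] += v
                    W[i - 1, i - 1] -= v
            self._W = W
        elif spec.kind == "delayed":
            E = np.zeros((N, N))
            groups: dict = {}
            arcs = []  # (receiver, sender, weight, delay)
            for i in range(1, N + 1):
                for j in G.neighbors(i):
                    pij = spec.edge_value(G, i, j, "p")
                    tij = spec.edge_value(G, i, j, "tau")
                    if pij < 0 or tij < 0:
                        raise ValueError(f"negative p or tau on edge ({i}, {j})")
                    w = float(np.exp(-pij * tij))
                    arcs.append((i, j, w, tij))
                    E[i - 1, j - 1] += w
                    groups.setdefault(tij, np.zeros(N))[i - 1] += w
            self._arrival_arcs = arcs
            self._E = E
            self._delay_groups = sorted(groups.items())
        self.max_delay = max((d for d, _ in self._delay_groups), default=0.0)

    def replicator_term(self, X: np.ndarray) -> np.ndarray:
        if self.shared_payoff:
            F = X @ self._A.T
        else:
            F = np.einsum("ikj,ij->ik", self._A, X)
        avg = np.einsum("ij,ij->i", X, F)
        return X * (F - avg[:, None])

    def transport_term(
        self, X: np.ndarray, t: float, history: Optional[HistoryBuffer]
    ) -> np.ndarray:
        spec = self.transport
        if spec.kind == "none":
            return np.zeros_like(X)
        if spec.kind == "linear":
            return self._W @ X
        # delayed
        if any(d > 0 for d, _ in self._delay_groups) and history is None:
            raise ValueError("delayed transport with tau > 0 requires a history buffer")
        if spec.delayed_form == "arrivals":
            out = np.zeros_like(X)
            for i, j, w, d in self._arrival_arcs:
                past = X if d == 0.0 else history.interpolate(t - d)
                out[i - 1] += w * (past[j - 1] - X[i - 1])
            return out
        out = self._E @ X
        for d, coeff in self._delay_groups:
            past = X if d == 0.0 else history.interpolate(t - d)
            out -= coeff[:, None] * past
        return out


def network_rhs(
    model: ModelSpec,
    x,
    t: float = 0.0,
    history: Optional[HistoryBuffer] = None,
) -> np.ndarray:
    """Right-hand side of the coupled system: replicator + transport, row per node."""
    X = _ensure_array(x)
    if X.shape != (model.N, model.n_species):
        raise ValueError(
            f"expected state of shape ({model.N}, {model.n_species}), got {X.shape}"
        )
    return model.replicator_term(X) + model.transport_term(X, t, history)


def make_rhs(
    model: ModelSpec, history: Optional[HistoryBuffer] = None
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Bind a model (and history) into the ``f(t, X)`` contract the integrator uses."""

    def f(t: float, X: np.ndarray) -> np.ndarray:
        return model.replicator_term(X) + model.transport_term(X, t, history)

    return f


def lyapunov_V(xstar, x) -> float:
    """Relative-entropy Lyapunov function
    ``V = -sum_i sum_k x*_k ln(x^i_k / x*_k)`` (>= 0, zero iff every node is
    at ``x*``); non-increasing along trajectories when ``x*`` is an ESS and
    the coupling satisfies the stability margin."""
    xs = np.asarray(xstar, dtype=float)
    X = _ensure_array(x)
    if np.any(X <= 0):
        raise ValueError("Lyapunov function requires strictly positive frequencies")
    if np.any(xs <= 0):
        raise ValueError("the reference equilibrium must be strictly interior")
    return float(-np.sum(xs * np.log(X / xs)))


def simplex_drift(x) -> tuple:
    """Monitor: (max over nodes of |row sum - 1|, min coordinate)."""
    X = _ensure_array(x)
    return (
        float(np.max(np.abs(X.sum(axis=1) - 1.0))),
        float(X.min()),
    )
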