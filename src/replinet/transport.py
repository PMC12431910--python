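"""Inter-node exchange terms and trajectory history for delay lookups.

Two exchange mechanisms couple the node-local replicator dynamics:

* linear velocity transport
  ``T^nu_i = sum_{j in c(i)} nu_ij (x^j(t) - x^i(t))`` — instantaneous
  diffusive mixing with per-edge transfer velocity ``nu``;
* delayed, survival-weighted transport
  ``T^p_i = sum_{j in c(i)} exp(-p_ij tau_ij) (x^j(t) - x^i(t - tau_ij))`` —
  journeys take ``tau`` time units and only a fraction ``exp(-p tau)``
  survives them.

The delayed form needs past states between accepted integrator steps; the
:class:`HistoryBuffer` stores accepted states and right-hand sides and
answers lookups by cubic Hermite interpolation, which is locally fourth-order
accurate and therefore does not throttle the integrator's convergence order.
Before the initial time the history is the constant initial condition.
"""
from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np

__all__ = [
    "TransportSpec",
    "HistoryBuffer",
    "linear_transport",
    "delayed_transport",
    "interpolate_history",
]

ParamMap = Union[float, Dict[Tuple[int, int], float]]


@dataclass
class TransportSpec:
    """Selects the transport mechanism and its parameters.

    ``kind`` is ``"none"``, ``"linear"`` (uses ``nu``) or ``"delayed"``
    (uses ``p`` and ``tau``).  Scalars apply network-wide; per-edge values
    stored on the graph (or in ``per_edge``, keyed by ``(src, dst)``)
    override them.  ``delayed_form="arrivals"`` switches the delayed term to
    ``exp(-p tau)(x^j(t - tau) - x^i(t))`` for sensitivity checks only.
    """

    kind: str = "none"
    nu: float = 0.0
    p: float = 0.0
    tau: float = 0.0
    per_edge: Dict[Tuple[int, int], Dict[str, float]] = field(default_factory=dict)
    delayed_form: str = "printed"

    def __post_init__(self) -> None:
        if self.kind not in ("none", "linear", "delayed"):
            raise ValueError(f"unknown transport kind {self.kind!r}")
        if self.delayed_form not in ("printed", "arrivals"):
            raise ValueError(f"unknown delayed_form {self.delayed_form!r}")
        if self.kind == "linear" and self.nu < 0:
            raise ValueError("transfer velocity nu must be nonnegative")
        if self.kind == "delayed" and (self.p < 0 or self.tau < 0):
            raise ValueError("survival rate p and travel time tau must be nonnegative")

    def edge_value(self, G, i: int, j: int, key: str) -> float:
        """Effective parameter on the edge feeding node ``i`` from ``j``.

        Priority: value stored on the graph edge, then the ``per_edge``
        override (either key order), then the global scalar.
        """
        stored = G.edge_param(i, j, key)
        if stored is not None:
            return float(stored)
        for pair in ((i, j), (j, i)):
            if pair in self.per_edge and key in self.per_edge[pair]:
                return float(self.per_edge[pair][key])
        return float(getattr(self, key))


class HistoryBuffer:
    """Accepted-step states and derivatives, with dense cubic-Hermite output.

    Queries at ``t <= t0`` return the initial state exactly (constant
    pre-history); queries between stored times use the bracketing Hermite
    segment; queries up to one step beyond the last accepted time use the
    last segment's polynomial extension (needed for stage-time delay lookups
    during the current step).
    """

    def __init__(self, t0: float, initial_state: np.ndarray, initial_deriv: np.ndarray):
        self.t0 = float(t0)
        self.initial_state = np.array(initial_state, dtype=float)
        self.times = [self.t0]
        self.states = [self.initial_state.copy()]
        self.derivs = [np.array(initial_deriv, dtype=float)]
        self._cache: Dict[float, np.ndarray] = {}

    @property
    def t_last(self) -> float:
        return self.times[-1]

    def append(self, t: float, state: np.ndarray, deriv: np.ndarray) -> None:
        if t <= self.times[-1]:
            raise ValueError(f"history times must increase: {t} <= {self.times[-1]}")
        self.times.append(float(t))
        self.states.append(np.array(state, dtype=float))
        self.derivs.append(np.array(deriv, dtype=float))
        self._cache.clear()

    def interpolate(self, t: float) -> np.ndarray:
        """Dense-output state at time ``t``."""
        if t <= self.t0:
            return self.initial_state
        cached = self._cache.get(t)
        if cached is not None:
            return cached
        if len(self.times) == 1:
            # No accepted step yet: fall back to constant history.
            value = self.initial_state
        else:
            last_h = self.times[-1] - self.times[-2]
            if t > self.times[-1] + last_h * (1 + 1e-9):
                raise ValueError(
                    f"history covers up to t={self.times[-1]} (+ one-step "
                    f"extension), cannot interpolate at t={t}"
                )
            hi = bisect_right(self.times, t)
            hi = min(max(hi, 1), len(self.times) - 1)
            value = _hermite(
                self.times[hi - 1], self.times[hi],
                self.states[hi - 1], self.states[hi],
                self.derivs[hi - 1], self.derivs[hi], t,
            )
        self._cache[t] = value
        return value


def _hermite(t0, t1, y0, y1, d0, d1, t):
    h = t1 - t0
    s = (t - t0) / h
    s2 = s * s
    s3 = s2 * s
    return (
        (2 * s3 - 3 * s2 + 1) * y0
        + (s3 - 2 * s2 + s) * h * d0
        + (-2 * s3 + 3 * s2) * y1
        + (s3 - s2) * h * d1
    )


def interpolate_history(H: HistoryBuffer, t: float) -> np.ndarray:
    """Functional alias for :meth:`HistoryBuffer.interpolate`."""
    return H.interpolate(t)


def _edge_scalar(value: ParamMap, i: int, j: int) -> float:
    if isinstance(value, dict):
        if (i, j) in value:
            return float(value[(i, j)])
        if (j, i) in value:
            return float(value[(j, i)])
        raise KeyError(f"no parameter for edge ({i}, {j})")
    return float(value)


def linear_transport(states: np.ndarray, G, nu: ParamMap) -> np.ndarray:
    """Velocity transport ``row i = sum_{j in c(i)} nu_ij (x^j - x^i)``.

    ``nu`` is a scalar or a ``{(i, j): nu}`` map.  Row sums over species
    vanish whenever all node states are on the simplex, which is the
    mechanism preserving per-node density under coupling.
    """
    X = np.asarray(states, dtype=float)
    out = np.zeros_like(X)
    for i in range(1, G.N + 1):
        for j in G.neighbors(i):
            v = _edge_scalar(nu, i, j)
            if v < 0:
                raise ValueError(f"negative transfer velocity on edge ({i}, {j})")
            out[i - 1] += v * (X[j - 1] - X[i - 1])
    return out


def delayed_transport(
    H: HistoryBuffer,
    t: float,
    G,
    p: ParamMap,
    tau: ParamMap,
    states: Optional[np.ndarray] = None,
    *,
    arrivals: bool = False,
) -> np.ndarray:
    """Survival-weighted delayed transport.

    ``row i = sum_{j in c(i)} exp(-p_ij tau_ij) (x^j(t) - x^i(t - tau_ij))``
    as printed; with ``arrivals=True`` the alternative form
    ``exp(-p tau)(x^j(t - tau) - x^i(t))`` is used instead (sensitivity
    checks only).  ``states`` supplies the ensemble at time ``t`` (stage
    values during a step); when omitted it is interpolated from history.
    With ``p = 0`` and ``tau = 0`` the printed form reduces exactly to
    linear transport with unit velocity.
    """
    if states is None:
        states = H.interpolate(t)
    X = np.asarray(states, dtype=float)
    out = np.zeros_like(X)
    delayed_cache: Dict[float, np.ndarray] = {}
    for i in range(1, G.N + 1):
        for j in G.neighbors(i):
            pij = _edge_scalar(p, i, j)
            tij = _edge_scalar(tau, i, j)
            if pij < 0 or tij < 0:
                raise ValueError(f"negative p or tau on edge ({i}, {j})")
            weight = np.exp(-pij * tij)
            if tij == 0.0:
                past = X
            else:
                key = t - tij
                past = delayed_cache.get(key)
                if past is None:
                    past = H.interpolate(key)
                    delayed_cache[key] = past
            if arrivals:
                out[i - 1] += weight * (past[j - 1] - X[i - 1])
            else:
                out[i - 1] += weight * (X[j - 1] - past[i - 1])
    return out
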