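"""Fourth-order Gauss-Legendre implicit Runge-Kutta in predictor-corrector form.

The two-stage Gauss-Legendre method (collocation at the Gauss points
``c = 1/2 -+ sqrt(3)/6``) is implicit, A-stable and fourth-order; on linear
problems its amplification factor is the (2,2) Pade approximant of the
exponential, which makes it essentially non-dissipative on oscillatory
replicator orbits where first-order Euler schemes visibly blow up (explicit)
or damp (implicit).

The implicit stage equations are solved P-(EC)^k style: explicit-Euler
predictors at the stage abscissae, then functional (fixed-point) corrector
sweeps of

    k_i <- f(t_n + c_i dt, y_n + dt sum_j a_ij k_j)

until ``max(||k1 - k1^C||_2, ||k2 - k2^C||_2) < epsilon``.  Functional
iteration contracts whenever ``dt`` times the local Lipschitz constant is
below one (all bounded-payoff experiments here); a Newton fallback on the
stage system (finite-difference Jacobian) covers stiff probes where it does
not.  First-order explicit/implicit Euler steps are provided as baselines.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .dynamics import EnsembleState, ModelSpec, SimplexDriftError, make_rhs, simplex_drift
from .transport import HistoryBuffer

__all__ = [
    "IntegratorConfig",
    "Trajectory",
    "CorrectorError",
    "gl4_tableau",
    "pec_step",
    "solve_stages_newton",
    "euler_explicit_step",
    "euler_implicit_step",
    "integrate",
]

_SQRT3 = math.sqrt(3.0)

_METHODS = ("gl4pec", "euler_explicit", "euler_implicit")


@dataclass
class IntegratorConfig:
    """Fixed-step integration settings.

    ``epsilon`` is the corrector tolerance on the stage residuals (Euclidean
    norm over all components); ``drift_guard`` aborts a run whose per-node
    density drifts beyond it, which signals a time step too large for the
    corrector to contract.
    """

    dt: float
    t_end: float
    epsilon: float = 1e-12
    max_corrector_iters: int = 50
    method: str = "gl4pec"
    newton_fallback: bool = True
    drift_guard: float = 1e-6
    negativity_guard: float = 0.1

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_corrector_iters < 1:
            raise ValueError("max_corrector_iters must be at least 1")
        if self.method not in _METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {_METHODS}")


class CorrectorError(RuntimeError):
    """Corrector failed to meet the stage-residual tolerance."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"stage corrector did not converge: residual {residual:.3e} after "
            f"{iterations} iterations (dt likely too large for contraction)"
        )


def gl4_tableau():
    """Butcher tableau (a, b, c) of the two-stage Gauss-Legendre method."""
    a = np.array(
        [
            [0.25, 0.25 - _SQRT3 / 6.0],
            [0.25 + _SQRT3 / 6.0, 0.25],
        ]
    )
    b = np.array([0.5, 0.5])
    c = np.array([0.5 - _SQRT3 / 6.0, 0.5 + _SQRT3 / 6.0])
    return a, b, c


def _stage_points(y, t, dt, k1, k2, a, c):
    y1 = y + dt * (a[0, 0] * k1 + a[0, 1] * k2)
    y2 = y + dt * (a[1, 0] * k1 + a[1, 1] * k2)
    return (t + c[0] * dt, y1), (t + c[1] * dt, y2)


def _gl4_step(f, y, t, dt, f0, epsilon, max_iters, newton_fallback):
    """One predictor-corrector step; ``f0 = f(t, y)`` is reused from history."""
    a, b, c = gl4_tableau()
    # Explicit-Euler predictors at the stage abscissae.
    k1 = f(t + c[0] * dt, y + c[0] * dt * f0)
    k2 = f(t + c[1] * dt, y + c[1] * dt * f0)
    iterations = 0
    converged = False
    residual = math.inf
    for _ in range(max_iters):
        (t1, y1), (t2, y2) = _stage_points(y, t, dt, k1, k2, a, c)
        k1c = f(t1, y1)
        k2c = f(t2, y2)
        iterations += 1
        residual = max(
            float(np.linalg.norm(k1 - k1c)), float(np.linalg.norm(k2 - k2c))
        )
        k1, k2 = k1c, k2c
        if residual < epsilon:
            converged = True
            break
    if not converged:
        if not newton_fallback:
            raise CorrectorError(residual, iterations)
        k1, k2 = solve_stages_newton(f, y, t, dt, k1, k2, epsilon)
    y_next = y + 0.5 * dt * (k1 + k2)
    return y_next, iterations


def pec_step(
    f: Callable[[float, np.ndarray], np.ndarray],
    y: np.ndarray,
    t: float,
    dt: float,
    *,
    epsilon: float = 1e-12,
    max_iters: int = 50,
    newton_fallback: bool = True,
):
    """One Gauss-Legendre step from ``(t, y)``; returns ``(y_next, iterations)``."""
    y = np.asarray(y, dtype=float)
    return _gl4_step(f, y, t, dt, f(t, y), epsilon, max_iters, newton_fallback)


def _fd_jacobian(f, t, y):
    y = np.asarray(y, dtype=float)
    m = y.size
    flat = y.ravel()
    f0 = np.asarray(f(t, y)).ravel()
    J = np.empty((m, m))
    for col in range(m):
        eps = 1e-7 * (1.0 + abs(flat[col]))
        pert = flat.copy()
        pert[col] += eps
        J[:, col] = (np.asarray(f(t, pert.reshape(y.shape))).ravel() - f0) / eps
    return J


def solve_stages_newton(f, y, t, dt, k1, k2, epsilon, max_iters: int = 25):
    """Solve the two implicit stage equations by Newton iteration.

    The Jacobian of ``f`` is approximated by forward differences at the
    current stage points; exact for linear problems, ample for the small
    systems integrated here.  Used as the fallback when functional iteration
    does not contract (stiff probes).
    """
    a, b, c = gl4_tableau()
    y = np.asarray(y, dtype=float)
    m = y.size
    k = np.concatenate([np.asarray(k1).ravel(), np.asarray(k2).ravel()])
    shape = np.asarray(k1).shape
    eye = np.eye(2 * m)
    residual = math.inf
    for iteration in range(max_iters):
        k1m, k2m = k[:m].reshape(shape), k[m:].reshape(shape)
        (t1, y1), (t2, y2) = _stage_points(y, t, dt, k1m, k2m, a, c)
        g = np.concatenate(
            [
                k[:m] - np.asarray(f(t1, y1)).ravel(),
                k[m:] - np.asarray(f(t2, y2)).ravel(),
            ]
        )
        residual = float(np.linalg.norm(g))
        if residual < epsilon:
            return k[:m].reshape(shape), k[m:].reshape(shape)
        J1 = _fd_jacobian(f, t1, y1)
        J2 = _fd_jacobian(f, t2, y2)
        JG = eye.copy()
        JG[:m, :m] -= dt * a[0, 0] * J1
        JG[:m, m:] -= dt * a[0, 1] * J1
        JG[m:, :m] -= dt * a[1, 0] * J2
        JG[m:, m:] -= dt * a[1, 1] * J2
        k = k - np.linalg.solve(JG, g)
    raise CorrectorError(residual, max_iters)


def euler_explicit_step(f, y, t, dt):
    """First-order explicit Euler baseline."""
    y = np.asarray(y, dtype=float)
    return y + dt * f(t, y)


def euler_implicit_step(f, y, t, dt, *, epsilon: float = 1e-12, max_iters: int = 50):
    """First-order implicit Euler baseline, solved by Newton iteration."""
    y = np.asarray(y, dtype=float)
    m = y.size
    z = (y + dt * f(t, y)).ravel()  # explicit predictor
    target = y.ravel()
    eye = np.eye(m)
    residual = math.inf
    for _ in range(max_iters):
        zy = z.reshape(y.shape)
        fz = np.asarray(f(t + dt, zy)).ravel()
        g = z - target - dt * fz
        residual = float(np.linalg.norm(g))
        if residual < epsilon:
            return z.reshape(y.shape)
        J = eye - dt * _fd_jacobian(f, t + dt, zy)
        z = z - np.linalg.solve(J, g)
    raise CorrectorError(residual, max_iters)


@dataclass
class Trajectory:
    """Uniformly sampled solution: times, states (steps+1, N, n), history, meta."""

    times: np.ndarray
    states: np.ndarray
    history: Optional[HistoryBuffer] = None
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]

    @property
    def n_species(self) -> int:
        return self.states.shape[2]

    def node(self, i: int) -> np.ndarray:
        """Time series of node ``i`` (1-based), shape (steps+1, n)."""
        return self.states[:, i - 1, :]

    def final_state(self) -> EnsembleState:
        return EnsembleState(self.states[-1].copy(), time=float(self.times[-1]))

    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        """Tidy table with columns time, node, species, frequency."""
        sel = slice(None, None, stride)
        times = self.times[sel]
        states = self.states[sel]
        m, N, n = states.shape
        return pd.DataFrame(
            {
                "time": np.repeat(times, N * n),
                "node": np.tile(np.repeat(np.arange(1, N + 1), n), m),
                "species": np.tile(np.arange(1, n + 1), m * N),
                "frequency": states.ravel(),
            }
        )

    def write_csv(self, path, stride: int = 1) -> None:
        self.to_frame(stride=stride).to_csv(path, index=False, float_format="%.17g")


def integrate(model: ModelSpec, x0, cfg: IntegratorConfig) -> Trajectory:
    """Fixed-step march of the networked replicator system to ``t_end``.

    Accepted steps (states and right-hand sides) are appended to a history
    buffer that serves the delayed-transport lookups; predictor/corrector
    stage values never enter the history.  Deterministic for fixed inputs.
    """
    if isinstance(x0, EnsembleState):
        X = x0.values.copy()
    else:
        X = np.asarray(x0, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        X = X.copy()
    if X.shape != (model.N, model.n_species):
        raise ValueError(
            f"initial condition must have shape ({model.N}, {model.n_species}), "
            f"got {X.shape}"
        )
    n_steps = int(round(cfg.t_end / cfg.dt))
    if abs(n_steps * cfg.dt - cfg.t_end) > 1e-9 * max(1.0, cfg.t_end):
        raise ValueError(f"t_end={cfg.t_end} is not an integer number of steps of dt={cfg.dt}")

    history = HistoryBuffer(0.0, X, np.zeros_like(X))
    f = make_rhs(model, history)
    history.derivs[0] = f(0.0, X)

    times = np.linspace(0.0, n_steps * cfg.dt, n_steps + 1)
    states = np.empty((n_steps + 1, model.N, model.n_species))
    states[0] = X

    total_iters = 0
    max_iters_seen = 0
    max_drift = 0.0
    min_coord = float(X.min())

    for step in range(n_steps):
        t = times[step]
        if cfg.method == "gl4pec":
            X, iters = _gl4_step(
                f, X, t, cfg.dt, history.derivs[-1],
                cfg.epsilon, cfg.max_corrector_iters, cfg.newton_fallback,
            )
            total_iters += iters
            max_iters_seen = max(max_iters_seen, iters)
        elif cfg.method == "euler_explicit":
            X = euler_explicit_step(f, X, t, cfg.dt)
        else:
            X = euler_implicit_step(
                f, X, t, cfg.dt, epsilon=cfg.epsilon, max_iters=cfg.max_corrector_iters
            )
        t_next = times[step + 1]
        drift, mincoord = simplex_drift(X)
        max_drift = max(max_drift, drift)
        min_coord = min(min_coord, mincoord)
        if drift > cfg.drift_guard:
            raise SimplexDriftError(
                f"per-node density drift {drift:.3e} exceeds guard "
                f"{cfg.drift_guard:.1e} at t={t_next:.4g}; reduce dt"
            )
        if mincoord < -cfg.negativity_guard:
            raise SimplexDriftError(
                f"a species frequency reached {mincoord:.3g} at t={t_next:.4g}: "
                "the state has left the simplex (delayed transport does not "
                "guarantee positivity) and the off-simplex dynamics is "
                "divergent; shorten the horizon"
            )
        states[step + 1] = X
        history.append(t_next, X, f(t_next, X))

    meta = {
        "method": cfg.method,
        "dt": cfg.dt,
        "t_end": cfg.t_end,
        "epsilon": cfg.epsilon,
        "corrector_iterations_total": total_iters,
        "corrector_iterations_max": max_iters_seen,
        "max_simplex_drift": max_drift,
        "min_coordinate": min_coord,
    }
    return Trajectory(times=times, states=states, history=history, meta=meta)
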