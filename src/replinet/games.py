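"""Evolutionary games on the probability simplex.

A game is an ``n x n`` payoff (fitness) matrix ``A``: when the population is at
frequencies ``x`` on the simplex, species ``k`` has fitness ``(Ax)_k`` and the
population-average fitness is ``x^T A x``.  The single-node replicator equation

    dx_k/dt = x_k ((Ax)_k - x^T A x)

drives strategies that out-perform the average up and the rest down.  This
module provides the vector field, the interior-equilibrium solve, Nash and
evolutionarily-stable-state (ESS) classification, the column-shift reduction to
a diagonal game, and seeded random games / simplex points.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "PayoffMatrix",
    "InteriorEquilibrium",
    "EquilibriumReport",
    "DEFAULT_SIMPLEX_TOL",
    "rps",
    "hdg",
    "named_game",
    "on_simplex",
    "check_simplex",
    "fitness",
    "average_fitness",
    "replicator_rhs",
    "interior_equilibrium",
    "is_nash",
    "is_ess",
    "diagonal_reduction",
    "ess_gap",
    "random_payoff",
    "random_simplex_point",
    "classify_equilibrium",
]

#: Default tolerance for simplex-membership checks.  Fixed-step fourth-order
#: integration at dt <= 0.01 keeps row-sum drift many orders of magnitude
#: below this.
DEFAULT_SIMPLEX_TOL = 1e-9

ArrayLike = Union[np.ndarray, Sequence[float]]


@dataclass(frozen=True)
class PayoffMatrix:
    """Square real payoff matrix for one node's game.

    Parameters
    ----------
    entries
        ``n x n`` real matrix, ``n >= 2``; entry ``A[k, j]`` is the payoff to
        strategy ``k`` against strategy ``j``.
    label
        Free-text name, e.g. ``"RPS"`` or ``"HDG"``.
    """

    entries: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        e = np.array(self.entries, dtype=float)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError(f"payoff matrix must be square, got shape {e.shape}")
        if e.shape[0] < 2:
            raise ValueError("a game needs at least two species")
        if not np.all(np.isfinite(e)):
            raise ValueError("payoff entries must be finite")
        e.setflags(write=False)
        object.__setattr__(self, "entries", e)

    @property
    def n(self) -> int:
        """Number of species/strategies."""
        return self.entries.shape[0]

    def to_csv(self, path) -> None:
        """Write as bare CSV: n rows x n columns, no header."""
        np.savetxt(path, self.entries, delimiter=",")

    @classmethod
    def from_csv(cls, path, label: str = "") -> "PayoffMatrix":
        return cls(np.loadtxt(path, delimiter=",", ndmin=2), label=label)


def rps() -> PayoffMatrix:
    """Rock-paper-scissors: skew-symmetric cyclic dominance, mixed
    equilibrium at (1/3, 1/3, 1/3) surrounded by closed orbits."""
    return PayoffMatrix([[0, 1, -1], [-1, 0, 1], [1, -1, 0]], label="RPS")


def hdg() -> PayoffMatrix:
    """Hawk-dove variant with nonzero payoff to the dove in mixed encounters;
    unique Nash (and ESS) at the mixed point (1/2, 1/2)."""
    return PayoffMatrix([[2, 3], [4, 1]], label="HDG")


_NAMED = {"RPS": rps, "HDG": hdg}


def named_game(label: str) -> PayoffMatrix:
    """Retrieve a built-in game by label ("RPS" or "HDG")."""
    try:
        return _NAMED[label.upper()]()
    except KeyError:
        raise KeyError(
            f"unknown game {label!r}; available: {sorted(_NAMED)}"
        ) from None


def _as_matrix(A) -> np.ndarray:
    if isinstance(A, PayoffMatrix):
        return A.entries
    M = np.asarray(A, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"payoff matrix must be square, got shape {M.shape}")
    return M


def _check_dims(M: np.ndarray, x: np.ndarray) -> None:
    if M.shape[0] != x.shape[-1]:
        raise ValueError(
            f"payoff matrix is {M.shape[0]}x{M.shape[1]} but the state has "
            f"{x.shape[-1]} species"
        )


def on_simplex(x: ArrayLike, tol: float = DEFAULT_SIMPLEX_TOL) -> bool:
    """True iff every coordinate >= -tol and the coordinates sum to 1 within tol."""
    x = np.asarray(x, dtype=float)
    return bool(np.all(x >= -tol) and abs(float(x.sum()) - 1.0) <= tol)


def check_simplex(x: ArrayLike, tol: float = DEFAULT_SIMPLEX_TOL) -> np.ndarray:
    """Validate simplex membership, returning the state as an array."""
    x = np.asarray(x, dtype=float)
    if not on_simplex(x, tol):
        raise ValueError(
            f"state {x} is not on the simplex within tolerance {tol} "
            f"(sum={x.sum()!r}, min={x.min()!r})"
        )
    return x


def fitness(A, x: ArrayLike) -> np.ndarray:
    """Per-species fitness ``Ax`` at population state ``x``."""
    M = _as_matrix(A)
    x = np.asarray(x, dtype=float)
    _check_dims(M, x)
    return M @ x


def average_fitness(A, x: ArrayLike) -> float:
    """Population-average fitness, the quadratic form ``x^T A x``."""
    M = _as_matrix(A)
    x = np.asarray(x, dtype=float)
    _check_dims(M, x)
    return float(x @ M @ x)


def replicator_rhs(A, x: ArrayLike) -> np.ndarray:
    """Single-node replicator vector field ``x_k ((Ax)_k - x^T A x)``.

    Components sum to zero on the simplex; faces (``x_k = 0``) are invariant.
    """
    M = _as_matrix(A)
    x = np.asarray(x, dtype=float)
    _check_dims(M, x)
    f = M @ x
    return x * (f - x @ f)


@dataclass(frozen=True)
class InteriorEquilibrium:
    """Outcome of the interior-equilibrium linear solve.

    ``status`` is ``"unique"`` (point returned), ``"absent"`` (system
    inconsistent, or the solution leaves the open simplex), or ``"degenerate"``
    (singular but consistent: a manifold of equilibria exists).
    """

    point: Optional[np.ndarray]
    status: str


# Strict interiority margin for the solved equilibrium: coordinates at exact
# machine zero (boundary solutions) must not count as interior.
_INTERIOR_MARGIN = 1e-12


def interior_equilibrium(A, *, full: bool = False):
    """Interior fixed point of the replicator dynamics, if one exists.

    Solves the linear system ``(Ax)_k - (Ax)_n = 0`` for ``k = 1..n-1``
    together with ``sum_k x_k = 1`` and returns the solution iff all
    coordinates are strictly positive.  With ``full=True`` returns an
    :class:`InteriorEquilibrium` carrying the degenerate/absent distinction;
    otherwise returns the point or ``None``.
    """
    M = _as_matrix(A)
    n = M.shape[0]
    B = np.vstack([M[:-1] - M[-1], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    scale = max(1.0, float(np.abs(B).max()))
    rank = np.linalg.matrix_rank(B, tol=1e-12 * scale * n)
    if rank < n:
        aug = np.hstack([B, b[:, None]])
        rank_aug = np.linalg.matrix_rank(aug, tol=1e-12 * scale * n)
        status = "degenerate" if rank_aug == rank else "absent"
        result = InteriorEquilibrium(None, status)
    else:
        x = np.linalg.solve(B, b)
        if np.all(x > _INTERIOR_MARGIN):
            result = InteriorEquilibrium(x, "unique")
        else:
            result = InteriorEquilibrium(None, "absent")
    return result if full else result.point


def is_nash(A, xstar: ArrayLike, tol: float = 1e-9) -> bool:
    """Nash check ``(x*)^T A x* >= (A x*)_k - tol`` for every pure strategy k.

    Because ``x -> x^T A x*`` is linear over the simplex its maximum is
    attained at a vertex, so comparing against the pure strategies is exact.
    """
    M = _as_matrix(A)
    xs = np.asarray(xstar, dtype=float)
    _check_dims(M, xs)
    f = M @ xs
    return bool(np.max(f) <= float(xs @ f) + tol)


def _is_ess_exact_2x2(M: np.ndarray, xs: np.ndarray, tol: float) -> bool:
    # Column-shifted invariants: a' = a - c, b' = d - b fully classify 2x2
    # replicator dynamics.
    ap = M[0, 0] - M[1, 0]
    bp = M[1, 1] - M[0, 1]
    if xs[0] >= 1.0 - tol:  # vertex (1, 0)
        return ap > tol or (abs(ap) <= tol and bp < -tol)
    if xs[1] >= 1.0 - tol:  # vertex (0, 1)
        return bp > tol or (abs(bp) <= tol and ap < -tol)
    # Interior candidate: must be the mixed equilibrium (Nash already checked
    # by the caller), which is an ESS iff both shifted payoffs are negative.
    return ap < -tol and bp < -tol


def is_ess(
    A,
    xstar: ArrayLike,
    radius: float = 0.1,
    n_samples: int = 64,
    seed: int = 0,
    *,
    tol: float = 1e-12,
    method: str = "auto",
) -> bool:
    """Evolutionarily-stable-state check.

    A state ``x*`` is an ESS iff it is Nash and ``(x*)^T A x > x^T A x`` for
    all ``x != x*`` in a neighborhood of ``x*``.  For ``n = 2`` a closed-form
    sign analysis is exact.  For larger games the check samples ``n_samples``
    seeded random simplex directions ``d = x - x*`` (invading mixtures within
    ``radius``) and tests the small-deviation expansion

        psi(x* + eps d) = eps (-d^T A x*) + eps^2 (-d^T A d)

    whose sign for small ``eps > 0`` is decided exactly by the two
    coefficients; the first violated direction returns ``False``.
    """
    M = _as_matrix(A)
    xs = np.asarray(xstar, dtype=float)
    _check_dims(M, xs)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    if not is_nash(M, xs):
        return False
    n = M.shape[0]
    if method not in ("auto", "exact", "sampled"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" or (method == "auto" and n == 2):
        if n != 2:
            raise ValueError("exact ESS branch is only available for n = 2")
        return _is_ess_exact_2x2(M, xs, tol)
    rng = np.random.default_rng(seed)
    Axs = M @ xs
    for _ in range(n_samples):
        y = rng.dirichlet(np.ones(n))
        d = y - xs
        norm = float(np.linalg.norm(d))
        if norm < 1e-12:
            continue
        d = d * min(1.0, radius / norm)  # invading mixture x* + d stays in radius
        c1 = -float(d @ Axs)
        c2 = -float(d @ M @ d)
        if not (c1 > tol or (abs(c1) <= tol and c2 > tol)):
            return False
    return True


def diagonal_reduction(A) -> PayoffMatrix:
    """Column-shift the game without changing its replicator field.

    Adding a constant to a column of ``A`` leaves ``x_k((Ax)_k - x^T A x)``
    unchanged on the simplex.  For ``n = 2`` the off-diagonal entries are
    shifted away, returning ``diag(a - c, d - b)``; for ``n >= 3`` the last
    row is shifted to zero.
    """
    M = _as_matrix(A)
    label = A.label if isinstance(A, PayoffMatrix) else ""
    if M.shape[0] == 2:
        reduced = np.diag([M[0, 0] - M[1, 0], M[1, 1] - M[0, 1]])
    else:
        reduced = M - M[-1]
    return PayoffMatrix(reduced, label=(label + "-reduced") if label else "reduced")


def ess_gap(A, xstar: ArrayLike, x: ArrayLike) -> float:
    """Stability functional ``psi(x) = sum_k (x*_k - x_k) (Ax)_k``.

    Positive for all ``x`` near ``x*`` exactly when ``x*`` strictly
    out-scores nearby invading mixtures.
    """
    M = _as_matrix(A)
    xs = np.asarray(xstar, dtype=float)
    x = np.asarray(x, dtype=float)
    _check_dims(M, xs)
    _check_dims(M, x)
    return float((xs - x) @ (M @ x))


def random_payoff(n: int, scale: float = 1.0, seed: int = 0) -> PayoffMatrix:
    """Random game: i.i.d. normal entries with standard deviation ``scale``."""
    if n < 2:
        raise ValueError("a game needs at least two species")
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    rng = np.random.default_rng(seed)
    return PayoffMatrix(rng.normal(0.0, scale, size=(n, n)) if scale > 0 else np.zeros((n, n)),
                        label=f"random(n={n},seed={seed})")


def random_simplex_point(n: int, seed: int = 0) -> np.ndarray:
    """Uniform (flat Dirichlet) sample on the open simplex; seeded."""
    if n < 2:
        raise ValueError("need at least two species")
    return np.random.default_rng(seed).dirichlet(np.ones(n))


@dataclass(frozen=True)
class EquilibriumReport:
    """Classification of one candidate point: fixed / Nash / ESS flags."""

    point: Optional[np.ndarray]
    is_interior: bool
    is_fixed_point: bool
    is_nash: bool
    is_ess: bool
    diagnostics: dict


def classify_equilibrium(A, x: ArrayLike, tol: float = 1e-9, seed: int = 0) -> EquilibriumReport:
    """Classify a simplex point under the game ``A``.

    The implication chain ESS => Nash => fixed point holds by construction.
    """
    M = _as_matrix(A)
    xs = check_simplex(x, tol=max(tol, DEFAULT_SIMPLEX_TOL))
    rhs = replicator_rhs(M, xs)
    fixed = bool(np.max(np.abs(rhs)) <= tol)
    nash = fixed and is_nash(M, xs, tol=tol)
    ess = nash and is_ess(M, xs, seed=seed)
    return EquilibriumReport(
        point=xs,
        is_interior=bool(np.all(xs > tol)),
        is_fixed_point=fixed,
        is_nash=nash,
        is_ess=ess,
        diagnostics={"max_rhs": float(np.max(np.abs(rhs)))},
    )
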