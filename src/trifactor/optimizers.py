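"""Per-iteration update rules for the four NMTF solvers.

Each ``*_step`` function performs one full iteration: it updates ``U``,
then ``V``, then ``S`` (column/element sweeps for coordinate descent),
with every later sub-update seeing the already-updated earlier factors.
All steps accept dense or sparse data through the same code path — the
only products touching ``X`` are ``X V S^T``, ``X^T U S`` and ``U^T X V``,
which sparse matrix multiplication handles without densifying anything.

Denominators of Hadamard divisions are floored at ``DIV_FLOOR`` before
dividing, which keeps the multiplicative zero-lock of MUR intact (a zero
factor entry has a zero numerator, so flooring the denominator still
yields zero) while ruling out NaN/Inf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import DataMatrix, FactorTriple, project_nonnegative

__all__ = [
    "mur_step",
    "als_step",
    "als_step_detailed",
    "pg_step",
    "pg_step_detailed",
    "cod_step",
    "PGStep",
    "DIV_FLOOR",
]

logger = logging.getLogger(__name__)

# floor for Hadamard-division denominators in MUR/PG
DIV_FLOOR = 1e-12


def _xvst(X: DataMatrix, V: np.ndarray, S: np.ndarray) -> np.ndarray:
    """X V S^T, an n x k1 matrix."""
    return np.asarray(X.values @ (V @ S.T))


def _xtus(X: DataMatrix, U: np.ndarray, S: np.ndarray) -> np.ndarray:
    """X^T U S, an m x k2 matrix."""
    return np.asarray(X.transpose_values() @ (U @ S))


def _utxv(X: DataMatrix, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """U^T X V, a k1 x k2 matrix."""
    return np.asarray(U.T @ (X.values @ V))


def _floored(A: np.ndarray) -> np.ndarray:
    return np.maximum(A, DIV_FLOOR)


# ---------------------------------------------------------------------------
# multiplicative update rules
# ---------------------------------------------------------------------------

def mur_step(X: DataMatrix, F: FactorTriple) -> FactorTriple:
    """One iteration of multiplicative update rules.

    U <- U  * (X V S^T)   / (U S V^T V S^T)
    V <- V  * (X^T U S)   / (V S^T U^T U S)
    S <- S  * (U^T X V)   / (U^T U S V^T V)

    Products and quotients are elementwise (Hadamard).  Zero entries of a
    factor stay zero; outputs are non-negative by construction.
    """
    U, S, V = F.U, F.S, F.V

    num = _xvst(X, V, S)
    den = U @ (S @ (V.T @ V) @ S.T)
    U = U * (num / _floored(den))

    num = _xtus(X, U, S)
    den = V @ (S.T @ (U.T @ U) @ S)
    V = V * (num / _floored(den))

    num = _utxv(X, U, V)
    den = (U.T @ U) @ S @ (V.T @ V)
    S = S * (num / _floored(den))

    return FactorTriple(U, S, V)


# ---------------------------------------------------------------------------
# alternating least squares
# ---------------------------------------------------------------------------

def _solve_right(B: np.ndarray, M: np.ndarray, what: str) -> np.ndarray:
    """Solve A M = B for A, with pseudo-inverse fallback on singular M."""
    try:
        return np.linalg.solve(M.T, B.T).T
    except np.linalg.LinAlgError:
        logger.warning("singular normal matrix in ALS %s update; using pinv", what)
        return B @ np.linalg.pinv(M)


def _solve_left(M: np.ndarray, B: np.ndarray, what: str) -> np.ndarray:
    """Solve M A = B for A, with pseudo-inverse fallback on singular M."""
    try:
        return np.linalg.solve(M, B)
    except np.linalg.LinAlgError:
        logger.warning("singular normal matrix in ALS %s update; using pinv", what)
        return np.linalg.pinv(M) @ B


def als_step(X: DataMatrix, F: FactorTriple) -> FactorTriple:
    """One iteration of alternating least squares with [.]_+ projection.

    Each factor is set to the unconstrained least-squares minimizer of the
    objective with the other two fixed, then negative entries are zeroed.
    The projection heuristic means the objective is NOT guaranteed to
    decrease; on dense data the method is known to be unstable.
    """
    return als_step_detailed(X, F)[0]


def als_step_detailed(
    X: DataMatrix, F: FactorTriple
) -> tuple[FactorTriple, dict[str, np.ndarray]]:
    """ALS iteration returning also the pre-projection least-squares solves.

    The unprojected solves satisfy the normal equations of their
    subproblems (e.g. ``(X V S^T) = U_pre (S V^T V S^T)`` for ``U``),
    which is what makes them inspectable independently of the projection
    heuristic.
    """
    U, S, V = F.U, F.S, F.V
    pre: dict[str, np.ndarray] = {}

    B = _xvst(X, V, S)
    M = S @ (V.T @ V) @ S.T
    pre["U"] = _solve_right(B, M, "U")
    U = project_nonnegative(pre["U"])

    B = _xtus(X, U, S)
    M = S.T @ (U.T @ U) @ S
    pre["V"] = _solve_right(B, M, "V")
    V = project_nonnegative(pre["V"])

    B = _utxv(X, U, V)
    pre["S"] = _solve_right(_solve_left(U.T @ U, B, "S"), V.T @ V, "S")
    S = project_nonnegative(pre["S"])

    return FactorTriple(U, S, V), pre


# ---------------------------------------------------------------------------
# projected gradients
# ---------------------------------------------------------------------------

@dataclass
class PGStep:
    """Projection matrices and step sizes of one projected-gradient iteration."""

    P_u: np.ndarray
    P_v: np.ndarray
    P_s: np.ndarray
    eta_u: float
    eta_v: float
    eta_s: float


def _pg_factor_update(
    A: np.ndarray,
    num: np.ndarray,
    den: np.ndarray,
    trace_quad,
    fixed_eta: float | None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Shared scaffold of Eqs for U, V, S: build P, pick eta, project.

    ``trace_quad(P)`` evaluates the trace term in the step-size denominator,
    a positive quadratic form in P.  When it vanishes (P = 0 at a fixed
    point, or a degenerate instance) the factor update is skipped.
    """
    P = A - (A / _floored(den)) * num
    if fixed_eta is not None:
        eta = fixed_eta
    else:
        denom = trace_quad(P)
        if denom == 0.0:
            return A, P, 0.0
        eta = float(np.sum(P * (den - num))) / denom
    return project_nonnegative(A - eta * P), P, eta


def pg_step(
    X: DataMatrix, F: FactorTriple, fixed_eta: float | None = None
) -> FactorTriple:
    """One iteration of projected gradients with adaptive step size.

    For each factor a projection matrix ``P`` (the scaled gradient) and a
    step size ``eta`` are computed, then ``factor <- [factor - eta P]_+``.
    With ``fixed_eta=1`` the update reduces exactly to the multiplicative
    update rule.  Returns only the updated factors; use
    :func:`pg_step_detailed` to inspect ``P`` and ``eta``.
    """
    return pg_step_detailed(X, F, fixed_eta)[0]


def pg_step_detailed(
    X: DataMatrix, F: FactorTriple, fixed_eta: float | None = None
) -> tuple[FactorTriple, PGStep]:
    U, S, V = F.U, F.S, F.V

    N = V.T @ V
    B = S @ N @ S.T  # k1 x k1, symmetric
    num = _xvst(X, V, S)
    den = U @ B
    U, P_u, eta_u = _pg_factor_update(
        U, num, den, lambda P: float(np.sum((P @ B) * P)), fixed_eta
    )

    M = U.T @ U
    C = S.T @ M @ S  # k2 x k2, symmetric
    num = _xtus(X, U, S)
    den = V @ C
    V, P_v, eta_v = _pg_factor_update(
        V, num, den, lambda P: float(np.sum((P @ C) * P)), fixed_eta
    )

    M = U.T @ U
    N = V.T @ V
    num = _utxv(X, U, V)
    den = M @ S @ N
    S, P_s, eta_s = _pg_factor_update(
        S, num, den, lambda P: float(np.sum((M @ P @ N) * P)), fixed_eta
    )

    return FactorTriple(U, S, V), PGStep(P_u, P_v, P_s, eta_u, eta_v, eta_s)


# ---------------------------------------------------------------------------
# cyclic coordinate descent (HALS-style)
# ---------------------------------------------------------------------------

def cod_step(X: DataMatrix, F: FactorTriple) -> FactorTriple:
    """One iteration of cyclic coordinate descent.

    Sweeps columns of U in ascending order, then columns of V, then the
    entries of S row-major.  Each column update

        u_i <- [u_i + ((X V S^T)_i - (U S V^T V S^T)_i) / (s_i V^T V s_i^T)]_+

    is the exact minimizer of the objective restricted to that column
    under non-negativity (the restricted problem is separable per entry),
    evaluated with all previously updated coordinates already in place.
    Coordinates whose curvature denominator is zero are skipped.
    """
    U, S, V = F.U.copy(), F.S.copy(), F.V.copy()
    k1, k2 = S.shape

    # --- columns of U ---
    A = _xvst(X, V, S)            # n x k1
    B = S @ (V.T @ V) @ S.T       # k1 x k1; B[i, i] = s_i. V^T V s_i.^T
    for i in range(k1):
        denom = B[i, i]
        if denom <= 0.0:
            logger.debug("cod: skipping U column %d (zero curvature)", i)
            continue
        U[:, i] = np.maximum(0.0, U[:, i] + (A[:, i] - U @ B[:, i]) / denom)

    # --- columns of V ---
    C = _xtus(X, U, S)            # m x k2
    D = S.T @ (U.T @ U) @ S       # k2 x k2; D[j, j] = s_.j^T U^T U s_.j
    for j in range(k2):
        denom = D[j, j]
        if denom <= 0.0:
            logger.debug("cod: skipping V column %d (zero curvature)", j)
            continue
        V[:, j] = np.maximum(0.0, V[:, j] + (C[:, j] - V @ D[:, j]) / denom)

    # --- entries of S, row-major ---
    E = _utxv(X, U, V)            # k1 x k2
    G = U.T @ U
    H = V.T @ V
    for i in range(k1):
        T = G[i, :] @ S           # running G[i,:] @ S, refreshed per row
        for j in range(k2):
            denom = G[i, i] * H[j, j]
            if denom <= 0.0:
                logger.debug("cod: skipping S entry (%d, %d)", i, j)
                continue
            new = max(0.0, S[i, j] + (E[i, j] - T @ H[:, j]) / denom)
            T[j] += G[i, i] * (new - S[i, j])
            S[i, j] = new

    return FactorTriple(U, S, V)
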