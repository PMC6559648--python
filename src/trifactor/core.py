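"""Core types and shared numerics for non-negative matrix tri-factorization.

An NMTF model approximates a non-negative data matrix ``X`` (n x m) by the
trilinear product ``U @ S @ V.T`` with non-negative latent matrices
``U`` (n x k1), ``S`` (k1 x k2) and ``V`` (m x k2).  Everything the four
solvers share lives here: the wrapped data matrix with its dense/sparse
storage flag, the factor triple, solver configuration, per-iteration trace,
the relative Frobenius objective, the relative-change stopping rule and the
projection onto the non-negative orthant.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "DataMatrix",
    "FactorTriple",
    "Method",
    "SolverConfig",
    "OptimizationTrace",
    "TraceEntry",
    "FitStatus",
    "FitResult",
    "DegenerateInputError",
    "relative_objective",
    "check_stop",
    "project_nonnegative",
]


class DegenerateInputError(ValueError):
    """Raised for inputs on which the normalized objective is undefined."""


class Method(str, enum.Enum):
    """Optimization technique selector."""

    MUR = "mur"  # multiplicative update rules
    ALS = "als"  # alternating least squares with [.]+ projection
    PG = "pg"    # projected gradients with adaptive step size
    COD = "cod"  # cyclic coordinate descent (HALS-style)


class FitStatus(str, enum.Enum):
    CONVERGED = "converged"
    MAX_ITER_REACHED = "max_iter_reached"
    DIVERGED = "diverged"


@dataclass(frozen=True)
class DataMatrix:
    """A validated non-negative data matrix, dense or sparse.

    Parameters
    ----------
    values
        Either a dense :class:`numpy.ndarray` or a ``scipy.sparse`` matrix
        in CSR form.  All stored entries must be non-negative and at least
        one must be positive (the normalized objective divides by
        ``||X||_F^2``).

    Notes
    -----
    Sparse matrices are treated as matrices whose unstored cells are exact
    zeros contributing to the loss, not as matrices with missing data.
    The squared Frobenius norm is computed once at construction and cached.
    """

    values: np.ndarray | sp.csr_matrix
    storage: str = field(init=False)
    sq_norm: float = field(init=False)

    def __post_init__(self) -> None:
        vals = self.values
        if sp.issparse(vals):
            vals = sp.csr_matrix(vals)
            vals.sum_duplicates()
            object.__setattr__(self, "values", vals)
            object.__setattr__(self, "storage", "sparse")
            data = vals.data
        else:
            vals = np.asarray(vals, dtype=float)
            if vals.ndim != 2:
                raise ValueError(f"expected a 2-D matrix, got ndim={vals.ndim}")
            object.__setattr__(self, "values", vals)
            object.__setattr__(self, "storage", "dense")
            data = vals
        if data.size and np.min(data) < 0:
            raise ValueError("data matrix contains negative entries")
        sq = float(data.ravel() @ data.ravel()) if data.size else 0.0
        if sq == 0.0:
            raise DegenerateInputError(
                "degenerate input: all-zero data matrix (||X||_F = 0)"
            )
        object.__setattr__(self, "sq_norm", sq)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def is_sparse(self) -> bool:
        return self.storage == "sparse"

    @property
    def nnz(self) -> int:
        """Number of explicitly stored non-zeros (sparse) or cells (dense)."""
        if self.is_sparse:
            return int(self.values.nnz)
        return int(np.count_nonzero(self.values))

    @property
    def density(self) -> float:
        return self.nnz / (self.n * self.m)

    def toarray(self) -> np.ndarray:
        if self.is_sparse:
            return self.values.toarray()
        return self.values

    def transpose_values(self):
        """X^T in the matching storage, for right-side products."""
        if self.is_sparse:
            return self.values.T.tocsr()
        return self.values.T


@dataclass
class FactorTriple:
    """The three latent matrices ``U`` (n x k1), ``S`` (k1 x k2), ``V`` (m x k2)."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        for name, mat in (("U", self.U), ("S", self.S), ("V", self.V)):
            if mat.ndim != 2:
                raise ValueError(f"{name} must be 2-D, got ndim={mat.ndim}")
            if mat.size and np.min(mat) < 0:
                raise ValueError(f"factor {name} contains negative entries")
        if self.U.shape[1] != self.S.shape[0]:
            raise ValueError(
                f"U has {self.U.shape[1]} columns but S has {self.S.shape[0]} rows"
            )
        if self.V.shape[1] != self.S.shape[1]:
            raise ValueError(
                f"V has {self.V.shape[1]} columns but S has {self.S.shape[1]} columns"
            )
        if self.k1 > self.U.shape[0] or self.k2 > self.V.shape[0]:
            warnings.warn(
                "factorization rank exceeds a matrix dimension "
                f"(k1={self.k1}, n={self.U.shape[0]}, k2={self.k2}, m={self.V.shape[0]})",
                stacklevel=2,
            )

    @property
    def k1(self) -> int:
        return self.S.shape[0]

    @property
    def k2(self) -> int:
        return self.S.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Dense reconstruction ``U @ S @ V.T``; intended for small problems."""
        return self.U @ self.S @ self.V.T

    def copy(self) -> "FactorTriple":
        return FactorTriple(self.U.copy(), self.S.copy(), self.V.copy())


@dataclass(frozen=True)
class SolverConfig:
    """Solver settings shared by all optimization methods.

    ``epsilon`` is the relative-change convergence threshold, ``n_start``
    the minimum number of iterations before the stopping rule may fire
    (multiplicative updates can plateau early and trigger it spuriously),
    and ``n_stop`` the iteration cap after which a run is flagged
    non-converged.
    """

    method: Method = Method.MUR
    epsilon: float = 1e-6
    n_start: int = 100
    n_stop: int = 50_000
    seed: int = 0
    pg_fixed_step: float | None = None  # pin eta (PG only); None = adaptive

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", Method(self.method))
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0 <= self.n_start < self.n_stop:
            raise ValueError("need 0 <= n_start < n_stop")


@dataclass(frozen=True)
class TraceEntry:
    iteration: int
    objective: float
    elapsed_seconds: float


@dataclass
class OptimizationTrace:
    """Per-iteration record of the relative objective D_i and wall time."""

    entries: list[TraceEntry] = field(default_factory=list)

    def append(self, iteration: int, objective: float, elapsed: float) -> None:
        if self.entries and iteration <= self.entries[-1].iteration:
            raise ValueError("iteration indices must be strictly increasing")
        self.entries.append(TraceEntry(iteration, objective, elapsed))

    def objectives(self) -> np.ndarray:
        return np.array([e.objective for e in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TraceEntry]:
        return iter(self.entries)


@dataclass
class FitResult:
    """Outcome of one factorization run."""

    factors: FactorTriple
    status: FitStatus
    iterations: int
    final_objective: float
    trace: OptimizationTrace

    @property
    def converged(self) -> bool:
        return self.status is FitStatus.CONVERGED


def _as_triple(F: FactorTriple | Sequence[np.ndarray]) -> FactorTriple:
    if isinstance(F, FactorTriple):
        return F
    return FactorTriple(*F)


def relative_objective(X: DataMatrix, F: FactorTriple) -> float:
    """Relative squared Frobenius reconstruction error.

    Returns ``||X - U S V^T||_F^2 / ||X||_F^2``.  For sparse ``X`` the
    norm is expanded as

        ||X||^2 - 2 tr(S^T U^T X V) + tr((U^T U S)(V^T V S^T)^T)

    so only ``k``-sized intermediates are formed and the dense n x m
    reconstruction is never materialized.
    """
    F = _as_triple(F)
    U, S, V = F.U, F.S, F.V
    if X.n != U.shape[0] or X.m != V.shape[0]:
        raise ValueError(
            f"shape mismatch: X is {X.shape}, U S V^T is "
            f"({U.shape[0]}, {V.shape[0]})"
        )
    if X.is_sparse:
        UtXV = U.T @ (X.values @ V)            # k1 x k2
        cross = float(np.sum(UtXV * S))
        MS = (U.T @ U) @ S                      # k1 x k2
        SN = S @ (V.T @ V)                      # k1 x k2
        quad = float(np.sum(MS * SN))
        num = X.sq_norm - 2.0 * cross + quad
        # tiny negative residue from cancellation is numerically zero
        return max(num, 0.0) / X.sq_norm
    R = X.values - U @ S @ V.T
    return float(R.ravel() @ R.ravel()) / X.sq_norm


# a relative objective below this is an exact factorization at float precision
ZERO_OBJECTIVE = 1e-15


def check_stop(
    D_prev: float, D_curr: float, cfg: SolverConfig, iteration: int
) -> bool:
    """Relative-change stopping rule ``|D_i+1 - D_i| / D_i < epsilon``.

    Never fires before ``cfg.n_start`` iterations.  A previous objective at
    or below ``ZERO_OBJECTIVE`` means the factorization is already exact to
    machine precision, which counts as converged (subject to the same
    ``n_start`` guard) — relative changes between denormal-scale values
    are numerically meaningless and would otherwise keep the rule from
    ever firing on an exactly recovered instance.
    """
    if iteration < cfg.n_start:
        return False
    if D_prev <= ZERO_OBJECTIVE:
        return True
    return abs(D_curr - D_prev) / D_prev < cfg.epsilon


def project_nonnegative(A: np.ndarray) -> np.ndarray:
    """Projection ``[A]_+`` onto the non-negative orthant (negatives -> 0)."""
    return np.maximum(A, 0.0)
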