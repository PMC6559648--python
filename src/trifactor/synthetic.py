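"""Synthetic non-negative matrices with known tri-factor structure.

Generates desk-scale fixtures in the two regimes the benchmark targets:
fully dense matrices (image-collection-like) and highly sparse matrices
with densities between 0.1% and a few percent (ratings/document-term-like).
A matrix is built as a noisy trilinear product of known uniform(0, 1)
factors; sparsity is produced by masking — unretained cells are true
zeros in the objective, not missing data — so the ground-truth factors
remain a meaningful (if no longer exact) reference point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import DataMatrix, FactorTriple

__all__ = [
    "SyntheticSpec",
    "make_synthetic",
    "make_sparse_lowrank",
    "regime_presets",
    "preset_by_name",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic instance.

    ``noise_level`` scales additive uniform(0, 1) noise, which keeps the
    matrix non-negative without any clipping step.  ``density`` is the
    fraction of cells retained by the sparsity mask; 1.0 means dense
    storage.
    """

    n: int
    m: int
    k1: int
    k2: int
    noise_level: float = 0.0
    density: float = 1.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.k1 > self.n or self.k2 > self.m:
            raise ValueError("need k1 <= n and k2 <= m")


def make_synthetic(spec: SyntheticSpec) -> tuple[DataMatrix, FactorTriple]:
    """Generate ``(X, truth)`` for a spec, deterministically from its seed.

    ``X = U S V^T + noise_level * E`` with all of U, S, V, E uniform(0, 1);
    if ``density < 1`` a uniformly random mask keeps exactly
    ``ceil(density * n * m)`` cells and the matrix is returned in sparse
    storage.
    """
    rng = np.random.default_rng(spec.seed)
    U = rng.random((spec.n, spec.k1))
    V = rng.random((spec.m, spec.k2))
    S = rng.random((spec.k1, spec.k2))
    truth = FactorTriple(U, S, V)

    X_full = U @ S @ V.T
    if spec.noise_level > 0:
        X_full = X_full + spec.noise_level * rng.random((spec.n, spec.m))

    if spec.density >= 1.0:
        return DataMatrix(X_full), truth

    total = spec.n * spec.m
    keep = int(np.ceil(spec.density * total))
    flat = rng.choice(total, size=keep, replace=False)
    rows, cols = np.divmod(flat, spec.m)
    X_sp = sp.csr_matrix(
        (X_full[rows, cols], (rows, cols)), shape=(spec.n, spec.m)
    )
    return DataMatrix(X_sp), truth


def make_sparse_lowrank(
    n: int,
    m: int,
    k: int,
    factor_density: float,
    seed: int = 0,
    noise_level: float = 0.0,
) -> tuple[DataMatrix, FactorTriple]:
    """A tri-factorizable sparse matrix built from sparse factors.

    Masking a dense product (see :func:`make_synthetic`) destroys its
    low-rank structure, so masked instances have no low-error fit at the
    true ranks.  This construction instead draws sparse non-negative
    ``U`` and ``V`` (each entry non-zero with probability
    ``factor_density``) and a positive diagonal ``S`` (k x k), so
    ``X = U S V^T`` holds exactly, is itself sparse (expected density is
    about ``k * factor_density**2``), and a zero-error factorization at
    rank ``k`` exists.  Used for parameter-recovery experiments on the
    sparse regime.

    ``noise_level`` adds uniform(0, 1)-scaled noise to the *stored*
    entries only, preserving the sparsity pattern.  A small positive
    value gives the objective a positive floor at which the
    relative-change stopping rule fires the way it does on real data;
    with an exactly zero floor, monotone solvers decay geometrically
    forever and only stop at the iteration cap.
    """
    if not 0 < factor_density <= 1:
        raise ValueError("factor_density must be in (0, 1]")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    U = rng.random((n, k)) * (rng.random((n, k)) < factor_density)
    V = rng.random((m, k)) * (rng.random((m, k)) < factor_density)
    S = np.diag(0.5 + rng.random(k))
    truth = FactorTriple(U, S, V)
    X = (sp.csr_matrix(U) @ sp.csr_matrix(S) @ sp.csr_matrix(V).T).tocsr()
    X.eliminate_zeros()
    if noise_level > 0:
        X.data = X.data + noise_level * rng.random(X.data.shape)
    return DataMatrix(X), truth


def regime_presets() -> list[SyntheticSpec]:
    """Named desk-scale presets mirroring the benchmark's data regimes.

    ``dense-small`` stands in for fully dense image collections;
    ``sparse-1pct`` for ratings matrices around 1.3% density;
    ``sparse-sub1pct`` for document-term matrices around 0.1% density.
    All presets keep ``n * m <= 250,000`` so every solver runs in seconds.
    """
    return [
        SyntheticSpec(
            n=150, m=100, k1=4, k2=4, noise_level=0.01, density=1.0,
            seed=0, name="dense-small",
        ),
        SyntheticSpec(
            n=400, m=300, k1=4, k2=4, noise_level=0.01, density=0.013,
            seed=0, name="sparse-1pct",
        ),
        SyntheticSpec(
            n=500, m=500, k1=4, k2=4, noise_level=0.0, density=0.001,
            seed=0, name="sparse-sub1pct",
        ),
    ]


def preset_by_name(name: str) -> SyntheticSpec:
    for spec in regime_presets():
        if spec.name == name:
            return spec
    known = ", ".join(s.name for s in regime_presets())
    raise KeyError(f"unknown preset {name!r}; known presets: {known}")
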