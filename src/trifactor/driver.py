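"""Factorization driver: initialization, iteration loop, restarts.

The loop mirrors the shared algorithmic skeleton of all four solvers:
initialize ``U``, ``V``, ``S`` with uniform(0, 1) draws, repeat the chosen
update rule, record the relative objective ``D_i`` after each full
iteration, and terminate on convergence (relative change below epsilon
after at least ``n_start`` iterations), on the ``n_stop`` iteration cap,
or on detected divergence.

Divergence is called operationally from a single trace: a non-finite
objective, a mostly-rising trailing window, or a blow-up of the latest
objective relative to the window's minimum.
"""

from __future__ import annotations

import time
from typing import Callable, Sequence

import numpy as np

from .core import (
    DataMatrix,
    FactorTriple,
    FitResult,
    FitStatus,
    Method,
    OptimizationTrace,
    SolverConfig,
    check_stop,
    relative_objective,
)
from .optimizers import als_step, cod_step, mur_step, pg_step

__all__ = [
    "init_factors",
    "factorize",
    "detect_divergence",
    "run_restarts",
    "best_run",
    "objective_span",
    "mean_converged_iterations",
    "export_trace",
    "DIVERGENCE_WINDOW",
    "DIVERGENCE_LEVEL_FACTOR",
]

DIVERGENCE_WINDOW = 20
DIVERGENCE_LEVEL_FACTOR = 10.0
# objective changes below this absolute level are treated as exact-zero noise
DIVERGENCE_ABS_FLOOR = 1e-12


def init_factors(n: int, m: int, k1: int, k2: int, seed: int) -> FactorTriple:
    """Uniform(0, 1) random initialization of U (n x k1), V (m x k2), S (k1 x k2).

    The same seed always yields bitwise-identical factors.
    """
    if min(n, m, k1, k2) < 1:
        raise ValueError("n, m, k1, k2 must all be >= 1")
    rng = np.random.default_rng(seed)
    U = rng.random((n, k1))
    V = rng.random((m, k2))
    S = rng.random((k1, k2))
    return FactorTriple(U, S, V)


def _step_function(cfg: SolverConfig) -> Callable[[DataMatrix, FactorTriple], FactorTriple]:
    if cfg.method is Method.MUR:
        return mur_step
    if cfg.method is Method.ALS:
        return als_step
    if cfg.method is Method.PG:
        return lambda X, F: pg_step(X, F, fixed_eta=cfg.pg_fixed_step)
    if cfg.method is Method.COD:
        return cod_step
    raise ValueError(f"unknown method: {cfg.method}")


def detect_divergence(
    trace: OptimizationTrace,
    window: int = DIVERGENCE_WINDOW,
    rise_tol: float = 1e-6,
) -> bool:
    """Flag oscillating, exploding or non-finite optimization traces.

    True iff, within the trailing ``window`` iterations, the objective is
    non-finite anywhere, or it rose relative to the previous iteration in
    more than half of the window's steps, or the latest value exceeds the
    window's minimum by more than a factor of ``DIVERGENCE_LEVEL_FACTOR``.
    The oscillation and level rules wait for a full window so early
    transients are not misread, and a step counts as a rise only when the
    relative increase exceeds ``rise_tol`` — fluctuations below the
    convergence tolerance, or below ``DIVERGENCE_ABS_FLOOR`` absolutely
    (an exactly recovered factorization jitters at machine precision),
    are numerical noise on a plateau, not oscillation.
    """
    if len(trace) == 0:
        raise ValueError("trace is empty")
    obj = trace.objectives()
    tail = obj[-window:]
    if not np.all(np.isfinite(tail)):
        return True
    if len(obj) < window:
        return False
    deltas = np.diff(tail)
    rises = deltas > np.maximum(rise_tol * np.abs(tail[:-1]), DIVERGENCE_ABS_FLOOR)
    if np.sum(rises) > len(deltas) / 2:
        return True
    lo = np.min(tail)
    return bool(tail[-1] > DIVERGENCE_LEVEL_FACTOR * lo + DIVERGENCE_ABS_FLOOR)


def factorize(
    X: DataMatrix,
    cfg: SolverConfig,
    k1: int,
    k2: int,
    init: FactorTriple | None = None,
) -> FitResult:
    """Run one factorization to convergence, the iteration cap, or divergence.

    Parameters
    ----------
    X
        Non-negative data matrix (dense or sparse).
    cfg
        Solver settings; ``cfg.seed`` drives the random initialization.
    k1, k2
        Factorization ranks.
    init
        Optional explicit starting factors (overrides seeded init), e.g.
        for warm starts near a known solution.
    """
    step = _step_function(cfg)
    F = init.copy() if init is not None else init_factors(X.n, X.m, k1, k2, cfg.seed)

    trace = OptimizationTrace()
    D_prev = relative_objective(X, F)
    status = FitStatus.MAX_ITER_REACHED
    iteration = 0
    t0 = time.perf_counter()
    for iteration in range(1, cfg.n_stop + 1):
        F = step(X, F)
        D = relative_objective(X, F)
        trace.append(iteration, D, time.perf_counter() - t0)
        if not np.isfinite(D):
            status = FitStatus.DIVERGED
            break
        if check_stop(D_prev, D, cfg, iteration):
            status = FitStatus.CONVERGED
            break
        if detect_divergence(trace, rise_tol=cfg.epsilon):
            status = FitStatus.DIVERGED
            break
        D_prev = D

    final = trace.entries[-1].objective if len(trace) else D_prev
    return FitResult(
        factors=F,
        status=status,
        iterations=iteration,
        final_objective=final,
        trace=trace,
    )


def run_restarts(
    X: DataMatrix,
    cfg: SolverConfig,
    k1: int,
    k2: int,
    n_restarts: int = 10,
) -> list[FitResult]:
    """Independent restarts seeded ``cfg.seed, cfg.seed + 1, ...``."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    results = []
    for r in range(n_restarts):
        cfg_r = SolverConfig(
            method=cfg.method,
            epsilon=cfg.epsilon,
            n_start=cfg.n_start,
            n_stop=cfg.n_stop,
            seed=cfg.seed + r,
            pg_fixed_step=cfg.pg_fixed_step,
        )
        results.append(factorize(X, cfg_r, k1, k2))
    return results


def best_run(results: Sequence[FitResult]) -> FitResult:
    """The run with the lowest final objective."""
    return min(results, key=lambda r: r.final_objective)


def objective_span(results: Sequence[FitResult]) -> tuple[float, float]:
    """(min, max) of final objectives across runs — the spread a trace plot shades."""
    finals = [r.final_objective for r in results]
    return (min(finals), max(finals))


def mean_converged_iterations(results: Sequence[FitResult]) -> float:
    """Mean iteration count over converged runs only; NaN if none converged."""
    its = [r.iterations for r in results if r.converged]
    return float(np.mean(its)) if its else float("nan")


def export_trace(trace: OptimizationTrace, path) -> None:
    """Write a trace as delimited text: ``iteration,objective,elapsed_seconds``."""
    with open(path, "w") as fh:
        fh.write("iteration,objective,elapsed_seconds\n")
        for e in trace:
            fh.write(f"{e.iteration},{e.objective!r},{e.elapsed_seconds!r}\n")
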