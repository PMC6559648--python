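"""Desk-scale benchmarking harness comparing the four solvers.

Reproduces the structure of the standard convergence study for NMTF
optimizers on synthetic presets: per (preset, method) cells with mean
iterations and runtime over converged restarts, non-convergence flags,
per-run final objectives, and iteration speed-up ratios relative to
multiplicative updates.  Non-converged runs are excluded from iteration
and runtime means and flagged instead, so a cell is either a mean over
converged runs or an explicit "no convergence" marker.

Plotting hooks emit trace data as tidy frames rather than figures, so any
plotting backend can be layered on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DataMatrix, FitResult, Method, SolverConfig
from .driver import factorize, mean_converged_iterations, run_restarts
from .synthetic import SyntheticSpec, make_synthetic

__all__ = ["BenchReport", "compare_methods", "rank_sweep", "trace_frame"]

_DEFAULT_METHODS = (Method.MUR, Method.ALS, Method.PG, Method.COD)


@dataclass
class BenchReport:
    """Aggregated comparison of solvers across synthetic presets."""

    rows: list[dict] = field(default_factory=list)
    runs: dict = field(default_factory=dict)  # (preset, method) -> list[FitResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def cell(self, preset: str, method: Method | str) -> dict:
        method = Method(method)
        for row in self.rows:
            if row["preset"] == preset and row["method"] == method.value:
                return row
        raise KeyError((preset, method))


def _aggregate(preset: str, method: Method, results: Sequence[FitResult]) -> dict:
    conv = [r for r in results if r.converged]
    mean_iter = mean_converged_iterations(results)
    mean_rt = (
        float(np.mean([r.trace.entries[-1].elapsed_seconds for r in conv]))
        if conv
        else float("nan")
    )
    return {
        "preset": preset,
        "method": method.value,
        "n_runs": len(results),
        "n_converged": len(conv),
        "non_converged": len(conv) == 0,
        "mean_iterations": mean_iter,
        "mean_runtime_seconds": mean_rt,
        "final_objectives": [r.final_objective for r in results],
        "best_final_objective": min(r.final_objective for r in results),
    }


def compare_methods(
    presets: Sequence[SyntheticSpec],
    cfg: SolverConfig,
    n_restarts: int = 10,
    methods: Sequence[Method | str] = _DEFAULT_METHODS,
) -> BenchReport:
    """Run every method on every preset with shared restart seeds.

    All methods on a given preset start from identical initializations
    (same seed sequence), so iteration counts are directly comparable.
    Speed-up ratios ``MUR iterations / method iterations`` are attached
    where both methods converged.
    """
    report = BenchReport()
    for spec in presets:
        X, _truth = make_synthetic(spec)
        name = spec.name or f"{spec.n}x{spec.m}"
        cells = {}
        for method in methods:
            method = Method(method)
            cfg_m = SolverConfig(
                method=method,
                epsilon=cfg.epsilon,
                n_start=cfg.n_start,
                n_stop=cfg.n_stop,
                seed=cfg.seed,
                pg_fixed_step=cfg.pg_fixed_step if method is Method.PG else None,
            )
            results = run_restarts(X, cfg_m, spec.k1, spec.k2, n_restarts)
            report.runs[(name, method.value)] = results
            cells[method.value] = _aggregate(name, method, results)
        mur_iter = cells.get(Method.MUR.value, {}).get("mean_iterations", float("nan"))
        for cell in cells.values():
            ok = (
                np.isfinite(mur_iter)
                and np.isfinite(cell["mean_iterations"])
                and cell["mean_iterations"] > 0
            )
            cell["speedup_vs_mur"] = (
                mur_iter / cell["mean_iterations"] if ok else float("nan")
            )
            report.rows.append(cell)
    return report


def rank_sweep(
    X: DataMatrix,
    ranks: Sequence[int],
    cfg: SolverConfig,
    n_restarts: int = 1,
    methods: Sequence[Method | str] = _DEFAULT_METHODS,
) -> pd.DataFrame:
    """Runtime and iterations as a function of factorization rank k1 = k2 = k.

    Means exclude non-converged runs; the best (lowest) final objective
    across restarts is reported per cell.
    """
    max_rank = max(ranks)
    if max_rank > min(X.n, X.m):
        raise ValueError(
            f"rank {max_rank} exceeds min(n, m) = {min(X.n, X.m)}"
        )
    rows = []
    for k in ranks:
        for method in methods:
            method = Method(method)
            cfg_m = SolverConfig(
                method=method,
                epsilon=cfg.epsilon,
                n_start=cfg.n_start,
                n_stop=cfg.n_stop,
                seed=cfg.seed,
                pg_fixed_step=cfg.pg_fixed_step if method is Method.PG else None,
            )
            results = run_restarts(X, cfg_m, k, k, n_restarts)
            agg = _aggregate(f"k={k}", method, results)
            agg["rank"] = k
            rows.append(agg)
    return pd.DataFrame(rows)


def trace_frame(results: Sequence[FitResult], labels: Sequence[str] | None = None) -> pd.DataFrame:
    """Tidy per-iteration trace data for plotting: run, iteration, objective, elapsed."""
    if labels is None:
        labels = [f"run{i}" for i in range(len(results))]
    rows = []
    for label, res in zip(labels, results):
        for e in res.trace:
            rows.append(
                {
                    "run": label,
                    "iteration": e.iteration,
                    "objective": e.objective,
                    "elapsed_seconds": e.elapsed_seconds,
                }
            )
    return pd.DataFrame(rows)
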