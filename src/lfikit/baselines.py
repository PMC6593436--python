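"""Grid-search and Nelder–Mead baselines with the same contract as run_bo.

Grid search evaluates the simulator once at the centre of each cell of an
even partition of the space (n_per_dim^d evaluations) and returns the
argmin cell centre plus the full table for visualization.  Nelder–Mead runs
the classic downhill simplex on the noisy objective from a prior-drawn
start; independent restarts emulate a parallelized variant by picking the
run with the smallest training error.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DiscrepancyFunction,
    EvaluationRecord,
    ParameterSpace,
    SimulatorContract,
    derive_seed,
)

__all__ = [
    "GridConfig",
    "SimplexConfig",
    "run_grid",
    "run_nelder_mead",
]

logger = logging.getLogger("lfikit")


@dataclass(frozen=True)
class GridConfig:
    """Even-partition grid; cells are evaluated at their centres."""

    n_per_dim: int = 5

    def __post_init__(self):
        if self.n_per_dim < 2:
            raise ValueError("n_per_dim must be at least 2")

    def total_evaluations(self, d: int) -> int:
        return self.n_per_dim**d


@dataclass(frozen=True)
class SimplexConfig:
    """Standard downhill-simplex coefficients plus stopping and restart settings."""

    reflection: float = 1.0
    expansion: float = 2.0
    contraction: float = 0.5
    shrink: float = 0.5
    max_iterations: int = 100
    x_tol: float = 1e-6
    f_tol: float = 1e-8
    restarts: int = 1
    initial_step: float = 0.25  # unit-cube edge of the initial simplex

    def __post_init__(self):
        if min(self.reflection, self.expansion, self.contraction, self.shrink) <= 0:
            raise ValueError("simplex coefficients must be positive")
        if self.expansion <= 1:
            raise ValueError("expansion coefficient must exceed 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def run_grid(
    simulator: SimulatorContract,
    discrepancy: DiscrepancyFunction,
    observed,
    space: ParameterSpace,
    config: GridConfig = GridConfig(),
    seed: int = 0,
    n_jobs: int = 1,
):
    """Evaluate the simulator at every grid cell centre.

    Returns ``(records, best_theta, table)`` where ``table`` is a DataFrame
    with one row per cell (cell indices, natural-unit coordinates and the
    discrepancy; NaN marks a failed simulator run, excluded from the
    argmin).  Per-cell seeds are derived from the master seed so concurrent
    execution gives results identical to sequential.
    """
    d = space.dimension
    n = config.n_per_dim
    centers_1d = (np.arange(n) + 0.5) / n
    cells = list(itertools.product(range(n), repeat=d))
    thetas = [space.from_unit_cube(np.array([centers_1d[i] for i in cell])) for cell in cells]
    seeds = [derive_seed(seed, "grid", k) for k in range(len(cells))]

    def _one(theta, s):
        try:
            return float(discrepancy(observed, simulator.run(theta, s)))
        except Exception:
            logger.warning("simulator failed at grid cell theta=%s; recorded missing", theta)
            return np.nan

    if n_jobs > 1:
        from joblib import Parallel, delayed

        values = Parallel(n_jobs=n_jobs)(
            delayed(_one)(thetas[k], seeds[k]) for k in range(len(cells))
        )
    else:
        values = [_one(thetas[k], seeds[k]) for k in range(len(cells))]

    records = [
        EvaluationRecord(thetas[k], seeds[k], values[k], round_index=0)
        for k in range(len(cells))
        if np.isfinite(values[k])
    ]
    if not records:
        raise RuntimeError("all grid evaluations failed")

    rows = []
    for k, cell in enumerate(cells):
        row = {f"cell_{name}": idx for name, idx in zip(space.names, cell)}
        row.update({name: thetas[k][i] for i, name in enumerate(space.names)})
        row["discrepancy"] = values[k]
        rows.append(row)
    table = pd.DataFrame(rows)

    vals = np.array(values)
    best_k = int(np.nanargmin(vals))
    return records, thetas[best_k], table


# ---------------------------------------------------------------------------
# Nelder–Mead downhill simplex
# ---------------------------------------------------------------------------


def _nm_single(f, u0: np.ndarray, cfg: SimplexConfig):
    """One downhill-simplex run in unit-cube coordinates with bound clipping.

    ``f(u)`` is the (noisy) objective; each call is a fresh simulator run.
    Returns (best_u, best_f, n_evals_used is implicit in f's counter).
    """
    d = u0.size
    simplex = [np.clip(u0, 0, 1)]
    for i in range(d):
        v = u0.copy()
        v[i] = v[i] + cfg.initial_step if v[i] + cfg.initial_step <= 1 else v[i] - cfg.initial_step
        simplex.append(np.clip(v, 0, 1))
    simplex = np.array(simplex)
    fvals = np.array([f(v) for v in simplex])

    for _ in range(cfg.max_iterations):
        order = np.argsort(fvals)
        simplex, fvals = simplex[order], fvals[order]
        if (np.max(np.abs(simplex[1:] - simplex[0])) < cfg.x_tol
                and np.max(np.abs(fvals[1:] - fvals[0])) < cfg.f_tol):
            break
        centroid = simplex[:-1].mean(axis=0)
        worst = simplex[-1]
        xr = np.clip(centroid + cfg.reflection * (centroid - worst), 0, 1)
        fr = f(xr)
        if fr < fvals[0]:
            xe = np.clip(centroid + cfg.expansion * (xr - centroid), 0, 1)
            fe = f(xe)
            if fe < fr:
                simplex[-1], fvals[-1] = xe, fe
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            xc = np.clip(centroid + cfg.contraction * (worst - centroid), 0, 1)
            fc = f(xc)
            if fc < fvals[-1]:
                simplex[-1], fvals[-1] = xc, fc
            else:  # shrink toward the best vertex
                for i in range(1, d + 1):
                    simplex[i] = np.clip(
                        simplex[0] + cfg.shrink * (simplex[i] - simplex[0]), 0, 1
                    )
                    fvals[i] = f(simplex[i])
    order = np.argsort(fvals)
    return simplex[order[0]], float(fvals[order[0]])


def run_nelder_mead(
    simulator: SimulatorContract,
    discrepancy: DiscrepancyFunction,
    observed,
    space: ParameterSpace,
    config: SimplexConfig = SimplexConfig(),
    seed: int = 0,
    max_evaluations: int | None = None,
):
    """Downhill simplex on the noisy discrepancy from a prior-drawn start.

    With ``restarts > 1``, runs that many independent optimizations (fresh
    starts and seeds) and returns the vertex with the smallest *training*
    discrepancy across runs — the "parallel Nelder–Mead" simulation.
    Out-of-bounds vertices are clipped to the bounds.  Returns
    ``(records, best_theta)``.
    """
    records: list[EvaluationRecord] = []
    best_u, best_f = None, np.inf
    eval_budget = max_evaluations if max_evaluations is not None else np.inf

    for rs in range(config.restarts):
        counter = {"k": 0}

        def f(u, _rs=rs):
            if len(records) >= eval_budget:
                raise _BudgetExhausted
            theta = space.from_unit_cube(np.clip(u, 0, 1))
            s = derive_seed(seed, "nm", _rs, counter["k"])
            counter["k"] += 1
            val = float(discrepancy(observed, simulator.run(theta, s)))
            records.append(EvaluationRecord(theta, s, val, round_index=_rs))
            return val

        u0 = space.to_unit_cube(space.sample_prior(1, derive_seed(seed, "nmstart", rs))[0])
        try:
            u_star, f_star = _nm_single(f, u0, config)
        except _BudgetExhausted:
            break
        if f_star < best_f:
            best_u, best_f = u_star, f_star

    if best_u is None:
        if not records:
            raise RuntimeError("Nelder-Mead made no evaluations within the budget")
        best_rec = min(records, key=lambda r: r.discrepancy)
        return records, best_rec.theta
    return records, space.from_unit_cube(best_u)


class _BudgetExhausted(Exception):
    pass
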