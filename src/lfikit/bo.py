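"""Batch Bayesian optimization of the discrepancy surface.

Inference proceeds in rounds: propose a batch of parameter vectors, run the
simulator at each (with independent derived seeds), compute discrepancies
against the observed summaries, refit the GP surrogate, repeat until the
evaluation budget is spent.  The point estimate is the minimizer of the
surrogate's predicted mean.

Acquisition: the GP-UCB rule of Srinivas et al., written as a *lower*
confidence bound μ(θ) − sqrt(β_t)·σ(θ) because discrepancy is minimized
(lower acquisition = more desirable).  Batches are spread out with a local
penalization rule (González et al.): after each within-batch selection the
acquisition's improvement is multiplied by a distance-based penalizer around
the selected point, using a Lipschitz constant estimated as the maximum
gradient magnitude of μ over the candidate set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.stats import norm, qmc

from .core import (
    Budget,
    DiscrepancyFunction,
    EvaluationRecord,
    ParameterSpace,
    SimulatorContract,
    derive_seed,
)
from .gp import SurrogateModel, fit_surrogate, surrogate_minimum

__all__ = [
    "AcquisitionConfig",
    "BatchProposal",
    "beta_schedule",
    "acquisition_value",
    "propose_batch",
    "run_bo",
    "BOResult",
]

logger = logging.getLogger("lfikit")

_MIN_PAIR_DIST = 1e-6


@dataclass
class AcquisitionConfig:
    """Exploration schedule and acquisition-optimizer settings.

    ``delta`` is the confidence parameter of the β_t schedule
    β_t = 2·log(t^(d/2+2)·π²/(3δ)); ``n_candidates`` quasi-random candidate
    points are scored and the best ``n_refine`` are polished locally.
    """

    delta: float = 0.1
    n_candidates: int = 512
    n_refine: int = 5

    def beta(self, t: int, d: int) -> float:
        return beta_schedule(t, d, self.delta)


def beta_schedule(t: int, d: int, delta: float = 0.1) -> float:
    """GP-UCB exploration coefficient β_t (Srinivas-style schedule)."""
    t = max(int(t), 1)
    return 2.0 * np.log(t ** (d / 2.0 + 2.0) * np.pi**2 / (3.0 * delta))


@dataclass
class BatchProposal:
    """One round's proposed parameter vectors (natural units)."""

    theta: np.ndarray  # (batch_size, d)

    def __post_init__(self):
        self.theta = np.atleast_2d(np.asarray(self.theta, dtype=float))

    def __len__(self) -> int:
        return self.theta.shape[0]


def acquisition_value(model: SurrogateModel, theta, t: int,
                      config: AcquisitionConfig | None = None) -> float:
    """Lower confidence bound μ(θ) − sqrt(β_t)·σ(θ); lower = better."""
    config = config or AcquisitionConfig()
    pred = model.predict(theta)
    beta = config.beta(t, model.space.dimension)
    return pred.mean - np.sqrt(beta) * pred.sd


def _acquisition_batch(model: SurrogateModel, U: np.ndarray, beta: float) -> np.ndarray:
    mean, sd = model.predict_batch(U, unit=True)
    return mean - np.sqrt(beta) * sd


def _estimate_lipschitz(model: SurrogateModel, U: np.ndarray) -> float:
    grads = model.predict_mean_gradient(U)
    L = float(np.max(np.linalg.norm(grads, axis=1)))
    return max(L, 1e-6)


def _penalizers(U: np.ndarray, chosen: list[np.ndarray], model: SurrogateModel,
                L: float, M: float) -> np.ndarray:
    """Π_j φ_j(u): soft exclusion balls around already-chosen batch points."""
    if not chosen:
        return np.ones(U.shape[0])
    pen = np.ones(U.shape[0])
    C = np.array(chosen)
    mu_c, sd_c = model.predict_batch(C, unit=True)
    for j in range(C.shape[0]):
        r = np.linalg.norm(U - C[j], axis=1)
        z = (L * r - M + mu_c[j]) / (np.sqrt(2.0) * max(sd_c[j], 1e-12))
        pen *= norm.cdf(z)
    return pen


def propose_batch(
    model: SurrogateModel | None,
    space: ParameterSpace,
    batch_size: int,
    t: int,
    config: AcquisitionConfig | None = None,
    seed: int = 0,
) -> BatchProposal:
    """Select a batch of evaluation points for round ``t``.

    With no model (first round) returns i.i.d. prior draws.  Otherwise
    sequentially picks ``batch_size`` minimizers of the locally penalized
    acquisition over a Sobol candidate set with local refinement.
    """
    config = config or AcquisitionConfig()
    d = space.dimension
    if model is None:
        theta = space.sample_prior(batch_size, seed)
        return BatchProposal(theta)

    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Sobol power-of-two balance warning
        sob = qmc.Sobol(d, scramble=True, seed=rng)
        cand = sob.random(config.n_candidates)
    cand = np.vstack([cand, model.U])  # include training locations as anchors
    beta = config.beta(t, d)

    # local refinement of the plain acquisition from the best few candidates
    acq = _acquisition_batch(model, cand, beta)

    def acq_fn(u):
        mean, sd = model.predict_batch(u[None, :], unit=True)
        return float(mean[0] - np.sqrt(beta) * sd[0])

    refined = []
    for idx in np.argsort(acq)[: config.n_refine]:
        res = optimize.minimize(
            acq_fn, cand[idx], method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * d, options={"maxiter": 50},
        )
        refined.append(np.clip(res.x, 0, 1))
    if refined:
        cand = np.vstack([cand, refined])
        acq = np.concatenate([acq, _acquisition_batch(model, np.array(refined), beta)])

    L = _estimate_lipschitz(model, cand)
    M = float(np.min(model.y))
    acq_max = float(np.max(acq))
    improvement = acq_max - acq  # >= 0, larger = more desirable

    chosen: list[np.ndarray] = []
    for _ in range(batch_size):
        pen = _penalizers(cand, chosen, model, L, M)
        score = improvement * pen
        order = np.argsort(-score)
        pick = None
        for idx in order:
            u = cand[idx]
            if all(np.linalg.norm(u - c) > _MIN_PAIR_DIST for c in chosen):
                pick = u
                break
        if pick is None:  # all candidates collide: jitter a uniform draw
            pick = np.clip(rng.uniform(0, 1, size=d), 0, 1)
        chosen.append(pick)

    return BatchProposal(space.from_unit_cube(np.array(chosen)))


# ---------------------------------------------------------------------------
# The round loop
# ---------------------------------------------------------------------------


@dataclass
class BOResult:
    records: list[EvaluationRecord]
    model: SurrogateModel
    theta_point: np.ndarray
    predicted_min: float
    hyper_trace: list[dict] = field(default_factory=list)


def run_bo(
    simulator: SimulatorContract,
    discrepancy: DiscrepancyFunction,
    observed,
    space: ParameterSpace,
    prior=None,
    budget: Budget = Budget(60, 10),
    config: AcquisitionConfig | None = None,
    seed: int = 0,
    hyper_config: dict | None = None,
    n_jobs: int = 1,
    round_callback=None,
) -> BOResult:
    """Run batch Bayesian optimization of the discrepancy.

    Per round: propose a batch, run the simulator at each proposal with a
    derived seed hash(master, round, slot), compute discrepancies against
    ``observed``, append records, refit the surrogate (warm-started).  A
    simulator failure at a θ excludes that record with a warning but still
    counts against the budget.  Batch runs may execute concurrently
    (``n_jobs > 1``) with results identical to sequential execution because
    seeds are derived up front.

    ``round_callback(round_index, records, model)`` is invoked after each
    refit (used by the comparison harness for checkpointing).
    """
    config = config or AcquisitionConfig()
    if budget.max_evaluations < 2 * space.dimension:
        raise ValueError("budget.max_evaluations must be at least 2*d")
    records: list[EvaluationRecord] = []
    model: SurrogateModel | None = None
    hyper_trace: list[dict] = []

    def _one(theta, s):
        sim = simulator.run(theta, s)
        return float(discrepancy(observed, sim))

    for t, bsize in enumerate(budget.batch_sizes()):
        proposal = propose_batch(
            model, space, bsize, t, config, seed=derive_seed(seed, "propose", t)
        )
        eval_seeds = [derive_seed(seed, "eval", t, slot) for slot in range(bsize)]
        if n_jobs > 1:
            from joblib import Parallel, delayed

            outs = Parallel(n_jobs=n_jobs)(
                delayed(_safe_eval)(_one, proposal.theta[i], eval_seeds[i])
                for i in range(bsize)
            )
        else:
            outs = [_safe_eval(_one, proposal.theta[i], eval_seeds[i]) for i in range(bsize)]
        for i, out in enumerate(outs):
            if out is None:
                logger.warning(
                    "simulator failed at theta=%s (round %d, slot %d); "
                    "evaluation counted but excluded", proposal.theta[i], t, i,
                )
                continue
            records.append(
                EvaluationRecord(proposal.theta[i], eval_seeds[i], out, round_index=t)
            )
        if len(records) >= 2:
            cfg = dict(hyper_config or {})
            if model is not None:
                cfg.setdefault("init", model.hyper)
            cfg.setdefault("seed", derive_seed(seed, "hyper", t))
            model = fit_surrogate(records, space, cfg)
            hyper_trace.append(model.hyper.to_dict())
        best = min((r.discrepancy for r in records), default=np.nan)
        logger.info("round %d: %d records, best discrepancy %.4g", t, len(records), best)
        if round_callback is not None and model is not None:
            round_callback(t, list(records), model)

    if model is None:
        raise RuntimeError("no successful evaluations; cannot fit surrogate")
    theta_point, pred_min = surrogate_minimum(
        model, space, seed=derive_seed(seed, "surrmin")
    )
    return BOResult(records, model, theta_point, pred_min, hyper_trace)


def _safe_eval(fn, theta, s):
    try:
        return fn(theta, s)
    except Exception:  # simulator crash: tolerated, logged by caller
        return None
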