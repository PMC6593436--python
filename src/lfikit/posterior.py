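"""ε-approximate ABC posterior from the GP surrogate, MCMC, and slices.

ABC replaces the intractable likelihood P(D_obs|θ) with the relaxation
P(d_θ < ε | θ), where d_θ is the stochastic discrepancy at θ and ε is the
approximation threshold.  Because the GP surrogate's marginal at any θ is
Gaussian N(μ(θ), σ(θ)²), this ε-approximate likelihood is itself
approximated by the Gaussian CDF:

    P(d_θ < ε | θ) ≈ Φ((ε − μ(θ)) / σ(θ)).

Multiplying by the prior gives the (unnormalized) ε-approximate posterior;
its mean — estimated with random-walk Metropolis–Hastings — is the ABC PM
point estimate.  The default threshold rule sets ε a small offset (0.01 on
the discrepancy scale) above the surrogate's estimated minimum, so the
accepted region hugs the best achievable model fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import log_ndtr

from .core import ParameterSpace, derive_seed
from .gp import SurrogateModel, surrogate_minimum

__all__ = [
    "ThresholdConfig",
    "MCMCConfig",
    "PosteriorSamples",
    "approx_log_likelihood",
    "resolve_threshold",
    "log_posterior_unnorm",
    "sample_posterior",
    "posterior_mean",
    "evaluate_slices",
    "plot_slices",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Either a fixed ε or the rule ε = (estimated surrogate minimum) + offset."""

    epsilon: float | None = None
    offset: float = 0.01

    def __post_init__(self):
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("fixed epsilon must be positive")


@dataclass
class MCMCConfig:
    """Adaptive random-walk Metropolis settings (unit-cube proposals)."""

    n_samples: int = 20000
    burn_in_fraction: float = 0.5
    initial_step: float = 0.1
    target_acceptance: tuple[float, float] = (0.2, 0.4)
    adapt_interval: int = 100
    n_chains: int = 1


@dataclass
class PosteriorSamples:
    """MCMC draws from the ε-approximate posterior (natural units)."""

    samples: np.ndarray  # (n_samples, d)
    acceptance_rate: float
    space: ParameterSpace
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def approx_log_likelihood(model: SurrogateModel, theta, eps: float) -> float:
    """log Φ((ε − μ(θ))/σ(θ)), the log ε-approximate likelihood.

    Computed with a numerically stable log-CDF (``scipy.special.log_ndtr``
    switches to the complementary-error-function tail expansion), so deep
    tails ((ε − μ)/σ < −8) return large negative values instead of −inf from
    underflow.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    pred = model.predict(theta)
    return float(log_ndtr((eps - pred.mean) / pred.sd))


def resolve_threshold(
    model: SurrogateModel,
    space: ParameterSpace | None = None,
    config: ThresholdConfig = ThresholdConfig(),
    seed: int = 0,
) -> float:
    """Resolve ε: fixed value, or minimum predicted mean plus the offset."""
    if config.epsilon is not None:
        return float(config.epsilon)
    _, pred_min = surrogate_minimum(model, space or model.space, seed=seed)
    return float(pred_min + config.offset)


def log_posterior_unnorm(model: SurrogateModel, prior: ParameterSpace, theta,
                         eps: float) -> float:
    """Unnormalized log ε-approximate posterior; −inf outside the bounds.

    ``prior`` is the parameter space carrying the per-parameter priors.
    """
    theta = np.asarray(theta, dtype=float)
    lp = prior.prior_log_density(theta)
    if not np.isfinite(lp):
        return -np.inf
    return lp + approx_log_likelihood(model, theta, eps)


def _reflect(u: np.ndarray) -> np.ndarray:
    """Reflect unit-cube coordinates at the [0,1] boundaries."""
    u = np.mod(u, 2.0)
    return np.where(u > 1.0, 2.0 - u, u)


def sample_posterior(
    model: SurrogateModel,
    prior: ParameterSpace,
    eps: float,
    space: ParameterSpace | None = None,
    n_samples: int = 20000,
    seed: int = 0,
    mcmc_config: MCMCConfig | None = None,
    log_target=None,
) -> PosteriorSamples:
    """Random-walk Metropolis–Hastings over the ε-approximate posterior.

    Gaussian proposals in unit-cube coordinates with reflection at the
    bounds; the proposal scale adapts during burn-in toward an acceptance
    rate of 0.2–0.4 and is frozen afterwards.  Burn-in draws are discarded.
    ``log_target(theta)`` may replace the surrogate-based posterior (used by
    the quadrature-oracle tests).  Deterministic given the seed.
    """
    cfg = mcmc_config or MCMCConfig()
    if n_samples < 1000:
        raise ValueError("n_samples must be at least 1000")
    space = space or (model.space if model is not None else prior)
    d = space.dimension
    rng = np.random.default_rng(seed)

    if log_target is None:
        # fast path: cached single-point GP prediction in unit coordinates
        def log_target_u(u):
            th = space.from_unit_cube(u)
            lp = prior.prior_log_density(th)
            if not np.isfinite(lp):
                return -np.inf
            m, s = model.predict_one_unit(u)
            return lp + float(log_ndtr((eps - m) / s))
    else:
        def log_target_u(u):
            return log_target(space.from_unit_cube(u))

    n_burn = int(np.ceil(n_samples * cfg.burn_in_fraction / (1 - cfg.burn_in_fraction)))
    total = n_samples + n_burn

    # start at the prior mean (clipped inside), a reasonable high-density point
    u = np.clip(space.to_unit_cube(space.clip(space.prior_mean())), 1e-6, 1 - 1e-6)
    lp = log_target_u(u)
    if not np.isfinite(lp):  # fall back to prior draws until finite
        for _ in range(200):
            u = rng.uniform(0, 1, size=d)
            lp = log_target_u(u)
            if np.isfinite(lp):
                break

    step = cfg.initial_step
    draws = np.empty((total, d))
    accepts = 0
    window_accepts = 0
    lo, hi = cfg.target_acceptance
    for i in range(total):
        prop = _reflect(u + rng.normal(0, step, size=d))
        lp_prop = log_target_u(prop)
        if np.log(rng.uniform()) < lp_prop - lp:
            u, lp = prop, lp_prop
            accepts += 1
            window_accepts += 1
        draws[i] = u
        if i < n_burn and (i + 1) % cfg.adapt_interval == 0:
            rate = window_accepts / cfg.adapt_interval
            if rate < lo:
                step *= 0.7
            elif rate > hi:
                step *= 1.4
            step = float(np.clip(step, 1e-4, 1.0))
            window_accepts = 0

    kept = draws[n_burn:]
    acc_rate = accepts / total
    if acc_rate < 0.01:
        raise RuntimeError(
            f"MCMC acceptance rate {acc_rate:.4f} below 0.01 after adaptation; "
            "the posterior may be degenerate (check ε and the surrogate)"
        )
    half = kept.shape[0] // 2
    theta_nat = space.from_unit_cube(kept)
    diagnostics = {
        "split_means_first": space.from_unit_cube(kept[:half].mean(axis=0)).tolist(),
        "split_means_second": space.from_unit_cube(kept[half:].mean(axis=0)).tolist(),
        "final_step": step,
        "n_burn": n_burn,
    }
    return PosteriorSamples(theta_nat, acc_rate, space, diagnostics)


def posterior_mean(samples: PosteriorSamples) -> np.ndarray:
    """Coordinate-wise average of the posterior draws (natural units)."""
    if samples.n_samples == 0:
        raise ValueError("no posterior samples")
    return samples.samples.mean(axis=0)


# ---------------------------------------------------------------------------
# Slice evaluation (posterior / model-fit visualization)
# ---------------------------------------------------------------------------


def evaluate_slices(fn, space: ParameterSpace, center, resolution: int = 40) -> dict:
    """1D and 2D slices of ``fn`` through ``center``.

    For every parameter, a 1D grid varying that parameter with the others
    held at the center; for every unordered pair, a 2D grid.  Returns
    ``{"1d": {name: (grid, values)}, "2d": {(name_i, name_j): (gi, gj, V)}}``
    with grids in natural units.  Render with :func:`plot_slices`.
    """
    center = np.asarray(center, dtype=float)
    if not space.contains(center):
        raise ValueError("slice center must lie within the parameter bounds")
    d = space.dimension
    grids = [np.linspace(space.lower[i], space.upper[i], resolution) for i in range(d)]

    out_1d = {}
    for i, name in enumerate(space.names):
        vals = np.empty(resolution)
        for k, g in enumerate(grids[i]):
            th = center.copy()
            th[i] = g
            vals[k] = fn(th)
        out_1d[name] = (grids[i], vals)

    out_2d = {}
    for i, j in combinations(range(d), 2):
        V = np.empty((resolution, resolution))
        for a, gi in enumerate(grids[i]):
            for b, gj in enumerate(grids[j]):
                th = center.copy()
                th[i], th[j] = gi, gj
                V[a, b] = fn(th)
        out_2d[(space.names[i], space.names[j])] = (grids[i], grids[j], V)

    return {"1d": out_1d, "2d": out_2d, "center": center}


def plot_slices(slices: dict, out_dir, prefix: str = "slice") -> list[str]:
    """Render slice grids to PNG files; returns the written paths."""
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name, (g, v) in slices["1d"].items():
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(g, v)
        ax.set_xlabel(name)
        ax.set_ylabel("value")
        path = os.path.join(out_dir, f"{prefix}_1d_{name}.png")
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    for (ni, nj), (gi, gj, V) in slices["2d"].items():
        fig, ax = plt.subplots(figsize=(4, 3.2))
        m = ax.pcolormesh(gj, gi, V, shading="auto")
        ax.contour(gj, gi, V, colors="k", linewidths=0.5)
        ax.set_xlabel(nj)
        ax.set_ylabel(ni)
        fig.colorbar(m, ax=ax)
        path = os.path.join(out_dir, f"{prefix}_2d_{ni}_{nj}.png")
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
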