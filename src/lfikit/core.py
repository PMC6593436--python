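"""Shared domain types for likelihood-free inference over bounded parameter spaces.

A simulator model maps a parameter vector θ to stochastic summary statistics.
Inference methods in this package never see the simulator's internals: they
interact through :class:`ParameterSpace` (named, bounded, ordered real
parameters with per-parameter priors), the simulator contract
(``run(theta, seed) -> SummaryStatistics``), and a discrepancy function
δ(D_obs, D_pred) ≥ 0 measuring misfit between observed and simulated
summaries.  All surrogate and acquisition computations happen on the unit
hypercube; user-facing values are in natural units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "Prior",
    "UniformPrior",
    "TruncatedNormalPrior",
    "ScaledBetaPrior",
    "Parameter",
    "ParameterSpace",
    "SimulatorContract",
    "DiscrepancyFunction",
    "EvaluationRecord",
    "Budget",
    "derive_seed",
    "load_parameter_space",
    "parameter_space_from_yaml",
]

MAX_SEED = 2**31 - 1


def derive_seed(master_seed: int, *path: int | str) -> int:
    """Derive a reproducible child seed from a master seed and an index path.

    Used so that every simulator run, MCMC chain, and policy-training run
    receives its own independent stream: concurrency cannot reorder
    randomness because seeds are fixed up front from ``(master, round, slot)``
    style paths.  Always returns a value in ``[0, 2**31)``.
    """
    h = [int(master_seed) & 0xFFFFFFFF]
    for p in path:
        if isinstance(p, str):
            h.extend(b for b in p.encode())
        else:
            h.append(int(p) & 0xFFFFFFFF)
    return int(np.random.SeedSequence(h).generate_state(1)[0]) % MAX_SEED


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


class Prior:
    """Per-parameter prior over a bounded interval [lower, upper].

    Subclasses wrap scipy.stats frozen distributions; densities are proper
    (integrate to 1 over the bounds) and log-density is -inf outside them.
    """

    lower: float
    upper: float

    def log_density(self, x: float) -> float:
        raise NotImplementedError

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def mean(self) -> float:
        raise NotImplementedError

    def sd(self) -> float:
        raise NotImplementedError

    def spec(self) -> dict:
        raise NotImplementedError


class UniformPrior(Prior):
    def __init__(self, lower: float, upper: float):
        if not lower < upper:
            raise ValueError(f"uniform prior needs lower < upper, got [{lower}, {upper}]")
        self.lower, self.upper = float(lower), float(upper)
        self._dist = stats.uniform(loc=self.lower, scale=self.upper - self.lower)

    def log_density(self, x: float) -> float:
        if x < self.lower or x > self.upper:
            return -np.inf
        return float(-np.log(self.upper - self.lower))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=n)

    def mean(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def sd(self) -> float:
        return (self.upper - self.lower) / np.sqrt(12.0)

    def spec(self) -> dict:
        return {"family": "uniform"}


class TruncatedNormalPrior(Prior):
    """Normal(mean, sd) truncated to [lower, upper].

    Truncation (rather than rejection bookkeeping) keeps the density proper
    when the untruncated mean lies outside the search range, which happens
    for several of the memory-architecture priors (e.g. a latency-factor
    prior centred above its plausibility bound).
    """

    def __init__(self, mean: float, sd: float, lower: float, upper: float):
        if sd <= 0:
            raise ValueError("sd must be positive")
        if not lower < upper:
            raise ValueError(f"truncated normal needs lower < upper, got [{lower}, {upper}]")
        self.loc, self.scale = float(mean), float(sd)
        self.lower, self.upper = float(lower), float(upper)
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        self._dist = stats.truncnorm(a, b, loc=self.loc, scale=self.scale)
        # closed-form log density: N(loc, scale) restricted and renormalized
        mass = stats.norm.cdf(b) - stats.norm.cdf(a)
        self._log_const = -np.log(self.scale) - 0.5 * np.log(2 * np.pi) - np.log(mass)

    def log_density(self, x: float) -> float:
        if x < self.lower or x > self.upper:
            return -np.inf
        z = (x - self.loc) / self.scale
        return float(self._log_const - 0.5 * z * z)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._dist.rvs(size=n, random_state=rng)

    def mean(self) -> float:
        return float(self._dist.mean())

    def sd(self) -> float:
        return float(self._dist.std())

    def spec(self) -> dict:
        return {"family": "normal", "mean": self.loc, "sd": self.scale}


class ScaledBetaPrior(Prior):
    """Beta(α, β) linearly rescaled to [lower, upper]."""

    def __init__(self, alpha: float, beta: float, lower: float = 0.0, upper: float = 1.0):
        if alpha <= 0 or beta <= 0:
            raise ValueError("beta shape parameters must be positive")
        if not lower < upper:
            raise ValueError(f"beta prior needs lower < upper, got [{lower}, {upper}]")
        self.alpha, self.beta = float(alpha), float(beta)
        self.lower, self.upper = float(lower), float(upper)
        self._dist = stats.beta(self.alpha, self.beta, loc=self.lower, scale=self.upper - self.lower)
        from scipy.special import betaln

        self._log_const = -betaln(self.alpha, self.beta) - np.log(self.upper - self.lower)

    def log_density(self, x: float) -> float:
        if x < self.lower or x > self.upper:
            return -np.inf
        t = (x - self.lower) / (self.upper - self.lower)
        if t <= 0.0 or t >= 1.0:
            # boundary: density may be 0 or infinite depending on the shapes
            return float(self._dist.logpdf(x))
        return float(
            self._log_const
            + (self.alpha - 1) * np.log(t)
            + (self.beta - 1) * np.log1p(-t)
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self._dist.rvs(size=n, random_state=rng)

    def mean(self) -> float:
        return float(self._dist.mean())

    def sd(self) -> float:
        return float(self._dist.std())

    def spec(self) -> dict:
        return {"family": "beta", "alpha": self.alpha, "beta": self.beta}


def _build_prior(family: str, lower: float, upper: float, **kw) -> Prior:
    family = family.lower()
    if family == "uniform":
        return UniformPrior(lower, upper)
    if family in ("normal", "truncated_normal"):
        return TruncatedNormalPrior(kw["mean"], kw["sd"], lower, upper)
    if family == "beta":
        return ScaledBetaPrior(kw["alpha"], kw["beta"], lower, upper)
    raise ValueError(f"unknown prior family {family!r}")


# ---------------------------------------------------------------------------
# Parameter space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Parameter:
    name: str
    lower: float
    upper: float
    prior: Prior

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(
                f"parameter {self.name!r}: lower bound {self.lower} must be "
                f"strictly below upper bound {self.upper}"
            )


class ParameterSpace:
    """Ordered list of named, bounded real parameters with priors.

    The affine map to the unit hypercube (``to_unit_cube`` /
    ``from_unit_cube``) is the coordinate system used by the GP surrogate,
    the acquisition optimizer, and the MCMC proposal.
    """

    def __init__(self, params: Sequence[Parameter]):
        names = [p.name for p in params]
        if len(set(names)) != len(names):
            raise ValueError(f"parameter names must be unique, got {names}")
        if not params:
            raise ValueError("parameter space must have at least one parameter")
        self.params = list(params)
        self.names = names
        self.lower = np.array([p.lower for p in params], dtype=float)
        self.upper = np.array([p.upper for p in params], dtype=float)

    @property
    def dimension(self) -> int:
        return len(self.params)

    def __len__(self) -> int:
        return len(self.params)

    def __repr__(self) -> str:
        inner = ", ".join(f"{p.name}∈[{p.lower},{p.upper}]" for p in self.params)
        return f"ParameterSpace({inner})"

    # -- unit-cube mapping ---------------------------------------------------

    def _check_bounds(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        for i, p in enumerate(self.params):
            v = theta[..., i]
            if np.any(v < p.lower - 1e-12) or np.any(v > p.upper + 1e-12):
                raise ValueError(
                    f"parameter {p.name!r} out of bounds [{p.lower}, {p.upper}]: {v}"
                )

    def to_unit_cube(self, theta) -> np.ndarray:
        """Map natural-units θ to [0,1]^d (affine per dimension)."""
        theta = np.asarray(theta, dtype=float)
        self._check_bounds(theta)
        return (theta - self.lower) / (self.upper - self.lower)

    def from_unit_cube(self, u) -> np.ndarray:
        """Inverse of :meth:`to_unit_cube`."""
        u = np.asarray(u, dtype=float)
        return self.lower + u * (self.upper - self.lower)

    def contains(self, theta) -> bool:
        theta = np.asarray(theta, dtype=float)
        return bool(np.all(theta >= self.lower - 1e-12) and np.all(theta <= self.upper + 1e-12))

    def clip(self, theta) -> np.ndarray:
        return np.clip(np.asarray(theta, dtype=float), self.lower, self.upper)

    # -- prior ----------------------------------------------------------------

    def prior_log_density(self, theta) -> float:
        """Sum of per-parameter prior log densities; -inf outside the support."""
        theta = np.asarray(theta, dtype=float)
        total = 0.0
        for i, p in enumerate(self.params):
            ld = p.prior.log_density(float(theta[i]))
            if not np.isfinite(ld):
                return -np.inf
            total += ld
        return total

    def sample_prior(self, n: int, seed: int) -> np.ndarray:
        """n i.i.d. draws from the joint (independent) prior, shape (n, d)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        cols = [p.prior.sample(n, rng) for p in self.params]
        return np.column_stack(cols)

    def prior_mean(self) -> np.ndarray:
        return np.array([p.prior.mean() for p in self.params])

    def prior_sd(self) -> np.ndarray:
        return np.array([p.prior.sd() for p in self.params])

    def to_config(self) -> list[dict]:
        out = []
        for p in self.params:
            d = {"name": p.name, "lower": p.lower, "upper": p.upper}
            d.update({"prior": p.prior.spec()})
            out.append(d)
        return out


def load_parameter_space(config: Iterable[dict]) -> ParameterSpace:
    """Build a ParameterSpace from a list of parameter dicts.

    Each entry: ``{name, lower, upper, prior: {family, ...}}``; ``prior``
    defaults to uniform over the bounds.
    """
    params = []
    for entry in config:
        name = entry["name"]
        lo, hi = float(entry["lower"]), float(entry["upper"])
        pspec = dict(entry.get("prior", {"family": "uniform"}))
        family = pspec.pop("family")
        prior = _build_prior(family, lo, hi, **pspec)
        params.append(Parameter(name, lo, hi, prior))
    return ParameterSpace(params)


def parameter_space_from_yaml(text_or_path) -> ParameterSpace:
    """Load a parameter space from a YAML document (string or file path).

    The document holds a ``parameters:`` list as in :func:`load_parameter_space`.
    """
    import os

    if isinstance(text_or_path, (str, bytes)) and os.path.exists(text_or_path):
        with open(text_or_path) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = yaml.safe_load(text_or_path)
    if isinstance(doc, dict) and "parameters" in doc:
        doc = doc["parameters"]
    return load_parameter_space(doc)


# ---------------------------------------------------------------------------
# Simulator / discrepancy contracts and bookkeeping
# ---------------------------------------------------------------------------


@runtime_checkable
class SimulatorContract(Protocol):
    """A stochastic simulator: parameters in, summary statistics out, seeded.

    The same (theta, seed) pair must produce identical output; different
    seeds may differ.
    """

    space: ParameterSpace

    def run(self, theta: np.ndarray, seed: int): ...


DiscrepancyFunction = Callable[[object, object], float]
"""δ(D_obs, D_pred) -> nonnegative real; δ(x, x) = 0 or a documented floor."""


@dataclass
class EvaluationRecord:
    """One simulator run: parameters, seed and the resulting discrepancy."""

    theta: np.ndarray
    seed: int
    discrepancy: float
    round_index: int = 0

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.isfinite(self.discrepancy):
            raise ValueError(f"discrepancy must be finite, got {self.discrepancy}")


@dataclass(frozen=True)
class Budget:
    """Evaluation budget: total simulator runs and per-round batch size.

    The final batch is truncated when max_evaluations is not divisible by
    batch_size.
    """

    max_evaluations: int
    batch_size: int = 1

    def __post_init__(self):
        if self.max_evaluations < 1:
            raise ValueError("max_evaluations must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.batch_size > self.max_evaluations:
            raise ValueError("batch_size cannot exceed max_evaluations")

    def batch_sizes(self) -> list[int]:
        full, rem = divmod(self.max_evaluations, self.batch_size)
        sizes = [self.batch_size] * full
        if rem:
            sizes.append(rem)
        return sizes
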