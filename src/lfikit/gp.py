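"""Gaussian-process surrogate of the discrepancy surface.

The inference methods treat the map θ ↦ d_θ (the stochastic discrepancy) as
an expensive black box.  A GP regression model fitted to the evaluations so
far provides a predicted mean μ(θ) and standard deviation σ(θ) everywhere in
the space; these feed both the acquisition rule (where to simulate next) and
the ε-approximate likelihood Φ((ε − μ(θ))/σ(θ)).

Kernel: squared-exponential with automatic-relevance-determination (ARD)
lengthscales on the unit hypercube — the standard surrogate choice for
Bayesian optimization.  Targets are centred and scaled by their running
mean/sd before fitting; predictions are un-scaled on output.  The predictive
standard deviation includes the noise variance, so far from all data it
reverts to sqrt(signal_variance + noise_variance) (the model's total prior
uncertainty about a new evaluation).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .core import EvaluationRecord, ParameterSpace

__all__ = [
    "GPHyperparams",
    "SurrogatePrediction",
    "SurrogateModel",
    "fit_surrogate",
    "surrogate_minimum",
]

# jitter ladder tried in order when the Cholesky factorization fails
_JITTERS = (0.0, 1e-10, 1e-8, 1e-6)

# marginal-likelihood optimization bounds, unit-cube / standardized-target scale
_LS_BOUNDS = (0.01, 10.0)
_SV_BOUNDS = (1e-3, 100.0)
_NOISE_BOUNDS = (1e-6, 10.0)


@dataclass
class GPHyperparams:
    """SE-ARD kernel hyperparameters on the unit-cube / standardized scale."""

    lengthscales: np.ndarray
    signal_variance: float = 1.0
    noise_variance: float = 1e-4
    mean_const: float = 0.0

    def __post_init__(self):
        self.lengthscales = np.atleast_1d(np.asarray(self.lengthscales, dtype=float))
        if np.any(self.lengthscales <= 0):
            raise ValueError("lengthscales must be positive")
        if self.signal_variance <= 0:
            raise ValueError("signal_variance must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "lengthscales": self.lengthscales.tolist(),
            "signal_variance": float(self.signal_variance),
            "noise_variance": float(self.noise_variance),
            "mean_const": float(self.mean_const),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GPHyperparams":
        return cls(
            lengthscales=np.asarray(d["lengthscales"], dtype=float),
            signal_variance=d["signal_variance"],
            noise_variance=d["noise_variance"],
            mean_const=d.get("mean_const", 0.0),
        )


@dataclass(frozen=True)
class SurrogatePrediction:
    mean: float
    sd: float


def _sq_dists(X1: np.ndarray, X2: np.ndarray, ls: np.ndarray) -> np.ndarray:
    A = X1 / ls
    B = X2 / ls
    return (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )


def se_ard_kernel(X1: np.ndarray, X2: np.ndarray, hyper: GPHyperparams) -> np.ndarray:
    """Squared-exponential ARD kernel matrix k(X1, X2)."""
    d2 = np.maximum(_sq_dists(X1, X2, hyper.lengthscales), 0.0)
    return hyper.signal_variance * np.exp(-0.5 * d2)


class SurrogateModel:
    """Fitted GP over unit-cube inputs predicting the discrepancy.

    Holds the training inputs U (unit cube), raw targets y (natural
    discrepancy units), the hyperparameters, and a cached Cholesky
    factorization of K + noise·I on the standardized-target scale.
    """

    def __init__(self, U: np.ndarray, y: np.ndarray, hyper: GPHyperparams,
                 space: ParameterSpace):
        self.U = np.atleast_2d(np.asarray(U, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.U.shape[0] != self.y.shape[0]:
            raise ValueError("inputs and targets must have equal length")
        if self.U.shape[0] < 1:
            raise ValueError("need at least one training point")
        self.space = space
        self.hyper = hyper
        # standardization by the running mean/sd of the targets
        self.y_mean = float(np.mean(self.y))
        ysd = float(np.std(self.y))
        self.y_sd = ysd if ysd > 1e-12 else 1.0
        self._z = (self.y - self.y_mean) / self.y_sd
        self._factorize()

    # -- linear algebra -------------------------------------------------------

    def _factorize(self) -> None:
        n = self.U.shape[0]
        K = se_ard_kernel(self.U, self.U, self.hyper)
        K[np.diag_indices_from(K)] += self.hyper.noise_variance
        err = None
        for jit in _JITTERS:
            try:
                self._L = cholesky(K + jit * np.eye(n), lower=True)
                self._jitter = jit
                break
            except np.linalg.LinAlgError as e:  # pragma: no cover - rare path
                err = e
        else:
            raise np.linalg.LinAlgError(
                f"kernel matrix not positive definite after jitter up to {_JITTERS[-1]}: "
                f"{err}; n={n}, hyper={self.hyper.to_dict()}"
            )
        resid = self._z - self.hyper.mean_const
        self._alpha = cho_solve((self._L, True), resid)

    @property
    def n_train(self) -> int:
        return self.U.shape[0]

    def log_marginal_likelihood(self) -> float:
        resid = self._z - self.hyper.mean_const
        n = self.U.shape[0]
        return float(
            -0.5 * resid @ self._alpha
            - np.sum(np.log(np.diag(self._L)))
            - 0.5 * n * np.log(2.0 * np.pi)
        )

    # -- prediction ------------------------------------------------------------

    def predict_batch(self, theta: np.ndarray, unit: bool = False):
        """Predict (mean, sd) at many points; natural discrepancy units.

        ``theta`` has shape (m, d); pass ``unit=True`` when the points are
        already in unit-cube coordinates.
        """
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        Ustar = theta if unit else self.space.to_unit_cube(theta)
        Ks = se_ard_kernel(self.U, Ustar, self.hyper)  # (n, m)
        mean_z = self.hyper.mean_const + Ks.T @ self._alpha
        v = solve_triangular(self._L, Ks, lower=True)
        var_z = (
            self.hyper.signal_variance
            + self.hyper.noise_variance
            - np.sum(v * v, axis=0)
        )
        var_z = np.maximum(var_z, 1e-12)
        mean = self.y_mean + self.y_sd * mean_z
        sd = self.y_sd * np.sqrt(var_z)
        return mean, sd

    def predict(self, theta) -> SurrogatePrediction:
        """Predict at a single point (natural units in, natural units out)."""
        mean, sd = self.predict_batch(np.atleast_2d(theta))
        return SurrogatePrediction(float(mean[0]), float(sd[0]))

    def predict_one_unit(self, u: np.ndarray) -> tuple[float, float]:
        """Low-overhead single-point prediction in unit-cube coordinates.

        Same posterior as :meth:`predict_batch` (uses a cached K⁻¹ instead of
        a triangular solve); the hot path for MCMC over the surrogate.
        """
        if not hasattr(self, "_Kinv"):
            eye = np.eye(self.U.shape[0])
            self._Kinv = cho_solve((self._L, True), eye)
        diff = (self.U - u) / self.hyper.lengthscales
        k = self.hyper.signal_variance * np.exp(-0.5 * np.einsum("ij,ij->i", diff, diff))
        mean_z = self.hyper.mean_const + k @ self._alpha
        var_z = (
            self.hyper.signal_variance
            + self.hyper.noise_variance
            - k @ self._Kinv @ k
        )
        var_z = max(var_z, 1e-12)
        return self.y_mean + self.y_sd * mean_z, self.y_sd * np.sqrt(var_z)

    def predict_mean_gradient(self, U: np.ndarray) -> np.ndarray:
        """∂μ/∂u at unit-cube points U, natural target units per unit-cube step."""
        U = np.atleast_2d(np.asarray(U, dtype=float))
        Ks = se_ard_kernel(self.U, U, self.hyper)  # (n, m)
        ls2 = self.hyper.lengthscales**2
        # grad_j μ(u) = Σ_i α_i k(u, x_i) (x_ij - u_j)/ls_j²
        diff = self.U[:, None, :] - U[None, :, :]  # (n, m, d)
        grad_z = np.einsum("i,inj->nj", self._alpha, (Ks[:, :, None] * diff) / ls2)
        return self.y_sd * grad_z

    # -- serialization ----------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "U": self.U.tolist(),
                "y": self.y.tolist(),
                "hyper": self.hyper.to_dict(),
                "space": self.space.to_config(),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModel":
        from .core import load_parameter_space

        d = json.loads(text)
        return cls(
            np.asarray(d["U"], dtype=float),
            np.asarray(d["y"], dtype=float),
            GPHyperparams.from_dict(d["hyper"]),
            load_parameter_space(d["space"]),
        )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _neg_lml(log_params: np.ndarray, U: np.ndarray, z: np.ndarray, d: int) -> float:
    ls = np.exp(log_params[:d])
    sv = np.exp(log_params[d])
    nv = np.exp(log_params[d + 1])
    hyper = GPHyperparams(ls, sv, nv, 0.0)
    n = U.shape[0]
    K = se_ard_kernel(U, U, hyper)
    K[np.diag_indices_from(K)] += nv
    try:
        L = cholesky(K + 1e-10 * np.eye(n), lower=True)
    except np.linalg.LinAlgError:
        return 1e25
    alpha = cho_solve((L, True), z)
    lml = -0.5 * z @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2 * np.pi)
    if not np.isfinite(lml):
        return 1e25
    return -lml


def _optimize_hyper(U: np.ndarray, z: np.ndarray, init: GPHyperparams,
                    n_restarts: int, seed: int) -> GPHyperparams:
    d = U.shape[1]
    bounds = (
        [(np.log(_LS_BOUNDS[0]), np.log(_LS_BOUNDS[1]))] * d
        + [(np.log(_SV_BOUNDS[0]), np.log(_SV_BOUNDS[1]))]
        + [(np.log(_NOISE_BOUNDS[0]), np.log(_NOISE_BOUNDS[1]))]
    )
    rng = np.random.default_rng(seed)
    starts = [
        np.concatenate(
            [
                np.log(np.clip(init.lengthscales, *_LS_BOUNDS)),
                [np.log(np.clip(init.signal_variance, *_SV_BOUNDS))],
                [np.log(np.clip(max(init.noise_variance, _NOISE_BOUNDS[0]), *_NOISE_BOUNDS))],
            ]
        )
    ]
    for _ in range(n_restarts):
        starts.append(
            np.concatenate(
                [
                    rng.uniform(np.log(0.05), np.log(2.0), size=d),
                    [rng.uniform(np.log(0.2), np.log(5.0))],
                    [rng.uniform(np.log(1e-4), np.log(0.5))],
                ]
            )
        )
    best_x, best_f = None, np.inf
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                _neg_lml, x0, args=(U, z, d), method="L-BFGS-B",
                bounds=bounds, options={"maxiter": 80},
            )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    ls = np.exp(best_x[:d])
    return GPHyperparams(ls, float(np.exp(best_x[d])), float(np.exp(best_x[d + 1])), 0.0)


def fit_surrogate(
    records: list[EvaluationRecord],
    space: ParameterSpace,
    hyper_config: dict | None = None,
) -> SurrogateModel:
    """Fit the GP surrogate to evaluation records.

    ``hyper_config`` keys (all optional):

    - ``optimize`` (default True): maximize the marginal likelihood over
      lengthscales, signal variance and noise variance (multi-start L-BFGS-B
      with bounds lengthscale ∈ [0.01, 10], noise ≥ 1e-6 on the
      unit-cube/standardized scale).
    - ``lengthscales``, ``signal_variance``, ``noise_variance``: fixed values
      (used directly when ``optimize`` is False, as initialization otherwise).
    - ``init`` (GPHyperparams): warm start, e.g. the previous round's fit.
    - ``n_restarts`` (default 2), ``seed`` (default 0).
    """
    cfg = dict(hyper_config or {})
    if len(records) < 2:
        raise ValueError("need at least 2 evaluation records to fit a surrogate")
    theta = np.array([r.theta for r in records], dtype=float)
    y = np.array([r.discrepancy for r in records], dtype=float)
    U = space.to_unit_cube(theta)
    d = space.dimension

    init = cfg.get("init")
    if init is None:
        init = GPHyperparams(
            lengthscales=np.asarray(cfg.get("lengthscales", np.full(d, 0.3)), dtype=float),
            signal_variance=float(cfg.get("signal_variance", 1.0)),
            noise_variance=float(cfg.get("noise_variance", 1e-2)),
        )

    if cfg.get("optimize", True):
        ysd = float(np.std(y))
        z = (y - np.mean(y)) / (ysd if ysd > 1e-12 else 1.0)
        hyper = _optimize_hyper(
            U, z, init, n_restarts=int(cfg.get("n_restarts", 2)),
            seed=int(cfg.get("seed", 0)),
        )
    else:
        hyper = init
        if len(np.unique(U, axis=0)) < len(U) and hyper.noise_variance == 0:
            raise ValueError("duplicate inputs require noise_variance > 0")

    return SurrogateModel(U, y, hyper, space)


def refit_surrogate(model: SurrogateModel, records: list[EvaluationRecord],
                    hyper_config: dict | None = None) -> SurrogateModel:
    """Refit with new data, warm-starting from the previous hyperparameters."""
    cfg = dict(hyper_config or {})
    cfg.setdefault("init", model.hyper)
    return fit_surrogate(records, model.space, cfg)


# ---------------------------------------------------------------------------
# Surrogate minimum (the BO point estimate)
# ---------------------------------------------------------------------------


def surrogate_minimum(
    model: SurrogateModel,
    space: ParameterSpace | None = None,
    n_restarts: int = 20,
    seed: int = 0,
):
    """Minimize the predicted mean μ(θ) by multi-start local search.

    Starts from ``n_restarts`` uniform unit-cube draws plus the best training
    points; L-BFGS-B in unit-cube coordinates.  Returns
    ``(theta_star, predicted_mean)`` in natural units.  Deterministic given
    the seed.
    """
    space = space or model.space
    rng = np.random.default_rng(seed)
    d = space.dimension

    def f(u):
        mean, _ = model.predict_batch(u[None, :], unit=True)
        return float(mean[0])

    def fgrad(u):
        return model.predict_mean_gradient(u[None, :])[0]

    starts = [rng.uniform(0, 1, size=d) for _ in range(n_restarts)]
    order = np.argsort(model.y)
    for idx in order[: min(5, model.n_train)]:
        starts.append(model.U[idx])

    best_u, best_f = None, np.inf
    for u0 in starts:
        res = optimize.minimize(
            f, u0, jac=fgrad, method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * d, options={"maxiter": 100},
        )
        if res.fun < best_f:
            best_u, best_f = np.clip(res.x, 0, 1), float(res.fun)
    theta = space.from_unit_cube(best_u)
    return theta, best_f
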