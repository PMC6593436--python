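"""Shared fixtures: toy simulators with known optima and small spaces."""

from __future__ import annotations

import numpy as np
import pytest

from lfikit import ParameterSpace, load_parameter_space


class QuadraticSimulator:
    """Pseudo-simulator whose 'summary' is a noisy quadratic in θ.

    With the observed summary fixed at 0 and discrepancy |pred − obs|, the
    discrepancy surface is (θ−opt)² + noise — a known-optimum test function
    for the optimizers.
    """

    def __init__(self, opt, noise: float = 0.01, lower=0.0, upper=1.0):
        self.opt = np.atleast_1d(np.asarray(opt, dtype=float))
        self.noise = noise
        d = self.opt.size
        self.space = load_parameter_space(
            [{"name": f"x{i+1}", "lower": lower, "upper": upper} for i in range(d)]
        )
        self.n_calls = 0

    def run(self, theta, seed: int) -> float:
        self.n_calls += 1
        rng = np.random.default_rng(seed)
        val = float(np.sum((np.asarray(theta, dtype=float) - self.opt) ** 2))
        if self.noise > 0:
            val += float(rng.normal(0.0, self.noise))
        return val


def abs_discrepancy(observed: float, predicted: float) -> float:
    return abs(predicted - observed)


@pytest.fixture
def quad2d() -> QuadraticSimulator:
    return QuadraticSimulator([0.3, 0.7], noise=0.01)


@pytest.fixture
def unit_space_1d() -> ParameterSpace:
    return load_parameter_space([{"name": "x", "lower": 0.0, "upper": 1.0}])


def naive_gp_predict(U, z, lengthscales, signal_variance, noise_variance, Ustar):
    """Dense linear-algebra GP oracle: explicit kernel-matrix inverse.

    Returns (mean_z, var_z) on the standardized-target scale, with the noise
    variance included in the predictive variance.  Independent of the
    package's Cholesky-based implementation.
    """
    U = np.atleast_2d(U)
    Ustar = np.atleast_2d(Ustar)
    ls = np.asarray(lengthscales, dtype=float)

    def k(a, b):
        d2 = np.sum(((a[:, None, :] - b[None, :, :]) / ls) ** 2, axis=2)
        return signal_variance * np.exp(-0.5 * d2)

    K = k(U, U) + noise_variance * np.eye(U.shape[0])
    Kinv = np.linalg.inv(K)
    Ks = k(Ustar, U)
    mean = Ks @ Kinv @ z
    var = signal_variance + noise_variance - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return mean, var
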