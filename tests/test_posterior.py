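"""ε-approximate likelihood, MCMC against a quadrature oracle, and slices."""

import numpy as np
import pytest
from scipy.stats import norm

from lfikit import (
    EvaluationRecord,
    MCMCConfig,
    ThresholdConfig,
    approx_log_likelihood,
    evaluate_slices,
    fit_surrogate,
    load_parameter_space,
    log_posterior_unnorm,
    posterior_mean,
    resolve_threshold,
    sample_posterior,
)
from lfikit.posterior import PosteriorSamples
from lfikit.stage import actr_parameter_space


@pytest.fixture
def space1d():
    return load_parameter_space([{"name": "x", "lower": 0.0, "upper": 1.0}])


class FixedSurrogate:
    """Stand-in surrogate with exact μ(θ), σ(θ) (bypasses GP regression)."""

    def __init__(self, space, mu_fn, sigma):
        self.space = space
        self.mu_fn = mu_fn
        self.sigma = sigma

    def predict(self, theta):
        from lfikit.gp import SurrogatePrediction

        th = np.atleast_1d(np.asarray(theta, dtype=float))
        return SurrogatePrediction(float(self.mu_fn(th)), self.sigma)

    def predict_one_unit(self, u):
        th = self.space.from_unit_cube(np.atleast_1d(u))
        return float(self.mu_fn(th)), self.sigma


def quad_mu(th):
    return (th[0] - 0.5) ** 2


class TestApproxLikelihood:
    def test_half_when_mean_equals_threshold(self, space1d):
        model = FixedSurrogate(space1d, lambda th: 0.3, sigma=0.1)
        assert approx_log_likelihood(model, [0.5], eps=0.3) == pytest.approx(np.log(0.5))

    def test_indicator_limit_as_sigma_vanishes(self, space1d):
        below = FixedSurrogate(space1d, lambda th: 0.1, sigma=1e-12)
        above = FixedSurrogate(space1d, lambda th: 0.9, sigma=1e-12)
        assert approx_log_likelihood(below, [0.5], eps=0.5) == pytest.approx(0.0, abs=1e-12)
        assert approx_log_likelihood(above, [0.5], eps=0.5) < -1e6

    def test_known_normal_cdf_value(self, space1d):
        # μ=0.6, σ=0.1, ε=0.48 → log Φ(−1.2)
        model = FixedSurrogate(space1d, lambda th: 0.6, sigma=0.1)
        got = approx_log_likelihood(model, [0.5], eps=0.48)
        assert got == pytest.approx(np.log(0.11507), abs=1e-4)
        assert got == pytest.approx(norm.logcdf(-1.2), abs=1e-10)

    def test_deep_tail_is_finite_and_stable(self, space1d):
        model = FixedSurrogate(space1d, lambda th: 100.0, sigma=0.5)
        val = approx_log_likelihood(model, [0.5], eps=0.01)
        assert np.isfinite(val) and val < -1e4


class TestThreshold:
    @pytest.mark.parametrize("min_mean,expected", [(0.47, 0.48), (7.44, 7.45)])
    def test_offset_rule_adds_001_above_surrogate_minimum(self, space1d, min_mean, expected):
        rng = np.random.default_rng(0)
        xs = rng.uniform(0, 1, 15)
        ys = min_mean + (xs - 0.5) ** 2  # minimum value min_mean at x=0.5
        recs = [EvaluationRecord([x], i, y) for i, (x, y) in enumerate(zip(xs, ys))]
        model = fit_surrogate(
            recs, space1d,
            {"optimize": False, "lengthscales": [0.3], "noise_variance": 1e-6},
        )
        eps = resolve_threshold(model, space1d, ThresholdConfig(offset=0.01), seed=0)
        assert eps == pytest.approx(expected, abs=5e-3)

    def test_fixed_epsilon_passes_through(self, space1d):
        model = FixedSurrogate(space1d, quad_mu, 0.05)
        assert resolve_threshold(model, space1d, ThresholdConfig(epsilon=1.0)) == 1.0


class TestLogPosterior:
    def test_outside_bounds_is_minus_inf(self, space1d):
        model = FixedSurrogate(space1d, quad_mu, 0.05)
        assert log_posterior_unnorm(model, space1d, [1.5], eps=0.1) == -np.inf

    def test_huge_epsilon_recovers_prior(self, space1d):
        model = FixedSurrogate(space1d, quad_mu, 0.05)
        # ε far above μ everywhere → log-likelihood ≈ 0, posterior ∝ prior
        for x in (0.1, 0.5, 0.9):
            lp = log_posterior_unnorm(model, space1d, [x], eps=50.0)
            assert lp == pytest.approx(space1d.prior_log_density([x]), abs=1e-10)

    def test_uniform_prior_preserves_likelihood_ordering(self, space1d):
        model = FixedSurrogate(space1d, quad_mu, 0.05)
        xs = [0.5, 0.4, 0.2]
        lps = [log_posterior_unnorm(model, space1d, [x], eps=0.05) for x in xs]
        assert lps[0] > lps[1] > lps[2]


def _quadrature_moments(log_post, lo=0.0, hi=1.0, n=20001):
    xs = np.linspace(lo, hi, n)
    logw = np.array([log_post(x) for x in xs])
    w = np.exp(logw - logw.max())
    w /= np.trapezoid(w, xs)
    mean = np.trapezoid(w * xs, xs)
    var = np.trapezoid(w * (xs - mean) ** 2, xs)
    return mean, np.sqrt(var)


def _ess(x):
    """Effective sample size via initial-positive-sequence autocorrelation."""
    x = np.asarray(x) - np.mean(x)
    n = x.size
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for k in range(1, min(n, 2000)):
        if acf[k] <= 0:
            break
        tau += 2 * acf[k]
    return n / tau


class TestMCMC:
    def _toy_target(self, space):
        model = FixedSurrogate(space, quad_mu, 0.05)

        def log_target(th):
            return log_posterior_unnorm(model, space, th, eps=0.05)

        return log_target

    def test_symmetric_posterior_mean_is_half(self, space1d):
        log_target = self._toy_target(space1d)
        samples = sample_posterior(
            None, space1d, eps=0.05, space=space1d, n_samples=20000, seed=3,
            log_target=lambda th: log_target(th),
        )
        assert posterior_mean(samples)[0] == pytest.approx(0.5, abs=0.01)

    def test_moments_match_dense_quadrature_oracle(self, space1d):
        log_target = self._toy_target(space1d)
        samples = sample_posterior(
            None, space1d, eps=0.05, space=space1d, n_samples=20000, seed=7,
            log_target=lambda th: log_target(th),
        )
        x = samples.samples[:, 0]
        q_mean, q_sd = _quadrature_moments(lambda v: log_target(np.array([v])))
        ess = _ess(x)
        se_mean = q_sd / np.sqrt(ess)
        assert abs(x.mean() - q_mean) < 3 * se_mean
        se_sd = q_sd / np.sqrt(2 * ess)  # delta-method SE for the sd
        assert abs(x.std() - q_sd) < 3 * se_sd

    def test_chain_is_deterministic_given_seed(self, space1d):
        log_target = self._toy_target(space1d)
        a = sample_posterior(None, space1d, 0.05, space1d, 1000, seed=11,
                             log_target=log_target)
        b = sample_posterior(None, space1d, 0.05, space1d, 1000, seed=11,
                             log_target=log_target)
        assert np.array_equal(a.samples, b.samples)
        assert a.acceptance_rate == b.acceptance_rate

    def test_acceptance_rate_in_adapted_band(self, space1d):
        log_target = self._toy_target(space1d)
        s = sample_posterior(None, space1d, 0.05, space1d, 10000, seed=2,
                             log_target=log_target)
        assert 0.1 < s.acceptance_rate < 0.6

    def test_all_samples_within_bounds(self):
        space = actr_parameter_space()
        model = FixedSurrogate(space, lambda th: 0.5, 0.2)
        s = sample_posterior(model, space, eps=0.6, space=space, n_samples=2000, seed=1)
        assert np.all(s.samples >= space.lower) and np.all(s.samples <= space.upper)


class TestPosteriorMean:
    def test_trivial_cases(self, space1d):
        same = PosteriorSamples(np.tile([[0.3]], (5, 1)), 0.3, space1d)
        assert posterior_mean(same)[0] == pytest.approx(0.3)
        two = PosteriorSamples(np.array([[0.2], [0.8]]), 0.3, space1d)
        assert posterior_mean(two)[0] == pytest.approx(0.5)


class TestSlices:
    def test_combinatorics_in_4d(self):
        space = actr_parameter_space()
        center = space.prior_mean()
        center = space.clip(center)
        sl = evaluate_slices(lambda th: 1.0, space, center, resolution=5)
        assert len(sl["1d"]) == 4
        assert len(sl["2d"]) == 6
        for _, (g, v) in sl["1d"].items():
            assert np.allclose(v, 1.0)  # constant fn → flat slices

    def test_slice_argmax_at_posterior_mode(self, space1d):
        model = FixedSurrogate(space1d, quad_mu, 0.05)

        def fn(th):
            return log_posterior_unnorm(model, space1d, th, eps=0.05)

        sl = evaluate_slices(fn, space1d, np.array([0.5]), resolution=101)
        g, v = sl["1d"]["x"]
        assert abs(g[np.argmax(v)] - 0.5) <= (g[1] - g[0])

    def test_center_outside_bounds_rejected(self, space1d):
        with pytest.raises(ValueError):
            evaluate_slices(lambda th: 0.0, space1d, np.array([1.5]))
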