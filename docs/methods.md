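# Methods

This note documents the models and procedures implemented in `lfikit`, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Problem setting

A stochastic simulator maps parameters θ ∈ ℝ^d (each bounded, with an
independent per-parameter prior) to summary statistics.  Model fit to
observed summaries is a discrepancy δ(D_obs, D_sim) ≥ 0; at fixed θ the
discrepancy is a random variable d_θ because the simulator is stochastic.
All inference operates on realizations of d_θ; the simulator is otherwise a
black box.  Every stochastic operation takes a seed and is bit-reproducible
given it; child seeds are derived from (master seed, structured path) via
`numpy.random.SeedSequence`, so batch evaluations can run concurrently
without reordering randomness.

Priors are one of uniform(lower, upper), normal(mean, sd) truncated to the
bounds, or beta(α, β) rescaled to the bounds.  Truncation (rather than
rejection) keeps densities proper even when the untruncated mean lies
outside the search range, which occurs for the LF and ANS priors of the
stage-duration fixture.  Log-densities use closed forms (validated against
scipy's frozen distributions and by numerical integration to 1e-3) because
they sit in the MCMC hot loop.

## GP surrogate

Squared-exponential kernel with per-dimension (ARD) lengthscales on the
unit hypercube; all surrogate and acquisition computations happen in
unit-cube coordinates, with natural units only at the user-facing surface.
Targets are centred and scaled by their running mean/sd before fitting.
The predictive variance includes the noise variance, so σ(θ) reverts to
√(signal + noise) far from data — the right scale for the ε-approximate
likelihood, which concerns a *new* simulator run.

Hyperparameters (lengthscales, signal variance, noise variance) are
re-estimated after every optimization round by marginal-likelihood
maximization: multi-start L-BFGS-B in log space with bounds
lengthscale ∈ [0.01, 10], signal ∈ [1e-3, 100], noise ∈ [1e-6, 10]
(standardized scale), warm-started from the previous round's values.
Cholesky factorizations use a jitter ladder 0 → 1e-10 → 1e-8 → 1e-6; a
matrix still not positive definite raises a diagnostic error.  The
constant mean is fixed at the running target mean (0 after
standardization).  Surrogate state (inputs, targets, hyperparameters,
space) serializes to JSON and reloads exactly.

## Bayesian optimization

Acquisition is the GP-UCB rule written as a lower confidence bound
μ(θ) − √β_t·σ(θ), because discrepancy is minimized.  The schedule is
β_t = 2·log(t^(d/2+2)·π²/(3δ)) with δ = 0.1.  The acquisition is
minimized over 512 scrambled-Sobol candidates plus the training inputs,
with L-BFGS-B refinement from the best 5.

Batches are constructed sequentially with local penalization: each already
chosen point x_j multiplies the acquisition's improvement (relative to the
candidate-set worst) by Φ((L‖x − x_j‖ − M + μ(x_j)) / (√2·σ(x_j))), where
M is the best observed discrepancy and L is a Lipschitz estimate — the
maximum analytic gradient norm of μ over the candidate set.  Chosen points
are required to be ≥ 1e-6 apart in the unit cube.  Round 0 (no model yet)
uses i.i.d. prior draws.

Per-evaluation seeds are derived as hash(master, round, slot) before the
batch runs, so concurrent execution (joblib, `n_jobs > 1`) is bit-identical
to sequential.  A simulator crash at one θ is logged, excluded from the
records, and still counted against the budget.  The BO point estimate is
the surrogate-mean minimizer (multi-start L-BFGS-B with analytic
gradients).

## ABC posterior

ε-approximate likelihood: P(d_θ < ε | θ) ≈ Φ((ε − μ(θ))/σ(θ)), computed
with `scipy.special.log_ndtr` so the deep tail ((ε − μ)/σ < −8) stays
finite.  The default threshold rule is ε = (estimated surrogate minimum) +
0.01; the offset lives on the discrepancy scale and is configurable
because that scale is pipeline-specific (RMSE in seconds vs ln-E).

MCMC is adaptive random-walk Metropolis in unit-cube coordinates with
reflection at the bounds: Gaussian proposals whose scale is multiplied by
0.7 / 1.4 every 100 burn-in steps when acceptance leaves [0.2, 0.4], then
frozen.  The first 50% of the chain is burn-in and discarded; a single
chain by default; 20 000 retained samples by default; acceptance below
0.01 after adaptation raises a diagnostic error.  The posterior mean (ABC
PM) is the coordinate-wise average in natural units.  1D/2D slice
evaluation through a centre point supports the posterior and model-fit
visualizations; rendering is a separate function so the numeric grids stay
testable.

## Baselines

Grid search evaluates cell centres of an even partition (n_per_dim^d
evaluations, one simulation per cell, no averaging); failed cells are
recorded as missing and excluded from the argmin.  Nelder–Mead uses the
standard coefficients (reflection 1, expansion 2, contraction 0.5, shrink
0.5) on the noisy objective, with out-of-bounds vertices clipped to the
bounds and the initial simplex spanning 0.25 of the unit cube from a
prior-drawn start.  `restarts = k` runs k independent optimizations and
returns the best *training* vertex — the "parallelized Nelder–Mead"
simulation.  Because each function value is a fresh stochastic simulation,
Nelder–Mead can over-fit chance low draws; the comparison harness's
hold-out traces make that visible.

## Menu-search pipeline

One episode: an 8-item menu has a target with probability 0.9 (uniform
position, highest semantic-relevance level); the agent either fixates an
item or quits.  Fixating the target selects it automatically and ends the
episode; fixating a non-target reveals its relevance and length and, with
probability 0.93 (one Bernoulli draw per fixation), both neighbours'
— the peripheral-vision constant is fixed, not inferred.  Quitting ends
the episode: a large reward if the target was truly absent, an equally
large penalty if present.  Other actions cost their duration: saccade
(37 ms + 2.7 ms per item of travel — a linear saccade-duration law;
coefficients configurable) plus the fixation `f_dur`; finding the target
adds the selection delay `d_sel`.  With probability `p_rec` the whole menu
layout is recalled at episode start.  Episodes are capped at 20 actions,
then a quit is forced.

The policy is learned per parameter vector by tabular Q-learning (ε-greedy
0.5 → 0.05 linear decay, learning rate 0.1, γ = 1 — episodic with a
forced-quit horizon).  The Q-state uses the sanctioned aggregation when
the full per-item (relevance × length) product space would exceed a
configured bound: the set of observed positions plus the target position
if observed.  In this generator non-target relevances are i.i.d. and carry
no information about target location, so the aggregation preserves the
decision-relevant state; with correlated menu semantics it would not, and
the full per-item key (used automatically for small menus, e.g. the
enumerable 2-item MDP in the tests) should be preferred.  Greedy
simulation in a never-visited state falls back deterministically to
"fixate the leftmost unobserved item, else quit".

Menu content generation (i.i.d. uniform relevance levels {0, 0.3, 0.6,
0.9}, two length classes with no direct behavioural role), the reward
magnitude (10 000 ms-equivalent, dominating any episode duration), and the
saccade coefficients are package choices where the underlying model
description is silent; all are configurable and none is inferred.

Summaries are per-condition completion-time mean and population sd (ms);
model fit is ln E, E = Σ_{c∈{pre,abs}} |Δμ_c| + |Δσ_c|, floored at
E = 1e-6 ms so identical summaries give ln(1e-6) rather than −∞.

What the synthetic menu data do not emulate: real users' scanpath
statistics, item-length effects on reading time, inter-subject strategy
variation beyond the three parameters, and menu semantics correlated with
target position.  Passing recovery tests therefore show the *inference
machinery* identifies the generating parameters of this model class — not
that the model captures human menu use.

## Stage-duration pipeline

Model fit is RMSE = √((1/9) Σ_{phase,stage} (d_obs − d_pred)²) over a 3×3
table of mean stage durations (s).  The bundled simulator is a synthetic
stand-in for the production-system architecture that normally produces
such tables (that architecture runs in its own LISP runtime and is not
reimplemented; it can be plugged in through the simulator contract).  The
stand-in maps unit-scaled (RT, LF) through fixed, linearly independent
cell-coefficient patterns (plus a mild quadratic term in RT), adds a weak
(3% scale) dependence on (BLC, ANS), and i.i.d. Gaussian cell noise with
sd 0.05 s.  It reproduces the qualitative sensitivity structure — RT and
LF identifiable, BLC and ANS not — which is the property the inference
stack is tested against; its cell values themselves have no empirical
meaning.

## Comparison harness

For each method × replication, training discrepancy (best so far) and
hold-out error at the current point estimate are recorded at increasing
evaluation-count checkpoints; bands are percentile summaries across
replications (5th/95th by default).  The resource axis is simulator
evaluation count — the hardware-independent twin of CPU-hours on fixed
hardware, since simulator runs dominate every method's cost.  Hold-out
error averages the discrepancy against hold-out summaries over runs at
points drawn uniformly within ±0.02 unit-cube units of the estimate
(clipped to bounds); the region size is a package choice, configurable.
Per-subject inference runs an independent ABC per subject with derived
seeds and isolated failures.  Exports (traces CSV with fixed column
order, summary JSON with sorted keys, full-precision floats) reload
bit-exactly, and repeated runs at the same seed are byte-identical.

## Problem sizes used in tests and the acceptance script

GP-oracle checks use ≤ 20 training points; the MCMC-vs-quadrature check
uses 20 000 retained samples on a fixed 1D toy surrogate; BO-vs-grid uses
a 2D stochastic quadratic (noise sd 0.01) with 60 evaluations against a
15² grid; menu end-to-end recovery trains 2 000 Q-learning episodes and
simulates 500 evaluation episodes per simulator call with a 48-evaluation
budget and 4 000 MCMC samples; stage-duration recovery uses a
200-evaluation budget.  These desk scales were chosen once as the smallest
sizes at which the respective properties are statistically stable;
production analyses should scale the Q-learning episode count and MCMC
chain length up by one to two orders of magnitude.

## Known limitations

- Continuous parameters only; no discrete/categorical support.
- Single-chain MCMC by default; split-mean diagnostics are reported but no
  automatic convergence assessment is enforced.
- The UCB/LCB acquisition is the only one implemented (no EI/PI/entropy
  search), and no sparse-GP approximations are provided, so budgets beyond
  a few thousand evaluations will be slow to refit.
- The menu model omits features of richer visual-search models: explicit
  selection actions, fixation-location state, semantic grouping.
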