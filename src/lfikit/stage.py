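"""Stage-duration pipeline: RMSE model fit over 3×3 duration tables and a
synthetic stand-in simulator for a memory-architecture model.

The observed data structure is a table of mean durations (seconds) of three
processing stages — encode, solve, respond — across three learning phases.
Model fit is the root-mean-square error over the nine phase×stage cells.

The real cognitive architecture behind this pipeline (a production-system
model with retrieval threshold RT, latency factor LF, base-level constant
BLC, and activation noise ANS) runs in its own LISP runtime and is not
reimplemented here; any such model can be plugged in through the simulator
contract.  For end-to-end testing this module provides a *synthetic*
stage-duration simulator with the same parameter-sensitivity structure:
durations depend strongly and smoothly on RT and LF, only weakly on BLC and
ANS (≤ 5% of the strong sensitivity scale), plus slight evaluation
stochasticity.  That structure is what makes RT/LF identifiable and
BLC/ANS not — the qualitative finding the inference stack must reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    Parameter,
    ParameterSpace,
    TruncatedNormalPrior,
    UniformPrior,
)

__all__ = [
    "StageDurationTable",
    "STAGES",
    "PHASES",
    "rmse_discrepancy",
    "actr_parameter_space",
    "SyntheticStageSimulator",
]

STAGES = ("encode", "solve", "respond")
PHASES = (1, 2, 3)


@dataclass(frozen=True)
class StageDurationTable:
    """3×3 matrix of mean durations (s): rows = learning phases 1–3,
    columns = stages (encode, solve, respond)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"stage-duration table must be 3x3, got {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("durations must be finite and nonnegative")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(PHASES, name="phase"),
                            columns=list(STAGES))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "StageDurationTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df[list(STAGES)].to_numpy(dtype=float))


def rmse_discrepancy(observed: StageDurationTable, predicted: StageDurationTable) -> float:
    """sqrt((1/9) Σ_{phase,stage} (d_obs − d_pred)²)."""
    diff = observed.values - predicted.values
    return float(np.sqrt(np.mean(diff**2)))


def actr_parameter_space() -> ParameterSpace:
    """Parameter-space fixture for the memory-architecture pipeline.

    RT ∈ [−4.5, −2.5] uniform; LF ∈ [0.001, 0.15] ~ N(0.2, 0.2);
    BLC ∈ [0, 20] ~ N(10, 10); ANS ∈ [0.001, 0.15] ~ N(0.3, 0.2); the
    normal priors are truncated to the search bounds (for LF and ANS the
    untruncated mean lies above the range, giving a monotone density).
    """
    return ParameterSpace([
        Parameter("RT", -4.5, -2.5, UniformPrior(-4.5, -2.5)),
        Parameter("LF", 0.001, 0.15, TruncatedNormalPrior(0.2, 0.2, 0.001, 0.15)),
        Parameter("BLC", 0.0, 20.0, TruncatedNormalPrior(10.0, 10.0, 0.0, 20.0)),
        Parameter("ANS", 0.001, 0.15, TruncatedNormalPrior(0.3, 0.2, 0.001, 0.15)),
    ])


# Fixed coefficient patterns of the synthetic response surface.  The strong
# (RT, LF) patterns are linearly independent across the 9 cells so both
# parameters are identifiable from a single table; the weak (BLC, ANS)
# patterns are scaled to <= 5% of the strong sensitivity.
_BASE = np.array([
    [1.8, 3.2, 1.1],
    [1.4, 2.5, 0.9],
    [1.1, 2.0, 0.8],
])
_COEF_RT = np.array([
    [0.50, 1.20, 0.20],
    [0.40, 0.90, 0.15],
    [0.30, 0.70, 0.10],
])
_COEF_LF = np.array([
    [0.90, -0.30, 0.50],
    [0.70, -0.20, 0.40],
    [0.50, -0.10, 0.30],
])
_COEF_BLC = np.array([
    [0.4, 0.6, 0.2],
    [0.3, 0.5, 0.2],
    [0.2, 0.4, 0.1],
])
_COEF_ANS = np.array([
    [0.5, 0.3, 0.2],
    [0.4, 0.3, 0.2],
    [0.3, 0.2, 0.1],
])
_WEAK_SCALE = 0.03  # 3% of the strong coefficient scale


class SyntheticStageSimulator:
    """Synthetic stand-in stage-duration simulator (not the real architecture).

    Deterministic smooth map from unit-cube-scaled (RT, LF) to the nine cell
    means (with a mild quadratic term in RT so the discrepancy surface has
    curvature), weak linear dependence on (BLC, ANS), and i.i.d. Gaussian
    cell noise with sd ``noise_sd`` (default 0.05 s — slight evaluation
    stochasticity).
    """

    def __init__(self, noise_sd: float = 0.05):
        if noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        self.noise_sd = float(noise_sd)
        self.space = actr_parameter_space()

    def mean_table(self, theta) -> np.ndarray:
        u = self.space.to_unit_cube(np.asarray(theta, dtype=float)) - 0.5
        u_rt, u_lf, u_blc, u_ans = u
        cells = (
            _BASE
            + _COEF_RT * u_rt
            + 0.6 * _COEF_RT * u_rt**2
            + _COEF_LF * u_lf
            + _WEAK_SCALE * (_COEF_BLC * u_blc + _COEF_ANS * u_ans)
        )
        return np.maximum(cells, 0.0)

    def run(self, theta, seed: int) -> StageDurationTable:
        rng = np.random.default_rng(int(seed))
        cells = self.mean_table(theta)
        if self.noise_sd > 0:
            cells = np.maximum(cells + rng.normal(0.0, self.noise_sd, size=(3, 3)), 0.0)
        return StageDurationTable(cells)
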