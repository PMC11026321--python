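"""Simulation-based power analyses for both experimental designs.

Experiment 1: synthetic participants behave exactly like the minimal-
trajectory model, with independent Gaussian noise added to every condition
mean (one data point per participant per cell of the 3 vertical-start x 8
target grid, clipped to the screen), so data points of individual
participants are uncorrelated. Each replicate runs the GG-corrected
two-way within-participant ANOVA; power per effect is the fraction of
replicates with p < alpha.

Experiment 2: the study's original design-stage simulation drew from each
empirical participant's trial mean and SD, which require the raw study
data; an explicit surrogate is used instead (documented defaults: test-target click means 0.28 screen heights
above/below the center, trial SD 0.07) and a hypothetical inducer-
eccentricity effect that grows linearly from zero at block start to
``effect_size`` per adjacent eccentricity level at block end. Each
replicate aggregates test trials to cell means and runs the 2 (target) x 3
(eccentricity) GG-corrected ANOVA, plus the 2 x 3 x 3 analysis with
subblock for the three-way interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .task import EXP1, EXP2, ScrollRequirement, required_displacement
from .strategies import minimal_path_click
from .stats import rm_anova_cube

__all__ = [
    "PowerConfig",
    "PowerResult",
    "Exp2Surrogate",
    "exp1_predictions",
    "exp1_power_sim",
    "exp2_power_sim",
]

EXP1_TARGETS = (1, 2, 3, 4, 6, 7, 8, 9)
EXP1_STARTS = (-0.4, 0.0, 0.4)


@dataclass(frozen=True)
class PowerConfig:
    """Settings of one Monte-Carlo power study."""

    n_participants: tuple = (18, 24, 30, 36)
    noise_sd: float = 0.20          # exp1: per-cell click noise SD
    effect_size: float = 0.03       # exp2: end-of-block effect per adjacent level
    n_reps: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass(frozen=True)
class PowerResult:
    """Per (n, effect) Monte-Carlo power estimates."""

    power: Dict[tuple, float]   # (n, effect_name) -> power in [0, 1]
    n_reps: int
    alpha: float

    def mc_se(self, n: int, effect: str) -> float:
        p = self.power[(n, effect)]
        return float(np.sqrt(p * (1.0 - p) / self.n_reps))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"n_participants": n, "effect": e, "power": p,
                 "mc_se": self.mc_se(n, e), "n_reps": self.n_reps}
                for (n, e), p in sorted(self.power.items())]
        return pd.DataFrame(rows)


def exp1_predictions() -> np.ndarray:
    """Minimal-trajectory click predictions on the Exp 1 grid.

    Returns an array of shape (3 vertical starts, 8 targets); the
    horizontal start side is symmetric and does not affect the vertical
    prediction.
    """
    gap_x = 0.5 + EXP1.start_offset_horizontal  # right start; symmetric
    pred = np.empty((len(EXP1_STARTS), len(EXP1_TARGETS)))
    for i, sv in enumerate(EXP1_STARTS):
        for j, t in enumerate(EXP1_TARGETS):
            req = ScrollRequirement.for_target(t, EXP1)
            pred[i, j] = minimal_path_click((gap_x, 0.5 + sv), req, EXP1)[0]
    return pred


def exp1_power_sim(cfg: PowerConfig) -> PowerResult:
    """Replicate the Exp 1 design-stage power simulation.

    Per replicate and participant, each of the 24 condition means equals
    the model prediction plus Normal(0, noise_sd), clipped to [0, 1]; the
    two-way GG-corrected ANOVA (vertical start x target number) is run and
    each effect's p compared with alpha.
    """
    rng = np.random.default_rng(cfg.seed)
    pred = exp1_predictions()
    effects = ("start_vertical", "target_number", "start_vertical:target_number")
    hits = {(n, e): 0 for n in cfg.n_participants for e in effects}
    for n in cfg.n_participants:
        for _ in range(cfg.n_reps):
            Y = pred[None, :, :] + rng.normal(0.0, cfg.noise_sd,
                                              size=(n, *pred.shape))
            np.clip(Y, 0.0, 1.0, out=Y)
            res = rm_anova_cube(Y, ["start_vertical", "target_number"])
            for eff in res:
                if eff.p < cfg.alpha:
                    hits[(n, eff.effect)] += 1
    power = {k: v / cfg.n_reps for k, v in hits.items()}
    return PowerResult(power=power, n_reps=cfg.n_reps, alpha=cfg.alpha)


@dataclass(frozen=True)
class Exp2Surrogate:
    """Surrogate per-participant trial model for the Exp 2 power study.

    Test-target click means sit ``mean_eccentricity`` above (target 13,
    downward scroll) and below (target 17, upward scroll) the screen
    center; individual trials scatter around them with ``trial_sd``.
    """

    mean_eccentricity: float = 0.28
    trial_sd: float = 0.07
    trials_per_target_subblock: int = 8
    n_subblocks: int = 3


def _exp2_ramp(surrogate: Exp2Surrogate) -> np.ndarray:
    """Linear within-block growth factor for each (subblock, trial) slot.

    Test trials are assumed evenly spread through each subblock; the factor
    rises from 0 at block start to 1 at block end.
    """
    s = np.arange(surrogate.n_subblocks)[:, None]
    r = (np.arange(surrogate.trials_per_target_subblock)[None, :] + 0.5)
    within = r / surrogate.trials_per_target_subblock
    return (s + within) / surrogate.n_subblocks


def exp2_power_sim(cfg: PowerConfig,
                   surrogate: Optional[Exp2Surrogate] = None) -> PowerResult:
    """Replicate the Exp 2 design-stage power simulation.

    The hypothetical inducer-eccentricity effect moves test-trial clicks
    away from the screen center by ``(level - 1) * effect_size * ramp``
    units, where level is 0/1/2 for low/medium/high blocks and ramp grows
    linearly from 0 to 1 within each block. Power is reported for the
    target x eccentricity interaction of the 2 x 3 analysis and for the
    three-way term of the 2 x 3 x 3 analysis including subblock.
    """
    surrogate = surrogate or Exp2Surrogate()
    rng = np.random.default_rng(cfg.seed)
    ramp = _exp2_ramp(surrogate)            # (subblock, trial)
    levels = np.array([0.0, 1.0, 2.0])      # low, medium, high
    # direction of "away from center": +1 for target 13 (high clicks),
    # -1 for target 17 (low clicks)
    tdir = np.array([1.0, -1.0])
    base = 0.5 + tdir * surrogate.mean_eccentricity
    effects2 = ("target:eccentricity",)
    effects3 = ("target:eccentricity:subblock",)
    hits = {(n, e): 0 for n in cfg.n_participants
            for e in effects2 + effects3}
    shape = (len(levels), surrogate.n_subblocks, len(tdir),
             surrogate.trials_per_target_subblock)
    shift = ((levels - 1.0)[:, None, None, None] * cfg.effect_size
             * ramp[None, :, None, :] * tdir[None, None, :, None])
    mean = base[None, None, :, None] + shift
    for n in cfg.n_participants:
        for _ in range(cfg.n_reps):
            trials = mean[None] + rng.normal(0.0, surrogate.trial_sd,
                                             size=(n, *shape))
            np.clip(trials, 0.0, 1.0, out=trials)
            cells = trials.mean(axis=-1)    # (n, ecc, subblock, target)
            Y2 = cells.mean(axis=2).transpose(0, 2, 1)   # (n, target, ecc)
            res2 = rm_anova_cube(Y2, ["target", "eccentricity"])
            for eff in res2:
                if eff.effect == "target:eccentricity" and eff.p < cfg.alpha:
                    hits[(n, "target:eccentricity")] += 1
            Y3 = cells.transpose(0, 3, 1, 2)  # (n, target, ecc, subblock)
            res3 = rm_anova_cube(Y3, ["target", "eccentricity", "subblock"])
            for eff in res3:
                if (eff.effect == "target:eccentricity:subblock"
                        and eff.p < cfg.alpha):
                    hits[(n, "target:eccentricity:subblock")] += 1
    power = {k: v / cfg.n_reps for k, v in hits.items()}
    return PowerResult(power=power, n_reps=cfg.n_reps, alpha=cfg.alpha)
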