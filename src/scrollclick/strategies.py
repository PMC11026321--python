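"""Candidate models of how a click position on the scrollable line is chosen.

Four strategies are implemented, each mapping a trial context to a predicted
first-click position on the line:

``minimal_path``
    Picks the click position minimizing the total cursor trajectory length
    (initial approach from the start square plus all drag and return
    movements), assuming linear trajectories and no unnecessary movements.
``target_click``
    Clicks the square carrying the target number if it is on screen, else
    the closest on-screen point of the line.
``edge_buffer``
    Uses the screen border as a buffer stop: any click inside the one-go
    interval, then a fast drag to the border. The interval midpoint is used
    as the point prediction; the predicted final cursor position is the
    border itself.
``heuristic``
    A two-component account: a direction-based eccentricity (clicks on the
    upper half of the line for downward scrolls and vice versa), whose size
    tracks the typical scroll amplitude of the recent task context, further
    adjusted partially toward the current trial's amplitude, and pulled
    toward the previous trial's click eccentricity (motor hysteresis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .task import (
    TaskConfig,
    LineState,
    INITIAL_STATE,
    ScrollRequirement,
    one_go_interval,
    scroll_path_cost,
)

__all__ = [
    "StrategyParams",
    "ContextState",
    "EdgeBufferPrediction",
    "minimal_path_click",
    "target_click",
    "edge_buffer_click",
    "heuristic_click",
    "update_context",
    "fit_heuristic_params",
    "STRATEGY_NAMES",
]

STRATEGY_NAMES = ("minimal_path", "target_click", "edge_buffer", "heuristic")

GRID_RESOLUTION = 0.001


@dataclass(frozen=True)
class StrategyParams:
    """Parameters of the two-component heuristic.

    base_eccentricity : float
        e0, distance of the direction-based click component from the screen
        center (screen heights).
    amplitude_gain : float
        k in [0, 1], shift of the click eccentricity per unit of deviation
        of the current amplitude from the context's typical amplitude. A
        value of 0.5 means a 100-pixel larger scroll moves the click only
        50 pixels further out.
    hysteresis_weight : float
        lambda in [0, 1], convex pull of the planned eccentricity toward the
        previous trial's click eccentricity.
    context_rate : float
        alpha in [0, 1], per-trial exponential-smoothing rate of the running
        mean absolute amplitude that defines the task context.
    noise_sd : float
        SD of trial-level Gaussian noise added to the click position.
    base_eccentricity_up, base_eccentricity_down : float, optional
        Direction-specific overrides of e0 (default: equal).
    """

    base_eccentricity: float = 0.25
    amplitude_gain: float = 0.5
    hysteresis_weight: float = 0.3
    context_rate: float = 0.1
    noise_sd: float = 0.07
    base_eccentricity_up: Optional[float] = None
    base_eccentricity_down: Optional[float] = None

    def __post_init__(self):
        for name in ("amplitude_gain", "hysteresis_weight", "context_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def effective_e0(self, direction: str) -> float:
        if direction == "up" and self.base_eccentricity_up is not None:
            return self.base_eccentricity_up
        if direction == "down" and self.base_eccentricity_down is not None:
            return self.base_eccentricity_down
        return self.base_eccentricity


@dataclass(frozen=True)
class ContextState:
    """Recent task context carried between trials.

    mean_abs_amplitude : running mean of |d| experienced in the block.
    prev_click_eccentricity : |y_prev - 0.5| of the previous click.
    prev_click_y : previous click position.
    """

    mean_abs_amplitude: float
    prev_click_eccentricity: float
    prev_click_y: float = 0.5

    @classmethod
    def initial(cls, params: StrategyParams,
                design_mean_abs_amplitude: float) -> "ContextState":
        """Context at block start: the design's mean |d| as the expected
        demand, and a neutral previous eccentricity of e0."""
        return cls(mean_abs_amplitude=design_mean_abs_amplitude,
                   prev_click_eccentricity=params.base_eccentricity,
                   prev_click_y=0.5)


def _grid(lo: float, hi: float, resolution: float) -> np.ndarray:
    n = int(round((hi - lo) / resolution))
    g = lo + resolution * np.arange(n + 1)
    g[-1] = hi
    return g


def minimal_path_click(start: tuple, requirement: ScrollRequirement,
                       config: TaskConfig, state: LineState = INITIAL_STATE,
                       resolution: float = GRID_RESOLUTION) -> tuple:
    """Click position minimizing the overall cursor trajectory length.

    The trajectory is the straight approach from ``start`` (x, y) to the
    nearest point of the line strip at the chosen height, plus the full
    scroll path cost (drags and return travels). The minimization runs on a
    grid of the given resolution; exact ties are broken toward the click
    closest to the start height, then toward the screen center.

    Returns ``(click_y, total_path_length)``.
    """
    start_x, start_y = start
    strip_lo, strip_hi = config.strip_x_interval()
    gap = max(0.0, max(strip_lo - start_x, start_x - strip_hi))
    d = requirement.displacement
    lo, hi = state.clickable_interval(config)
    ys = _grid(lo, hi, resolution)
    totals = np.empty_like(ys)
    for i, y in enumerate(ys):
        cost, _ = scroll_path_cost(float(y), d, config, state)
        totals[i] = math.hypot(gap, start_y - y) + cost
    best = totals.min()
    tied = ys[totals <= best + 1e-12]
    order = np.lexsort((np.abs(tied - 0.5), np.abs(tied - start_y)))
    click_y = float(tied[order[0]])
    return click_y, float(best)


def target_click(requirement: ScrollRequirement, config: TaskConfig,
                 state: LineState = INITIAL_STATE, start=None) -> float:
    """Center of the target's square if on screen, else the nearest
    on-screen point of the line."""
    y = config.square_center_y(requirement.target_number, state.offset)
    lo, hi = state.clickable_interval(config)
    return float(min(max(y, lo), hi))


@dataclass(frozen=True)
class EdgeBufferPrediction:
    """Point prediction of the border-buffer strategy."""

    click_y: float
    interval: tuple
    predicted_final_y: float
    predicted_final_at_border: bool = True


def edge_buffer_click(requirement: ScrollRequirement, config: TaskConfig,
                      state: LineState = INITIAL_STATE) -> EdgeBufferPrediction:
    """Border-buffer strategy: click anywhere in the one-go interval and
    drag rapidly to the screen border, which stops the cursor exactly when
    the line has moved far enough or beyond-the-target overshoot is
    impossible. The interval midpoint is returned as the point prediction.
    """
    d = requirement.displacement
    if d == 0:
        raise ValueError("edge-buffer strategy undefined for zero displacement")
    interval = one_go_interval(d, config, state)
    if interval is None:
        raise ValueError("no one-go click position exists for this trial")
    lo, hi = interval
    final = 1.0 if d > 0 else 0.0
    return EdgeBufferPrediction(click_y=(lo + hi) / 2.0, interval=interval,
                                predicted_final_y=final)


def heuristic_click(requirement: ScrollRequirement, ctx: ContextState,
                    params: StrategyParams, rng=None) -> float:
    """Two-component heuristic click position.

    The deterministic core is
    ``e* = e0 + k * (|d| - mean_abs_amplitude)`` and
    ``e = (1 - lambda) * e* + lambda * prev_click_eccentricity``;
    the click is ``y = 0.5 - sign(d) * e`` plus Gaussian noise, clipped to
    the screen. Upward scrolls (d > 0) therefore yield low clicks.
    """
    d = requirement.displacement
    if d == 0:
        raise ValueError("heuristic strategy undefined for zero displacement")
    e0 = params.effective_e0(requirement.direction)
    e_star = e0 + params.amplitude_gain * (abs(d) - ctx.mean_abs_amplitude)
    lam = params.hysteresis_weight
    e = (1.0 - lam) * e_star + lam * ctx.prev_click_eccentricity
    y = 0.5 - math.copysign(1.0, d) * e
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        y += rng.normal(0.0, params.noise_sd)
    return float(min(max(y, 0.0), 1.0))


def update_context(ctx: ContextState, requirement: ScrollRequirement,
                   click_y: float, params: StrategyParams) -> ContextState:
    """Advance the context after a trial: exponential smoothing of the mean
    absolute amplitude and carry-over of the click just made."""
    a = params.context_rate
    new_mean = (1.0 - a) * ctx.mean_abs_amplitude + a * abs(requirement.displacement)
    return ContextState(mean_abs_amplitude=new_mean,
                        prev_click_eccentricity=abs(click_y - 0.5),
                        prev_click_y=click_y)


def fit_heuristic_params(table, alpha: float,
                         initial_mean_abs_amplitude: float) -> dict:
    """Recover (e0, k, lambda) of the heuristic from observed clicks by OLS.

    Because the hysteresis component feeds on the *observed* previous click
    eccentricity, the generative model is linear in observables:

        ecc_t = (1-lam)*e0 + (1-lam)*k*(|d_t| - m_t) + lam*ecc_{t-1} + noise

    where ``ecc_t = sign(d_t) * (0.5 - y_t)`` and ``m_t`` is the running
    context mean replayed from the known amplitude sequence with rate
    ``alpha``. A single least-squares fit on all rows therefore identifies
    lambda directly and e0, k after dividing by (1 - lambda).

    Parameters
    ----------
    table : pandas.DataFrame
        Trial-ordered table with columns ``participant``, ``block``,
        ``displacement`` and ``initial_click_y``.
    alpha : float
        Context smoothing rate used during generation (assumed known).
    initial_mean_abs_amplitude : float
        Context mean at each block start.

    Returns
    -------
    dict with keys ``base_eccentricity``, ``amplitude_gain``,
    ``hysteresis_weight`` and ``n_obs``.
    """
    rows_x = []
    rows_y = []
    for (_, _), g in table.groupby(["participant", "block"], sort=False):
        d = g["displacement"].to_numpy(float)
        y = g["initial_click_y"].to_numpy(float)
        sign = np.sign(d)
        ecc = sign * (0.5 - y)
        m = np.empty_like(d)
        cur = initial_mean_abs_amplitude
        for i in range(len(d)):
            m[i] = cur
            cur = (1.0 - alpha) * cur + alpha * abs(d[i])
        # rows 1.. of the block regress on the previous observed eccentricity
        amp_dev = np.abs(d) - m
        X = np.column_stack([np.ones(len(d) - 1), amp_dev[1:], np.abs(y - 0.5)[:-1]])
        rows_x.append(X)
        rows_y.append(ecc[1:])
    X = np.vstack(rows_x)
    Y = np.concatenate(rows_y)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    lam = float(beta[2])
    one_minus = max(1.0 - lam, 1e-9)
    return {
        "base_eccentricity": float(beta[0]) / one_minus,
        "amplitude_gain": float(beta[1]) / one_minus,
        "hysteresis_weight": lam,
        "n_obs": int(len(Y)),
    }
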