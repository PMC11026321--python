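"""Synthetic participants: experimental designs and trial-level event logs.

Two designs are generated:

* ``exp1`` — 9-square number line; 8 blocks; each block crosses target
  number (1, 2, 3, 4, 6, 7, 8, 9) x vertical start position (low, center,
  high) x horizontal start side (left, right) once, in randomized order
  (48 trials per block).
* ``exp2`` — 11-square number line; three inducer-eccentricity block types
  (high: targets 10, 13, 17, 20; medium: 12, 13, 17, 18; low: 13, 14, 16,
  17) in random order per participant; each block holds three subblocks in
  which every (target, start side) pair appears four times in shuffled
  order (32 trials per subblock). Targets 13 and 17 are test trials in all
  block types; the remaining targets are inducers.

Trials are simulated as event logs (click/release with cursor coordinates
and the line offset) driven by a pluggable click-selection strategy plus a
simple motor model: drags aim at the exact completion point (or the screen
border when out of reach), receive Gaussian endpoint noise, and corrective
or substantive re-clicks are appended until the target square sits within
the task tolerance of the screen center. Segment durations are
distance-proportional.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence

import numpy as np

from .task import (
    TaskConfig,
    LineState,
    ScrollRequirement,
    get_config,
    required_displacement,
)
from . import strategies as strat

__all__ = [
    "TrialSpec",
    "Event",
    "TrialLog",
    "MotorParams",
    "ParticipantVariation",
    "EXP2_BLOCK_TARGETS",
    "EXP2_TEST_TARGETS",
    "generate_exp1_design",
    "generate_exp2_design",
    "make_strategy",
    "simulate_trial",
    "generate_dataset",
]

EXP1_TARGETS = (1, 2, 3, 4, 6, 7, 8, 9)
EXP2_BLOCK_TARGETS = {
    "high": (10, 13, 17, 20),
    "medium": (12, 13, 17, 18),
    "low": (13, 14, 16, 17),
}
EXP2_TEST_TARGETS = (13, 17)


@dataclass(frozen=True)
class TrialSpec:
    """Design-level description of one trial."""

    participant: int
    experiment: str
    block: int
    subblock: Optional[int]
    trial_index: int
    target_number: int
    start_vertical: float
    start_side: str
    condition: str = "none"
    eccentricity_condition: str = "none"


@dataclass(frozen=True)
class Event:
    time: float
    kind: str  # "click" | "release"
    cursor_x: float
    cursor_y: float
    line_offset: float


@dataclass(frozen=True)
class TrialLog:
    """Ordered click/release events of one trial; first pair is the start
    square, subsequent pairs are on the line."""

    spec: TrialSpec
    events: tuple
    outcome: str = "success"

    def validate(self, config: Optional[TaskConfig] = None,
                 tol: float = 1e-6) -> None:
        """Check alternation and offset synchrony; raise ValueError naming
        the offending event index."""
        ev = self.events
        if not ev or ev[0].kind != "click" or ev[-1].kind != "release":
            raise ValueError("log must start with a click and end with a release")
        for i, e in enumerate(ev):
            want = "click" if i % 2 == 0 else "release"
            if e.kind != want:
                raise ValueError(f"event {i}: expected {want}, got {e.kind}")
            if i % 2 == 1:
                prev = ev[i - 1]
                on_line = (config is None or
                           abs(prev.cursor_x - 0.5) <= config.line_half_width + tol)
                dy = e.cursor_y - prev.cursor_y if on_line else 0.0
                if abs((e.line_offset - prev.line_offset) - dy) > tol:
                    raise ValueError(
                        f"event {i}: line offset out of sync with drag")
            elif i > 0 and abs(e.line_offset - ev[i - 1].line_offset) > tol:
                raise ValueError(f"event {i}: line offset changed while released")


@dataclass(frozen=True)
class MotorParams:
    """Motor execution model (not part of the task; defaults documented in
    docs/methods.md)."""

    drag_sd: float = 0.02  # endpoint SD of a half-screen (0.5 unit) drag
    max_submovements: int = 20
    base_duration: float = 0.2  # s per segment
    duration_per_unit: float = 1.0  # s per screen height travelled
    start_click_time: float = 0.5  # s from start-square onset to its click
    hold_duration: float = 0.1  # s between a click and its release minimum


@dataclass(frozen=True)
class ParticipantVariation:
    """Between-participant normal deviations of heuristic parameters."""

    base_eccentricity_sd: float = 0.05
    amplitude_gain_sd: float = 0.1


def generate_exp1_design(n_participants: int, seed: int) -> List[TrialSpec]:
    """Full factorial Exp 1 design: 8 blocks x (8 targets x 3 vertical x 2
    horizontal start positions), shuffled independently per block."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    cells = list(itertools.product(EXP1_TARGETS, (-0.4, 0.0, 0.4), ("left", "right")))
    specs: List[TrialSpec] = []
    for p in range(n_participants):
        for block in range(8):
            order = rng.permutation(len(cells))
            for i, idx in enumerate(order):
                target, sv, side = cells[idx]
                specs.append(TrialSpec(
                    participant=p, experiment="exp1", block=block,
                    subblock=None, trial_index=i, target_number=target,
                    start_vertical=sv, start_side=side))
    return specs


def generate_exp2_design(n_participants: int, seed: int) -> List[TrialSpec]:
    """Exp 2 design: three eccentricity block types in random order per
    participant; 3 subblocks x 32 trials (4 targets x 2 sides x 4 reps)."""
    if n_participants < 1:
        raise ValueError("need at least one participant")
    rng = np.random.default_rng(seed)
    block_types = list(EXP2_BLOCK_TARGETS)
    specs: List[TrialSpec] = []
    for p in range(n_participants):
        order = [block_types[i] for i in rng.permutation(3)]
        for block, btype in enumerate(order):
            targets = EXP2_BLOCK_TARGETS[btype]
            for sub in range(3):
                cells = [(t, side) for t in targets for side in ("left", "right")
                         for _ in range(4)]
                perm = rng.permutation(len(cells))
                for i, idx in enumerate(perm):
                    target, side = cells[idx]
                    specs.append(TrialSpec(
                        participant=p, experiment="exp2", block=block,
                        subblock=sub, trial_index=i, target_number=target,
                        start_vertical=0.0, start_side=side,
                        condition=("test" if target in EXP2_TEST_TARGETS
                                   else "inducer"),
                        eccentricity_condition=btype))
    return specs


def _start_position(spec: TrialSpec, config: TaskConfig) -> tuple:
    x = 0.5 + (config.start_offset_horizontal if spec.start_side == "right"
               else -config.start_offset_horizontal)
    return (x, 0.5 + spec.start_vertical)


def make_strategy(name: str, config: TaskConfig,
                  params: Optional[strat.StrategyParams] = None) -> Callable:
    """Build a click-selection callable ``(spec, requirement, start, ctx,
    rng) -> click_y`` by strategy name."""
    if name == "minimal_path":
        cache: dict = {}

        def f(spec, req, start, ctx, rng):
            key = (round(start[0], 9), round(start[1], 9), req.target_number)
            if key not in cache:
                cache[key] = strat.minimal_path_click(start, req, config)[0]
            return cache[key]
    elif name == "target_click":
        def f(spec, req, start, ctx, rng):
            return strat.target_click(req, config)
    elif name == "edge_buffer":
        def f(spec, req, start, ctx, rng):
            return strat.edge_buffer_click(req, config).click_y
    elif name == "heuristic":
        p = params or strat.StrategyParams()

        def f(spec, req, start, ctx, rng):
            return strat.heuristic_click(req, ctx, p, rng)
    else:
        raise ValueError(f"unknown strategy {name!r}; "
                         f"choose from {strat.STRATEGY_NAMES}")
    return f


def simulate_trial(spec: TrialSpec, strategy: Callable, config: TaskConfig,
                   motor: MotorParams, rng,
                   ctx: Optional[strat.ContextState] = None) -> TrialLog:
    """Simulate one trial into an event log.

    Time 0 is start-square onset. The start square is clicked and released
    first (its release marks target onset). The strategy supplies the first
    click position on the line; drags aim at the exact completion point or
    the screen border, with Gaussian endpoint noise truncated at the
    borders. If the target ends outside the task tolerance, further
    submovements are appended: corrective re-clicks (residual < 0.1) go to
    the on-line point nearest the screen center, substantive ones to the
    nearest point with sufficient drag capacity.
    """
    d = required_displacement(spec.target_number, config)
    req = ScrollRequirement(spec.target_number, d)
    start_x, start_y = _start_position(spec, config)

    events = []
    t = motor.start_click_time
    events.append(Event(t, "click", start_x, start_y, 0.0))
    t += motor.hold_duration
    events.append(Event(t, "release", start_x, start_y, 0.0))

    click_y = strategy(spec, req, (start_x, start_y), ctx, rng)
    if not 0.0 <= click_y <= 1.0:
        raise ValueError(f"strategy produced off-screen click {click_y}")
    click_x = 0.5 + math.copysign(config.line_half_width, start_x - 0.5)

    offset = 0.0
    cursor = (start_x, start_y)
    y = click_y
    for sub in range(motor.max_submovements):
        # approach / reposition, then click
        dist = math.hypot(click_x - cursor[0], y - cursor[1])
        t += motor.base_duration + motor.duration_per_unit * dist
        events.append(Event(t, "click", click_x, y, offset))
        # drag toward completion, stopping at the border, with endpoint noise
        residual = d - offset
        intended = min(max(y + residual, 0.0), 1.0)
        actual = intended
        if motor.drag_sd > 0:
            # signal-dependent endpoint noise: SD proportional to drag
            # length, calibrated to drag_sd for a half-screen drag
            sd = motor.drag_sd * abs(intended - y) / 0.5
            if sd > 0:
                actual = min(max(intended + rng.normal(0.0, sd), 0.0), 1.0)
        offset += actual - y
        t += motor.base_duration + motor.duration_per_unit * abs(actual - y)
        events.append(Event(t, "release", click_x, actual, offset))
        cursor = (click_x, actual)
        residual = d - offset
        if abs(residual) <= config.target_tolerance:
            return TrialLog(spec=spec, events=tuple(events))
        # plan the next submovement
        lo, hi = LineState(offset).clickable_interval(config)
        if abs(residual) < 0.1:
            y = min(max(0.5, lo), hi)
        elif residual < 0:
            y = min(max(-residual, lo), hi)
        else:
            y = max(min(1.0 - residual, hi), lo)
    raise RuntimeError(
        f"trial did not complete within {motor.max_submovements} submovements")


def _jittered_params(base: strat.StrategyParams,
                     variation: Optional[ParticipantVariation],
                     rng) -> strat.StrategyParams:
    if variation is None:
        return base
    e0 = base.base_eccentricity + rng.normal(0.0, variation.base_eccentricity_sd)
    k = base.amplitude_gain + rng.normal(0.0, variation.amplitude_gain_sd)
    return replace(base, base_eccentricity=float(np.clip(e0, 0.0, 0.5)),
                   amplitude_gain=float(np.clip(k, 0.0, 1.0)))


def generate_dataset(design: Sequence[TrialSpec], strategy_name: str,
                     seed: int,
                     params: Optional[strat.StrategyParams] = None,
                     motor: Optional[MotorParams] = None,
                     variation: Optional[ParticipantVariation] = None,
                     config: Optional[TaskConfig] = None) -> tuple:
    """Simulate a whole design into trial logs.

    Deterministic given ``seed``. For the heuristic strategy an optional
    between-participant jitter of e0 and k can be applied, and the context
    state (running mean amplitude, previous click) is threaded through each
    block and reset at block boundaries.

    Returns ``(logs, manifest)`` where the manifest records seed, strategy
    and parameters.
    """
    if not design:
        return [], {}
    experiment = design[0].experiment
    config = config or get_config(experiment)
    motor = motor or MotorParams()
    base_params = params or strat.StrategyParams()
    rng = np.random.default_rng(seed)

    logs: List[TrialLog] = []
    by_participant: dict = {}
    for s in design:
        by_participant.setdefault(s.participant, []).append(s)

    for p, trials in by_participant.items():
        p_params = (_jittered_params(base_params, variation, rng)
                    if strategy_name == "heuristic" else base_params)
        strategy = make_strategy(strategy_name, config, p_params)
        # group by block to thread and reset context
        blocks: dict = {}
        for s in trials:
            blocks.setdefault(s.block, []).append(s)
        for block in sorted(blocks):
            block_trials = blocks[block]
            mean_abs = float(np.mean([
                abs(required_displacement(s.target_number, config))
                for s in block_trials]))
            ctx = strat.ContextState.initial(p_params, mean_abs)
            for s in block_trials:
                log = simulate_trial(s, strategy, config, motor, rng, ctx)
                logs.append(log)
                req = ScrollRequirement.for_target(s.target_number, config)
                first_line_click = log.events[2].cursor_y
                ctx = strat.update_context(ctx, req, first_line_click, p_params)

    manifest = {
        "experiment": experiment,
        "seed": int(seed),
        "strategy": strategy_name,
        "n_participants": len(by_participant),
        "n_trials": len(logs),
        "strategy_params": {
            "base_eccentricity": base_params.base_eccentricity,
            "amplitude_gain": base_params.amplitude_gain,
            "hysteresis_weight": base_params.hysteresis_weight,
            "context_rate": base_params.context_rate,
            "noise_sd": base_params.noise_sd,
        },
        "motor": {
            "drag_sd": motor.drag_sd,
            "base_duration": motor.base_duration,
            "duration_per_unit": motor.duration_per_unit,
        },
        "participant_variation": None if variation is None else {
            "base_eccentricity_sd": variation.base_eccentricity_sd,
            "amplitude_gain_sd": variation.amplitude_gain_sd,
        },
    }
    return logs, manifest
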