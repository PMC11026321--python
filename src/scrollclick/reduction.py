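"""Reduce trial event logs to per-trial dependent variables.

Per trial: the initial vertical click position on the line (the central
dependent variable), the final vertical cursor position at the last
release, the number of submovements (click/release pairs on the line), and
the response time from target onset to the final release. Trials whose
total duration from start-square onset exceeds 10 s are flagged excluded
(strict inequality, as is the 0.1-unit threshold separating corrective
from substantive submovements).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .task import TaskConfig, get_config, required_displacement
from .synthetic import TrialLog, TrialSpec

__all__ = [
    "SubmovementLabel",
    "TrialSummary",
    "reduce_trial",
    "classify_submovements",
    "summaries_to_frame",
    "summarize_conditions",
    "EXCLUSION_SECONDS",
    "CORRECTIVE_THRESHOLD",
]

EXCLUSION_SECONDS = 10.0
CORRECTIVE_THRESHOLD = 0.1


@dataclass(frozen=True)
class SubmovementLabel:
    kind: str  # "corrective" | "substantive"
    negligible_reposition: bool = False


@dataclass(frozen=True)
class TrialSummary:
    spec: TrialSpec
    initial_click_y: float
    final_cursor_y: float
    n_submovements: int
    response_time: float
    trial_duration: float
    excluded: bool
    submovement_labels: tuple = ()


def _line_pairs(log: TrialLog, config: TaskConfig):
    """Yield (click_event, release_event) pairs that occurred on the line."""
    ev = log.events
    for i in range(0, len(ev) - 1, 2):
        c, r = ev[i], ev[i + 1]
        if c.kind != "click" or r.kind != "release":
            raise ValueError(f"event {i}: non-alternating click/release events")
        if abs(c.cursor_x - 0.5) <= config.line_half_width + 1e-9:
            yield i, c, r


def reduce_trial(log: TrialLog, config: Optional[TaskConfig] = None) -> TrialSummary:
    """Reduce one event log to a TrialSummary.

    The first event pair off the line strip is the start square; its
    release stamps target onset. Raises ValueError for malformed logs,
    naming the offending event index.
    """
    config = config or get_config(log.spec.experiment)
    ev = log.events
    if len(ev) < 2 or len(ev) % 2 != 0:
        raise ValueError("log must consist of complete click/release pairs")
    pairs = list(_line_pairs(log, config))
    if not pairs:
        raise ValueError("no click/release pair on the line")
    # target onset: release of the last event pair before the first line pair
    first_line_idx = pairs[0][0]
    target_onset = ev[first_line_idx - 1].time if first_line_idx >= 2 else 0.0
    duration = ev[-1].time  # start-square onset is time 0
    labels = classify_submovements(log, config)
    return TrialSummary(
        spec=log.spec,
        initial_click_y=pairs[0][1].cursor_y,
        final_cursor_y=pairs[-1][2].cursor_y,
        n_submovements=len(pairs),
        response_time=ev[-1].time - target_onset,
        trial_duration=duration,
        excluded=duration > EXCLUSION_SECONDS,
        submovement_labels=tuple(labels),
    )


def classify_submovements(log: TrialLog,
                          config: Optional[TaskConfig] = None) -> List[SubmovementLabel]:
    """Label each line submovement.

    A submovement is corrective when, at its click, the residual line
    displacement to perfect alignment is below 0.1 units, substantive
    otherwise. Substantive submovements whose cursor repositioning since
    the previous release is below 0.1 units are additionally flagged as
    negligible repositions.
    """
    config = config or get_config(log.spec.experiment)
    d = required_displacement(log.spec.target_number, config)
    labels = []
    ev = log.events
    for i, c, r in _line_pairs(log, config):
        residual = abs(d - c.line_offset)
        if residual < CORRECTIVE_THRESHOLD:
            labels.append(SubmovementLabel("corrective"))
        else:
            reposition = math.inf
            if i >= 1:
                prev_rel = ev[i - 1]
                reposition = math.hypot(c.cursor_x - prev_rel.cursor_x,
                                        c.cursor_y - prev_rel.cursor_y)
            labels.append(SubmovementLabel(
                "substantive",
                negligible_reposition=reposition < CORRECTIVE_THRESHOLD))
    return labels


def summaries_to_frame(summaries: Sequence[TrialSummary]) -> pd.DataFrame:
    """Flatten summaries into a tidy trial table (one row per trial)."""
    rows = []
    configs = {}
    for s in summaries:
        sp = s.spec
        if sp.experiment not in configs:
            configs[sp.experiment] = get_config(sp.experiment)
        d = required_displacement(sp.target_number, configs[sp.experiment])
        rows.append({
            "participant": sp.participant,
            "experiment": sp.experiment,
            "block": sp.block,
            "subblock": sp.subblock,
            "trial_index": sp.trial_index,
            "target_number": sp.target_number,
            "start_vertical": sp.start_vertical,
            "start_side": sp.start_side,
            "displacement": d,
            "condition": sp.condition,
            "eccentricity_condition": sp.eccentricity_condition,
            "initial_click_y": s.initial_click_y,
            "final_cursor_y": s.final_cursor_y,
            "n_submovements": s.n_submovements,
            "response_time": s.response_time,
            "trial_duration": s.trial_duration,
            "excluded": s.excluded,
        })
    return pd.DataFrame(rows)


def summarize_conditions(summaries, grouping: Sequence[str],
                         dvs: Sequence[str] = ("initial_click_y",
                                               "final_cursor_y",
                                               "n_submovements",
                                               "response_time")) -> pd.DataFrame:
    """Per participant x condition cell means of the dependent variables
    over non-excluded trials, with cell counts.

    Raises ValueError listing any participant x cell combination that has
    no non-excluded trial (missing cells are reported, never dropped
    silently).
    """
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_to_frame(summaries)
    keep = df.loc[~df["excluded"]]
    keys = ["participant", *grouping]
    agg = keep.groupby(keys, sort=True)[list(dvs)].mean().reset_index()
    counts = keep.groupby(keys, sort=True).size().rename("n_trials").reset_index()
    out = agg.merge(counts, on=keys)

    participants = sorted(df["participant"].unique())
    level_sets = [sorted(df[g].dropna().unique()) for g in grouping]
    expected = {(p, *cell) for p in participants
                for cell in itertools.product(*level_sets)}
    present = {tuple(row) for row in out[keys].itertuples(index=False)}
    missing = sorted(expected - present)
    if missing:
        raise ValueError(
            f"missing condition cells (participant, {', '.join(grouping)}): "
            f"{missing[:20]}{' ...' if len(missing) > 20 else ''}")
    return out
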