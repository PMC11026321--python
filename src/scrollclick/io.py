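"""File formats: trial-log CSV, run configuration, manifests.

The trial-log dialect has one row per click/release event::

    participant,experiment,block,subblock,trial_index,target_number,
    start_vertical,start_side,condition,eccentricity_condition,
    event_index,event_kind,time_s,cursor_x,cursor_y,line_offset

Header required; UTF-8; "." decimal separator. Floats are written with
repr-style shortest round-trip formatting so that write -> read -> write
is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import yaml

from .synthetic import Event, TrialLog, TrialSpec

__all__ = [
    "TRIAL_LOG_COLUMNS",
    "write_trial_logs",
    "read_trial_logs",
    "write_manifest",
    "RunConfig",
    "load_run_config",
]

TRIAL_LOG_COLUMNS = (
    "participant", "experiment", "block", "subblock", "trial_index",
    "target_number", "start_vertical", "start_side", "condition",
    "eccentricity_condition", "event_index", "event_kind", "time_s",
    "cursor_x", "cursor_y", "line_offset",
)


def _fmt(x: float) -> str:
    return repr(float(x))


def write_trial_logs(logs: Sequence[TrialLog], path) -> None:
    """Write trial logs to the documented CSV dialect."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(TRIAL_LOG_COLUMNS) + "\n")
        for log in logs:
            s = log.spec
            sub = "" if s.subblock is None else str(s.subblock)
            prefix = (f"{s.participant},{s.experiment},{s.block},{sub},"
                      f"{s.trial_index},{s.target_number},"
                      f"{_fmt(s.start_vertical)},{s.start_side},"
                      f"{s.condition},{s.eccentricity_condition}")
            for i, e in enumerate(log.events):
                fh.write(f"{prefix},{i},{e.kind},{_fmt(e.time)},"
                         f"{_fmt(e.cursor_x)},{_fmt(e.cursor_y)},"
                         f"{_fmt(e.line_offset)}\n")


class TrialLogFormatError(ValueError):
    """Schema violation in a trial-log file, with row context."""


def read_trial_logs(path, validate: bool = True) -> List[TrialLog]:
    """Read trial logs written by :func:`write_trial_logs`.

    Validates the event-alternation and offset-synchrony invariants of
    every trial on load; schema violations raise
    :class:`TrialLogFormatError` naming the row.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if header.split(",") != list(TRIAL_LOG_COLUMNS):
            raise TrialLogFormatError(f"{path}: unexpected header {header!r}")
        trials: Dict[tuple, list] = {}
        order: List[tuple] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(TRIAL_LOG_COLUMNS):
                raise TrialLogFormatError(
                    f"{path}:{lineno}: expected {len(TRIAL_LOG_COLUMNS)} "
                    f"columns, found {len(parts)}")
            row = dict(zip(TRIAL_LOG_COLUMNS, parts))
            try:
                key = (int(row["participant"]), row["experiment"],
                       int(row["block"]),
                       None if row["subblock"] == "" else int(row["subblock"]),
                       int(row["trial_index"]))
                event = Event(time=float(row["time_s"]),
                              kind=row["event_kind"],
                              cursor_x=float(row["cursor_x"]),
                              cursor_y=float(row["cursor_y"]),
                              line_offset=float(row["line_offset"]))
                if event.kind not in ("click", "release"):
                    raise ValueError(f"bad event kind {event.kind!r}")
                spec = TrialSpec(
                    participant=key[0], experiment=key[1], block=key[2],
                    subblock=key[3], trial_index=key[4],
                    target_number=int(row["target_number"]),
                    start_vertical=float(row["start_vertical"]),
                    start_side=row["start_side"],
                    condition=row["condition"],
                    eccentricity_condition=row["eccentricity_condition"])
            except ValueError as exc:
                raise TrialLogFormatError(f"{path}:{lineno}: {exc}") from None
            if key not in trials:
                trials[key] = [spec, []]
                order.append(key)
            trials[key][1].append((int(row["event_index"]), lineno, event))
    logs = []
    for key in order:
        spec, events = trials[key]
        events.sort(key=lambda t: t[0])
        for j, (idx, lineno, ev) in enumerate(events):
            want = "click" if j % 2 == 0 else "release"
            if ev.kind != want:
                raise TrialLogFormatError(
                    f"{path}:{lineno}: event {idx} of trial {key}: "
                    f"expected {want}, got {ev.kind}")
        log = TrialLog(spec=spec, events=tuple(e for _, _, e in events))
        if validate:
            try:
                log.validate()
            except ValueError as exc:
                raise TrialLogFormatError(f"{path}: trial {key}: {exc}") from None
        logs.append(log)
    return logs


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA = {
    "experiment": {"exp1", "exp2"},
    "seed": None,
    "n_participants": None,
    "output_dir": None,
    "strategy": {"name", "base_eccentricity", "amplitude_gain",
                 "hysteresis_weight", "context_rate", "noise_sd",
                 "base_eccentricity_up", "base_eccentricity_down"},
    "motor": {"drag_sd", "max_submovements", "base_duration",
              "duration_per_unit", "start_click_time", "hold_duration"},
    "analysis": {"alpha", "grouping", "dv"},
    "power": {"n_participants", "noise_sd", "effect_size", "n_reps", "alpha"},
    "variation": {"base_eccentricity_sd", "amplitude_gain_sd"},
}


class RunConfig(dict):
    """Validated pipeline configuration (a thin dict wrapper)."""

    @property
    def experiment(self) -> str:
        return self["experiment"]

    @property
    def seed(self) -> int:
        return self["seed"]


def load_run_config(source) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``source`` may be a path or an already-parsed mapping. Unknown keys are
    rejected before any computation; ``seed`` and ``experiment`` are
    mandatory.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = source
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(raw) - set(_CONFIG_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, sub in _CONFIG_SCHEMA.items():
        if isinstance(sub, set) and key in raw and isinstance(raw[key], dict):
            if key == "experiment":
                continue
            bad = set(raw[key]) - sub
            if bad:
                raise ValueError(f"unknown keys under {key!r}: {sorted(bad)}")
    if "experiment" in raw and raw["experiment"] not in ("exp1", "exp2"):
        raise ValueError(f"experiment must be exp1 or exp2, "
                         f"got {raw.get('experiment')!r}")
    if "seed" not in raw:
        raise ValueError("config must set a seed (stochastic run)")
    if "experiment" not in raw:
        raise ValueError("config must name an experiment preset")
    return RunConfig(raw)
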