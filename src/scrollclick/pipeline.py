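"""End-to-end pipeline: simulate -> reduce -> ANOVA/contrasts -> mixed model.

All randomness flows from the single configured seed through per-stage
child streams derived deterministically from the stage name, so adding a
stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import logging
import time
import zlib
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from . import io as sio
from . import synthetic, reduction, stats
from .strategies import StrategyParams
from .synthetic import MotorParams, ParticipantVariation

__all__ = ["stage_seed", "run_pipeline"]

log = logging.getLogger("scrollclick")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic child seed for a named pipeline stage (< 2**31)."""
    return (int(master_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


def _strategy_params(cfg: dict) -> StrategyParams:
    block = dict(cfg.get("strategy", {}))
    block.pop("name", None)
    return StrategyParams(**block)


def run_pipeline(config, output_dir=None) -> Dict[str, object]:
    """Execute the full pipeline described by a run config.

    Writes the trial-log CSV, trial-summary CSV, ANOVA/contrast/LMM CSVs
    and a run manifest into ``output_dir``; idempotent for a fixed seed.
    Returns the in-memory artifacts keyed by stage name. Any stage failure
    is re-raised annotated with the stage name.
    """
    cfg = sio.load_run_config(config)
    out = Path(output_dir or cfg.get("output_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    experiment = cfg.experiment
    seed = cfg.seed
    artifacts: Dict[str, object] = {}
    strategy_name = cfg.get("strategy", {}).get("name", "heuristic")
    n = int(cfg.get("n_participants", 4))

    def run_stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        return result

    # -- simulate ----------------------------------------------------------
    def _simulate():
        design_seed = stage_seed(seed, "design")
        if experiment == "exp1":
            design = synthetic.generate_exp1_design(n, design_seed)
        else:
            design = synthetic.generate_exp2_design(n, design_seed)
        variation = None
        if "variation" in cfg:
            variation = ParticipantVariation(**cfg["variation"])
        logs, manifest = synthetic.generate_dataset(
            design, strategy_name, stage_seed(seed, "simulate"),
            params=_strategy_params(cfg),
            motor=MotorParams(**cfg.get("motor", {})),
            variation=variation)
        sio.write_trial_logs(logs, out / "trial_logs.csv")
        manifest["master_seed"] = int(seed)
        sio.write_manifest(manifest, out / "manifest.json")
        return logs

    logs = run_stage("simulate", _simulate)
    artifacts["logs"] = logs

    # -- reduce ------------------------------------------------------------
    def _reduce():
        summaries = [reduction.reduce_trial(l) for l in logs]
        frame = reduction.summaries_to_frame(summaries)
        frame.to_csv(out / "trial_summaries.csv", index=False)
        return frame

    frame = run_stage("reduce", _reduce)
    artifacts["summaries"] = frame

    # -- anova + contrasts -------------------------------------------------
    def _anova():
        dv = cfg.get("analysis", {}).get("dv", "initial_click_y")
        if experiment == "exp1":
            grouping = cfg.get("analysis", {}).get(
                "grouping", ["start_vertical", "target_number"])
        else:
            grouping = cfg.get("analysis", {}).get(
                "grouping", ["eccentricity_condition", "target_number"])
        cells = reduction.summarize_conditions(frame, grouping, dvs=[dv])
        effects = stats.rm_anova_gg(cells, grouping, dv=dv)
        eff_df = pd.DataFrame([vars(e) for e in effects])
        eff_df.to_csv(out / "anova.csv", index=False)
        contrasts = stats.consecutive_contrasts(cells, grouping[-1], dv=dv)
        con_df = pd.DataFrame([{**vars(c), "pair": f"{c.pair[0]}|{c.pair[1]}"}
                               for c in contrasts])
        con_df.to_csv(out / "contrasts.csv", index=False)
        return effects, contrasts

    artifacts["anova"], artifacts["contrasts"] = run_stage("anova", _anova)

    # -- hysteresis mixed model -------------------------------------------
    def _lmm():
        table = stats.build_hysteresis_predictors(frame, experiment)
        result = stats.fit_mixed_model(table)
        rows = [vars(fe) for fe in result.fixed]
        df = pd.DataFrame(rows)
        df["r2_marginal"] = result.r2_marginal
        df["r2_conditional"] = result.r2_conditional
        df.to_csv(out / "lmm.csv", index=False)
        (out / "lmm.txt").write_text(result.summary() + "\n", encoding="utf-8")
        return result

    artifacts["lmm"] = run_stage("lmm", _lmm)
    return artifacts
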