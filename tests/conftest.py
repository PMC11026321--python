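import numpy as np
import pytest

import scrollclick as sc
from scrollclick.strategies import StrategyParams
from scrollclick.synthetic import MotorParams


@pytest.fixture(scope="session")
def exp1_small_heuristic():
    """Three heuristic participants on the full Exp 1 design."""
    design = sc.generate_exp1_design(3, seed=11)
    logs, manifest = sc.generate_dataset(design, "heuristic", seed=42)
    return design, logs, manifest


@pytest.fixture(scope="session")
def exp1_small_frame(exp1_small_heuristic):
    _, logs, _ = exp1_small_heuristic
    summaries = [sc.reduce_trial(log) for log in logs]
    return sc.summaries_to_frame(summaries)


@pytest.fixture(scope="session")
def exp1_noiseless_minimal():
    """One noiseless minimal-path participant: fully deterministic logs."""
    design = sc.generate_exp1_design(1, seed=3)
    logs, _ = sc.generate_dataset(
        design, "minimal_path", seed=1,
        params=StrategyParams(noise_sd=0.0),
        motor=MotorParams(drag_sd=0.0))
    return design, logs
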