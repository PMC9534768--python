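import warnings

import numpy as np
import pandas as pd
import pytest

from revgen.io_core import LayoutSpec
from revgen.synthetic import AgentConfig, TaskConfig, simulate_session


@pytest.fixture(scope="session")
def standard_layouts() -> list[LayoutSpec]:
    return [LayoutSpec(1, 1, 3, 5, 1),
            LayoutSpec(2, 7, 3, 2, 2),
            LayoutSpec(3, 1, 3, 7, 3)]


@pytest.fixture(scope="session")
def small_session():
    """One small problem-general session reused by read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_session(
            task=TaskConfig(layout_sequence=(1, 2, 3)),
            agent=AgentConfig(),
            n_neurons=8, profile="pfc_like", seed=42,
            session_id="fix0", with_tracking=True,
        )


def perfect_trials(n_per_block: int = 30, n_blocks: int = 2) -> pd.DataFrame:
    """Hand-built trial table of an always-correct agent (free trials)."""
    rows = []
    t = 0.0
    idx = 0
    for b in range(n_blocks):
        good = "A" if b % 2 == 0 else "B"
        for _ in range(n_per_block):
            rows.append({
                "trial_index": idx, "problem_index": 1, "block_index": b,
                "good_side": good, "forced": False, "forced_side": "",
                "choice": good, "outcome": "reward",
                "initiation_time": t, "choice_time": t + 0.5,
                "outcome_time": t + 0.75,
            })
            t += 4.0
            idx += 1
    return pd.DataFrame(rows)
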