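import json

import numpy as np
import pandas as pd
import pytest

from revgen.behavior import performance_metrics
from revgen.synthetic import (
    AgentConfig,
    PopulationConfig,
    SimulationError,
    TaskConfig,
    generate_population,
    generate_spikes,
    simulate_behavior,
)
from conftest import perfect_trials


def test_task_config_invariants():
    with pytest.raises(ValueError):
        TaskConfig(reward_probs=(0.2, 0.8))
    with pytest.raises(ValueError):
        TaskConfig(reversal_delay_range=(10, 5))


def test_ema_crossing_closed_form():
    """A perfect agent crosses the 75% EMA threshold exactly on trial 6:
    1 - 0.5(1-alpha)^n >= 0.75 with alpha = 1 - e^(-1/8) first holds at n=6."""
    trials = perfect_trials(n_per_block=30, n_blocks=3)
    blocks, _ = performance_metrics(trials, pd.DataFrame(columns=["time", "port", "event"]))
    assert (blocks["trials_to_threshold"] == 6).all()


def test_no_forced_trials_when_fraction_zero():
    trials, _, _ = simulate_behavior(
        TaskConfig(forced_fraction=0.0), AgentConfig(), seed=0)
    assert not trials["forced"].any()


def test_same_seed_identical_output():
    a, pa, _ = simulate_behavior(TaskConfig(), AgentConfig(), seed=5)
    b, pb, _ = simulate_behavior(TaskConfig(), AgentConfig(), seed=5)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(pa, pb)


def test_reversals_respect_threshold_and_delay():
    """No block ends before the EMA crossing plus the minimum delay."""
    task = TaskConfig()
    trials, _, _ = simulate_behavior(task, AgentConfig(), seed=3)
    blocks, _ = performance_metrics(trials, pd.DataFrame(columns=["time", "port", "event"]))
    # every completed block must have crossed threshold
    assert blocks["trials_to_threshold"].notna().all()
    lo = task.reversal_delay_range[0]
    assert (blocks["n_trials"] >= blocks["trials_to_threshold"] + lo).all()


def test_trial_cap_raises():
    # an agent glued to B never tracks a reversal to A, so some block stalls
    stuck = AgentConfig(w_interaction=np.zeros(12),
                        w_choice=np.zeros(12), bias=-50.0)
    with pytest.raises(SimulationError, match="500"):
        simulate_behavior(TaskConfig(max_trials=500, forced_fraction=0.0),
                          stuck, seed=0)


def test_pfc_like_tuning_shared_across_problems():
    pop = generate_population(20, "pfc_like", seed=0)
    for tj in pop["tuning"]:
        t = json.loads(tj)
        assert t["remap_gain"][0] == t["remap_gain"][1] == t["remap_gain"][2]
        assert t["policy_gain"][0] == t["policy_gain"][1] == t["policy_gain"][2]


def test_ca1_like_remap_gains_independent_across_problems():
    pop = generate_population(800, "ca1_like", seed=1)
    g1, g2 = [], []
    for tj in pop["tuning"]:
        t = json.loads(tj)
        g1.append(np.log(t["remap_gain"][0]["3"]))
        g2.append(np.log(t["remap_gain"][1]["3"]))
    r = np.corrcoef(g1, g2)[0, 1]
    assert abs(r) < 0.1


def test_single_neuron_and_unknown_profile():
    assert len(generate_population(1, "pfc_like", seed=0)) == 1
    with pytest.raises(ValueError, match="profile"):
        generate_population(3, "cortex", seed=0)


def _flat_population(rate_hz: float, n: int = 1) -> pd.DataFrame:
    cfg = PopulationConfig(
        baseline_log_mean=np.log(rate_hz) if rate_hz > 0 else -np.inf,
        baseline_log_sd=0.0, port_gain_sd=0.0, remap_gain_sd=0.0,
        n_kernels_range=(0, 0), outcome_gain_sd=0.0, policy_gain_sd=0.0)
    pop = generate_population(n, cfg, seed=0)
    if rate_hz == 0:
        fixed = []
        for tj in pop["tuning"]:
            t = json.loads(tj)
            t["baseline"] = 0.0
            fixed.append(json.dumps(t))
        pop["tuning"] = fixed
    return pop


def test_homogeneous_poisson_counts():
    """With all gains off, spike counts follow Poisson(baseline x duration)."""
    trials = perfect_trials(n_per_block=40, n_blocks=2)
    trials["policy_true"] = 0.5
    layouts = [type("L", (), {})]
    from revgen.io_core import LayoutSpec
    layouts = [LayoutSpec(1, 1, 3, 5, 1)]
    pop = _flat_population(5.0)
    spikes = generate_spikes(trials, layouts, pop, seed=0)
    duration = trials["outcome_time"].iloc[-1] + 3.0
    expected = 5.0 * duration
    assert abs(len(spikes) - expected) < 4 * np.sqrt(expected)
    # dispersion index ~ 1 in 10-s windows
    counts, _ = np.histogram(spikes["spike_time"], bins=np.arange(0, duration, 10.0))
    disp = counts.var(ddof=1) / counts.mean()
    assert 0.7 < disp < 1.4


def test_zero_rate_neuron_silent():
    trials = perfect_trials(n_per_block=10, n_blocks=1)
    trials["policy_true"] = 0.5
    from revgen.io_core import LayoutSpec
    spikes = generate_spikes(trials, [LayoutSpec(1, 1, 3, 5, 1)],
                             _flat_population(0.0), seed=0)
    assert len(spikes) == 0


def test_event_kernel_psth_peaks_at_center():
    """A single choice-anchored kernel produces a PSTH peak at its center."""
    trials = perfect_trials(n_per_block=60, n_blocks=2)
    trials["policy_true"] = 0.5
    from revgen.io_core import LayoutSpec
    pop = _flat_population(1.0)
    t = json.loads(pop.loc[0, "tuning"])
    t["kernels"] = [{"anchor": "choice", "center": 0.12, "width": 0.05,
                     "amp": 40.0}]
    pop.loc[0, "tuning"] = json.dumps(t)
    spikes = generate_spikes(trials, [LayoutSpec(1, 1, 3, 5, 1)], pop, seed=2)
    rel = []
    st = spikes["spike_time"].to_numpy()
    for ct in trials["choice_time"]:
        rel.extend(st[(st > ct - 0.4) & (st < ct + 0.6)] - ct)
    hist, edges = np.histogram(rel, bins=np.arange(-0.4, 0.6, 0.04))
    peak = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    assert abs(peak - 0.12) < 0.05
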