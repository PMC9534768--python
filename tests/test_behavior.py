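import warnings

import numpy as np
import pandas as pd
import pytest

from revgen.behavior import (
    FitError,
    HistoryWeights,
    estimate_policy,
    fit_choice_history,
    fit_learning_curve,
    performance_metrics,
)
from revgen.io_core import LayoutSpec
from revgen.synthetic import AgentConfig, TaskConfig, simulate_behavior


def _trials_from_sequences(choices, outcomes) -> pd.DataFrame:
    n = len(choices)
    t = np.arange(n) * 4.0
    return pd.DataFrame({
        "trial_index": np.arange(n), "problem_index": 1, "block_index": 0,
        "good_side": "A", "forced": False, "forced_side": "",
        "choice": choices, "outcome": outcomes,
        "initiation_time": t, "choice_time": t + 0.5, "outcome_time": t + 0.75,
    })


def test_win_stay_lose_shift_fit():
    """A WSLS agent loads only the lag-1 choice x outcome interaction."""
    rng = np.random.default_rng(0)
    choices, outcomes = ["A"], ["reward"]
    for _ in range(3000):
        prev_c = 1 if choices[-1] == "A" else -1
        prev_o = 1 if outcomes[-1] == "reward" else -1
        stay = prev_c * prev_o       # +1 -> choose A after win on A etc.
        p_a = 0.95 if stay > 0 else 0.05
        choices.append("A" if rng.random() < p_a else "B")
        outcomes.append("reward" if rng.random() < 0.5 else "omission")
    w = fit_choice_history(_trials_from_sequences(choices, outcomes), n_lags=3)
    assert w.w_interaction[0] > 1.5
    others = np.concatenate([w.w_choice, w.w_outcome, w.w_interaction[1:]])
    assert np.all(np.abs(others) < 0.4)


def test_null_choices_give_near_zero_coefficients():
    rng = np.random.default_rng(1)
    n = 4000
    choices = np.where(rng.random(n) < 0.5, "A", "B")
    outcomes = np.where(rng.random(n) < 0.5, "reward", "omission")
    w = fit_choice_history(_trials_from_sequences(choices, outcomes), n_lags=3)
    assert np.all(np.abs(w.flat) < 0.15)


def test_generative_weight_recovery():
    agent = AgentConfig()
    task = TaskConfig(forced_fraction=0.0, blocks_per_problem=40,
                      problems_per_session=3, max_trials=20_000)
    trials, _, _ = simulate_behavior(task, agent, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = fit_choice_history(trials, n_lags=12)
    gen = np.concatenate([agent.w_choice, agent.w_outcome, agent.w_interaction])
    est = np.concatenate([w.w_choice, w.w_outcome, w.w_interaction])
    assert np.corrcoef(gen, est)[0, 1] > 0.9


def test_relabel_invariance():
    """Swapping A and B flips all signs consistently."""
    task = TaskConfig(forced_fraction=0.0, blocks_per_problem=10)
    trials, _, _ = simulate_behavior(task, AgentConfig(), seed=2)
    swapped = trials.copy()
    swapped["choice"] = np.where(trials["choice"] == "A", "B", "A")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w1 = fit_choice_history(trials, n_lags=4)
        w2 = fit_choice_history(swapped, n_lags=4)
# only the choice labels flip: the choice regressor and the interaction
    # regressor both change sign, so their coefficients are invariant, while
    # the outcome coefficient and intercept flip
    np.testing.assert_allclose(w1.w_choice, w2.w_choice, atol=1e-4)
    np.testing.assert_allclose(w1.w_outcome, -w2.w_outcome, atol=1e-4)
    np.testing.assert_allclose(w1.w_interaction, w2.w_interaction, atol=1e-4)
    np.testing.assert_allclose(w1.intercept, -w2.intercept, atol=1e-4)


def test_policy_zero_weights_is_half():
    trials = _trials_from_sequences(["A", "B", "A", "B", "A"],
                                    ["reward"] * 5)
    w = HistoryWeights(n_lags=2, intercept=0.0, w_choice=np.zeros(2),
                       w_outcome=np.zeros(2), w_interaction=np.zeros(2),
                       log_likelihood=0.0, n_trials=5)
    pol = estimate_policy(trials, w)
    assert np.all(np.isnan(pol.p_choose_a[:2]))
    np.testing.assert_allclose(pol.p_choose_a[2:], 0.5)


def test_policy_saturates_with_large_choice_weight():
    trials = _trials_from_sequences(["A", "A", "B"], ["reward"] * 3)
    w = HistoryWeights(n_lags=1, intercept=0.0, w_choice=np.array([40.0]),
                       w_outcome=np.zeros(1), w_interaction=np.zeros(1),
                       log_likelihood=0.0, n_trials=3)
    pol = estimate_policy(trials, w)
    assert pol.p_choose_a[1] > 0.999999     # after an A choice
    assert pol.p_choose_a[2] > 0.999999


def test_policy_hand_computed():
    trials = _trials_from_sequences(["A", "B", "A"],
                                    ["reward", "omission", "reward"])
    w = HistoryWeights(n_lags=1, intercept=0.3, w_choice=np.array([0.7]),
                       w_outcome=np.zeros(1), w_interaction=np.zeros(1),
                       log_likelihood=0.0, n_trials=3)
    pol = estimate_policy(trials, w)
    # trial 1: previous choice A (+1): logit = 0.3 + 0.7
    assert pol.p_choose_a[1] == pytest.approx(1 / (1 + np.exp(-1.0)))
    # trial 2: previous choice B (-1): logit = 0.3 - 0.7
    assert pol.p_choose_a[2] == pytest.approx(1 / (1 + np.exp(0.4)))


def test_out_of_sequence_poke_counting():
    from conftest import perfect_trials
    trials = perfect_trials(n_per_block=3, n_blocks=1)
    layouts = [LayoutSpec(1, 1, 3, 5, 1)]
    # trial 0 chooses A (port 3); one poke at B port (5) before next init
    pokes = pd.DataFrame({
        "time": [0.0, 0.5, 1.4, 4.0, 4.5],
        "port": [1, 3, 5, 1, 3],
        "event": ["in", "in", "in", "in", "in"],
    })
    _, per_trial = performance_metrics(trials, pokes, layouts=layouts)
    assert per_trial["out_of_sequence_pokes"].tolist() == [1, 0, 0]
    only_task = pokes[pokes["port"] != 5]
    _, per_trial2 = performance_metrics(trials, only_task, layouts=layouts)
    assert per_trial2["out_of_sequence_pokes"].sum() == 0


def test_learning_curve_noiseless_exact():
    x = np.arange(12)
    y = 1.0 + 4.0 * np.exp(-0.5 * x)
    fit = fit_learning_curve(y)
    assert fit.rate == pytest.approx(0.5, abs=1e-6)
    assert fit.asymptote == pytest.approx(1.0, abs=1e-6)
    assert fit.log_time_constant == pytest.approx(np.log(2.0), abs=1e-5)


def test_learning_curve_recovery_under_noise():
    rng = np.random.default_rng(0)
    x = np.arange(15)
    y = 1.0 + 4.0 * np.exp(-0.5 * x) + rng.normal(0, 0.05, len(x))
    fit = fit_learning_curve(y)
    assert abs(fit.rate - 0.5) / 0.5 < 0.10


def test_learning_curve_flat_flagged():
    fit = fit_learning_curve(np.full(8, 2.0))
    assert not fit.identifiable
    assert np.isnan(fit.log_time_constant)


def test_learning_curve_needs_four_points():
    with pytest.raises(FitError):
        fit_learning_curve(np.array([1.0, 2.0, 3.0]))
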