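import numpy as np
import pandas as pd
import pytest

from revgen.decoding import (
    STAGE_LABELS,
    StageDataset,
    cross_problem_decode,
    error_pattern_summary,
    make_stage_dataset,
)


def _session_trials(problem=1, n=24, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    combos = [("A", "reward"), ("A", "omission"),
              ("B", "reward"), ("B", "omission")] * (n // 4)
    for choice, outcome in combos:
        rows.append({"trial_index": len(rows), "problem_index": problem,
                     "choice": choice, "outcome": outcome,
                     "initiation_time": t, "choice_time": t + 0.5,
                     "outcome_time": t + 0.75})
        t += 4.0
    return pd.DataFrame(rows)


def _poisson_trains(trials, rates_by_stage, n_neurons, seed=0):
    """Neurons whose rate in each stage window is stage-specific."""
    rng = np.random.default_rng(seed)
    trains = []
    t_end = trials.outcome_time.max() + 2
    for n in range(n_neurons):
        st = list(np.sort(rng.uniform(0, t_end, rng.poisson(2 * t_end))))
        for tr in trials.itertuples(index=False):
            stage_c = f"{tr.choice}-choice"
            tag = "rew" if tr.outcome == "reward" else "om"
            for center, stage in [(tr.initiation_time, "Init"),
                                  (tr.choice_time, stage_c),
                                  (tr.choice_time + 0.25, f"{tr.choice}-{tag}")]:
                lam = rates_by_stage(n, stage)
                k = rng.poisson(lam * 0.04)
                st.extend(center + rng.uniform(-0.02, 0.02, k))
        trains.append(np.sort(st))
    return trains


def test_pseudotrial_counts_and_determinism():
    trials = _session_trials()
    trains = [np.sort(np.random.default_rng(1).uniform(0, 100, 300))
              for _ in range(4)]
    ds1 = make_stage_dataset([trains], [trials], 1, n_pseudotrials=50, seed=3)
    ds2 = make_stage_dataset([trains], [trials], 1, n_pseudotrials=50, seed=3)
    assert ds1.X.shape == (350, 4)
    np.testing.assert_array_equal(ds1.X, ds2.X)
    np.testing.assert_array_equal(ds1.y, ds2.y)


def test_no_pseudo_uses_real_events():
    trials = _session_trials(n=24)
    trains = [np.sort(np.random.default_rng(2).uniform(0, 100, 300))]
    ds = make_stage_dataset([trains[0:1]], [trials], 1, pseudo=False)
    # smallest stage count: 6 events per outcome stage
    assert ds.X.shape == (7 * 6, 1)


def test_confusion_rows_sum_to_one_and_separable_identity():
    trials = _session_trials(n=40)
    # stage-indexed deterministic rates, distinct per stage
    stage_rate = {lab: 40.0 * (i + 1) for i, lab in enumerate(STAGE_LABELS)}
    trains = _poisson_trains(trials, lambda n, s: stage_rate[s], 12, seed=0)
    ds = make_stage_dataset([trains], [trials], 1, n_pseudotrials=60, seed=0)
    conf = cross_problem_decode(ds, ds)
    np.testing.assert_allclose(conf.sum(axis=1), 1.0)
    assert np.mean(np.diag(conf.to_numpy())) > 0.9


def test_label_independent_features_near_chance():
    trials = _session_trials(n=40)
    trains = _poisson_trains(trials, lambda n, s: 20.0, 10, seed=1)
    ds_a = make_stage_dataset([trains], [trials], 1, n_pseudotrials=60, seed=0)
    ds_b = make_stage_dataset([trains], [trials], 1, n_pseudotrials=60, seed=9)
    conf = cross_problem_decode(ds_a, ds_b)
    assert np.mean(np.diag(conf.to_numpy())) < 0.35     # chance is 1/7


def test_neuron_mismatch_raises():
    trials = _session_trials()
    tr1 = [np.sort(np.random.default_rng(0).uniform(0, 100, 100))
           for _ in range(3)]
    ds3 = make_stage_dataset([tr1], [trials], 1, n_pseudotrials=20, seed=0)
    ds2 = make_stage_dataset([tr1[:2]], [trials], 1, n_pseudotrials=20, seed=0)
    with pytest.raises(ValueError, match="neuron"):
        cross_problem_decode(ds3, ds2)


def _identity_conf():
    return pd.DataFrame(np.eye(7), index=STAGE_LABELS, columns=STAGE_LABELS)


def _uniform_conf():
    return pd.DataFrame(np.full((7, 7), 1 / 7), index=STAGE_LABELS,
                        columns=STAGE_LABELS)


def test_error_summary_identity(standard_layouts):
    confs = {(2, 3): _identity_conf(), (3, 2): _identity_conf()}
    s = error_pattern_summary(confs, standard_layouts)
    assert s.p_abstract == pytest.approx(1.0)
    assert s.p_sequence == pytest.approx(0.0)
    assert s.p_port == pytest.approx(0.0)
    assert s.n_port_matrices == 2


def test_error_summary_uniform(standard_layouts):
    confs = {(1, 2): _uniform_conf(), (2, 1): _uniform_conf()}
    s = error_pattern_summary(confs, standard_layouts)
    assert s.p_abstract == pytest.approx(1 / 7)
    assert s.p_sequence == pytest.approx(1 / 7)


def test_port_probability_restricted_to_interchanging_pairs(standard_layouts):
    # port-coding confusion: Init decodes to B-choice and vice versa
    conf = _uniform_conf() * 0
    conf.loc["Init", "B-choice"] = 1.0
    conf.loc["B-choice", "Init"] = 1.0
    for lab in STAGE_LABELS:
        if conf.loc[lab].sum() == 0:
            conf.loc[lab, lab] = 1.0
    confs = {(2, 3): conf, (3, 2): conf, (1, 2): conf}
    s = error_pattern_summary(confs, standard_layouts)
    # only (2,3) and (3,2) interchange I and B ports
    assert s.n_port_matrices == 2
    assert s.p_port == pytest.approx(1.0)
    # a session without interchanging pairs yields no port probability
    s2 = error_pattern_summary({(1, 2): conf}, standard_layouts)
    assert s2.p_port is None
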