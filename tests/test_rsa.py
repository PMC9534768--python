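import numpy as np
import pandas as pd
import pytest

from revgen.rsa import (
    ConditionMatrix,
    RSAMatrix,
    build_rdms,
    condition_labels,
    condition_vectors,
    rdm_regression,
    rsa_matrix,
    rsa_timecourse,
)


@pytest.fixture
def rdms(standard_layouts):
    return build_rdms(standard_layouts)


def _idx(labels, p, s):
    return labels.index((p, s))


class TestBuildRDMs:
    def test_port_identities_propagate(self, rdms):
        """Initiation in the layout-2 problem shares its physical port with
        the B choice in the layout-3 problem (B3 = I2)."""
        L = rdms.labels
        assert rdms.matrices["Port"][_idx(L, 2, "I"), _idx(L, 3, "B-rew")] == 1
        assert rdms.matrices["Port"][_idx(L, 2, "I"), _idx(L, 3, "B-om")] == 1
        # I3 = I1 as well
        assert rdms.matrices["Port"][_idx(L, 1, "I"), _idx(L, 3, "I")] == 1
        # A port is shared everywhere
        assert rdms.matrices["Port"][_idx(L, 1, "A-rew"), _idx(L, 2, "A-om")] == 1
        # distinct ports are dissimilar
        assert rdms.matrices["Port"][_idx(L, 1, "I"), _idx(L, 1, "A-rew")] == 0

    def test_choice_rdm(self, rdms):
        L = rdms.labels
        m = rdms.matrices["A vs B choice"]
        assert m[_idx(L, 1, "A-rew"), _idx(L, 1, "A-om")] == 1
        assert m[_idx(L, 1, "A-rew"), _idx(L, 3, "A-om")] == 1
        assert m[_idx(L, 1, "A-rew"), _idx(L, 2, "B-rew")] == 0
        assert m[_idx(L, 1, "I"), _idx(L, 2, "I")] == 0

    def test_problem_specific_a_rdm(self, rdms):
        L = rdms.labels
        m = rdms.matrices["Problem-specific A choice"]
        assert m[_idx(L, 1, "A-rew"), _idx(L, 1, "A-om")] == 1
        assert m[_idx(L, 1, "A-rew"), _idx(L, 2, "A-om")] == 0

    def test_stage_and_outcome_rdms(self, rdms):
        L = rdms.labels
        stage = rdms.matrices["Choice vs Initiation"]
        assert stage[_idx(L, 1, "I"), _idx(L, 2, "I")] == 1
        assert stage[_idx(L, 1, "A-rew"), _idx(L, 3, "B-om")] == 1
        assert stage[_idx(L, 1, "I"), _idx(L, 1, "A-rew")] == 0
        out = rdms.matrices["Outcome"]
        assert out[_idx(L, 1, "A-rew"), _idx(L, 2, "B-rew")] == 1
        assert out[_idx(L, 1, "A-rew"), _idx(L, 2, "B-om")] == 0
        conj = rdms.matrices["Outcome at A vs B"]
        assert conj[_idx(L, 1, "A-rew"), _idx(L, 2, "A-rew")] == 1
        assert conj[_idx(L, 1, "A-rew"), _idx(L, 2, "B-rew")] == 0

    def test_requires_three_problems(self, standard_layouts):
        with pytest.raises(ValueError):
            build_rdms(standard_layouts[:2])


def _toy_trials():
    rows = []
    t = 0.0
    for p in (1, 2, 3):
        for choice, outcome in [("A", "reward"), ("A", "omission"),
                                ("B", "reward"), ("B", "omission")] * 2:
            rows.append({"trial_index": len(rows), "problem_index": p,
                         "choice": choice, "outcome": outcome,
                         "initiation_time": t, "choice_time": t + 0.5,
                         "outcome_time": t + 0.75})
            t += 4.0
    return pd.DataFrame(rows)


class TestConditionVectors:
    def test_single_spike_window_rate(self):
        trials = _toy_trials()
        # one spike exactly at the first A-rew choice entry in problem 1
        ct = trials.loc[(trials.problem_index == 1) & (trials.choice == "A")
                        & (trials.outcome == "reward"), "choice_time"].iloc[0]
        trains = [np.array([ct + 0.001])]
        trains += [np.array([0.1]), np.array([0.2])]
        cond = condition_vectors(trains, trials, half_width=0.02)
        labels = cond.labels
        # 2 events in the condition, 1 spike in one of them: mean count 0.5
        assert cond.values[_idx(labels, 1, "A-rew"), 0] == pytest.approx(
            0.5 / 0.04)
        # doubling the half-width halves the rate
        cond2 = condition_vectors(trains, trials, half_width=0.04)
        assert cond2.values[_idx(labels, 1, "A-rew"), 0] == pytest.approx(
            0.5 / 0.08)

    def test_zero_event_condition_raises(self):
        trials = _toy_trials()
        trials = trials[~((trials.problem_index == 2) & (trials.choice == "B")
                          & (trials.outcome == "omission"))]
        with pytest.raises(ValueError, match="B-om"):
            condition_vectors([np.array([0.1])] * 3, trials)


class TestRSAMatrix:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        cond = ConditionMatrix(rng.normal(size=(15, 30)),
                               condition_labels(), 0.0, 0.02)
        m = rsa_matrix(cond)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m.values), 1.0)
        assert np.all(np.abs(m.values) <= 1 + 1e-12)

    def test_identical_and_flipped_rows(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(15, 40))
        v[1] = v[0] + v.mean(axis=0) - v.mean(axis=0)   # keep shape
        v[1] = v[0].copy()
        cond = ConditionMatrix(v, condition_labels(), 0.0, 0.02)
        m = rsa_matrix(cond)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_needs_three_neurons(self):
        with pytest.raises(ValueError):
            rsa_matrix(ConditionMatrix(np.zeros((15, 2)),
                                       condition_labels(), 0.0, 0.02))


class TestRDMRegression:
    def test_exact_reconstruction(self, rdms):
        M = 0.5 * rdms.matrices["Outcome"] + 0.2
        np.fill_diagonal(M, 1.0)
        res = rdm_regression(RSAMatrix(values=M, labels=rdms.labels), rdms)
        assert res.betas["Outcome"] == pytest.approx(0.5, abs=1e-10)
        assert res.betas["constant"] == pytest.approx(0.2, abs=1e-10)
        for name, b in res.betas.items():
            if name not in ("Outcome", "constant"):
                assert abs(b) < 1e-10

    def test_constant_offdiagonals_absorbed(self, rdms):
        M = np.full((15, 15), 0.3)
        np.fill_diagonal(M, 1.0)
        res = rdm_regression(RSAMatrix(values=M, labels=rdms.labels), rdms)
        for name, b in res.betas.items():
            expect = 0.3 if name == "constant" else 0.0
            assert b == pytest.approx(expect, abs=1e-10)

    def test_cpd_matches_oracle(self, rdms):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(15, 15))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        res = rdm_regression(RSAMatrix(values=M, labels=rdms.labels), rdms)
        tri = np.tril_indices(15, k=-1)
        y = M[tri]
        names = rdms.names()
        X = np.column_stack([np.ones(len(y))] +
                            [rdms.matrices[k][tri] for k in names])

        def sse(A):
            b, *_ = np.linalg.lstsq(A, y, rcond=None)
            r = y - A @ b
            return float(r @ r)

        full = sse(X)
        for k, name in enumerate(names, start=1):
            red = sse(np.delete(X, k, axis=1))
            assert abs(res.cpd[name] - (red - full) / red) < 1e-10

    def test_collinear_rdms_detected(self, rdms):
        mats = dict(rdms.matrices)
        mats["Duplicate"] = mats["Outcome"].copy()
        from revgen.rsa import RDMSet
        bad = RDMSet(matrices=mats, labels=rdms.labels)
        M = np.eye(15)
        with pytest.raises(ValueError, match="collinear"):
            rdm_regression(RSAMatrix(values=M, labels=rdms.labels), bad)


def test_timecourse_single_offset_matches_pipeline(standard_layouts):
    rng = np.random.default_rng(0)
    trials = _toy_trials()
    trains = [np.sort(rng.uniform(0, trials.outcome_time.max(), 200))
              for _ in range(6)]
    tc = rsa_timecourse(trains, trials, standard_layouts,
                        offsets=np.array([0.1]))
    cond = condition_vectors(trains, trials, choice_offset=0.1)
    res = rdm_regression(rsa_matrix(cond), build_rdms(standard_layouts))
    for name, cpd in res.cpd.items():
        row = tc[(tc.rdm == name)]
        assert row.cpd.iloc[0] == pytest.approx(cpd)
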