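"""Representational similarity analysis over the 15 trial-event conditions.

Conditions are the cross of the session's three problems with five trial
events — Initiation, rewarded A choice, unrewarded A choice, rewarded B
choice, unrewarded B choice — ordered problem-major. Firing rates are mean
spike counts in narrow windows (+/-20 ms) around initiation and choice port
entries; sliding the choice windows later in the trial while holding the
initiation windows fixed produces the RSA time course through outcome time.

The observed condition-by-condition correlation matrix is modeled as a
linear combination of binary model similarity matrices (RDMs), each encoding
one candidate coding scheme (physical port, A-vs-B choice, outcome, outcome
conjunctive with choice, trial stage, problem-specific A choice). The Port
RDM is computed from the actual port identities, so the layout overlaps
(e.g. the type-3 B choice port being the type-2 initiation port) propagate
into the model. Influence of each RDM is quantified by its regression CPD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from revgen.io_core import LayoutSpec

__all__ = [
    "STAGES",
    "condition_labels",
    "ConditionMatrix",
    "RSAMatrix",
    "RDMSet",
    "condition_vectors",
    "rsa_matrix",
    "build_rdms",
    "rdm_regression",
    "rsa_timecourse",
]

STAGES = ["I", "A-rew", "A-om", "B-rew", "B-om"]


def condition_labels(problems=(1, 2, 3)) -> list[tuple[int, str]]:
    """(problem, stage) pairs, problem-major, stage order as in STAGES."""
    return [(p, s) for p in problems for s in STAGES]


@dataclass
class ConditionMatrix:
    """condition x neuron mean firing rates (Hz) with the window used."""

    values: np.ndarray                 # (15, n_neurons)
    labels: list[tuple[int, str]]
    choice_offset: float
    half_width: float

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.labels):
            raise ValueError("rows do not match condition labels")


@dataclass
class RSAMatrix:
    """15 x 15 Pearson correlations between demeaned condition vectors."""

    values: np.ndarray
    labels: list[tuple[int, str]]

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("RSA matrix must be symmetric")


@dataclass
class RDMSet:
    """Named binary model matrices over the same condition ordering."""

    matrices: dict[str, np.ndarray]
    labels: list[tuple[int, str]]

    def names(self) -> list[str]:
        return list(self.matrices)


def _stage_events(trials: pd.DataFrame, problem: int, stage: str) -> np.ndarray:
    """Event times (port entries) defining one condition."""
    t = trials[trials["problem_index"] == problem]
    if stage == "I":
        return t["initiation_time"].to_numpy(float)
    side, outcome = stage.split("-")
    outcome = {"rew": "reward", "om": "omission"}[outcome]
    sel = (t["choice"] == side) & (t["outcome"] == outcome)
    return t.loc[sel, "choice_time"].to_numpy(float)


def condition_vectors(
    spike_trains: list[np.ndarray],
    trials: pd.DataFrame,
    choice_offset: float = 0.0,
    half_width: float = 0.020,
    problems=(1, 2, 3),
) -> ConditionMatrix:
    """Mean windowed firing rate of every neuron in every condition.

    ``spike_trains`` is one sorted spike-time array per neuron. Choice-event
    windows are centered ``choice_offset`` seconds after port entry;
    initiation windows always sit at the entry itself.
    """
    labels = condition_labels(problems)
    n_neurons = len(spike_trains)
    out = np.zeros((len(labels), n_neurons))
    for row, (p, stage) in enumerate(labels):
        events = _stage_events(trials, p, stage)
        if events.size == 0:
            raise ValueError(f"condition (problem {p}, {stage}) has no events")
        offset = 0.0 if stage == "I" else choice_offset
        lo = events + offset - half_width
        hi = events + offset + half_width
        for n, train in enumerate(spike_trains):
            counts = np.searchsorted(train, hi) - np.searchsorted(train, lo)
            out[row, n] = counts.mean() / (2.0 * half_width)
    return ConditionMatrix(values=out, labels=labels,
                           choice_offset=choice_offset, half_width=half_width)


def rsa_matrix(cond: ConditionMatrix) -> RSAMatrix:
    """Pearson correlations between condition rows after per-neuron demeaning."""
    v = cond.values
    if v.shape[1] < 3:
        raise ValueError("need at least 3 neurons")
    demeaned = v - v.mean(axis=0, keepdims=True)      # demean each neuron
    sd = demeaned.std(axis=1)
    if np.any(sd < 1e-12):
        bad = [cond.labels[i] for i in np.where(sd < 1e-12)[0]]
        raise ValueError(f"zero-variance condition rows {bad}")
    corr = np.corrcoef(demeaned)
    return RSAMatrix(values=corr, labels=list(cond.labels))


def _port_of_condition(lay: LayoutSpec, stage: str) -> int:
    if stage == "I":
        return lay.initiation_port
    return lay.choice_A_port if stage.startswith("A") else lay.choice_B_port


def build_rdms(layouts: list[LayoutSpec]) -> RDMSet:
    """The six model similarity matrices for a session's three layouts."""
    problems = sorted(l.problem_index for l in layouts)
    if len(problems) != 3:
        raise ValueError("need layouts for exactly 3 problems")
    lay_by_problem = {l.problem_index: l for l in layouts}
    labels = condition_labels(problems)
    n = len(labels)

    def mat(pred) -> np.ndarray:
        m = np.zeros((n, n))
        for i, (pi, si) in enumerate(labels):
            for j, (pj, sj) in enumerate(labels):
                m[i, j] = float(pred(pi, si, pj, sj))
        return m

    def port(p, s):
        return _port_of_condition(lay_by_problem[p], s)

    def is_choice(s):
        return s != "I"

    def side(s):
        return s[0] if is_choice(s) else None

    def outcome(s):
        return s.split("-")[1] if is_choice(s) else None

    matrices = {
        "Port": mat(lambda pi, si, pj, sj: port(pi, si) == port(pj, sj)),
        "A vs B choice": mat(lambda pi, si, pj, sj:
                             is_choice(si) and is_choice(sj)
                             and side(si) == side(sj)),
        "Outcome": mat(lambda pi, si, pj, sj:
                       is_choice(si) and is_choice(sj)
                       and outcome(si) == outcome(sj)),
        "Outcome at A vs B": mat(lambda pi, si, pj, sj:
                                 is_choice(si) and is_choice(sj)
                                 and outcome(si) == outcome(sj)
                                 and side(si) == side(sj)),
        "Choice vs Initiation": mat(lambda pi, si, pj, sj:
                                    is_choice(si) == is_choice(sj)),
        "Problem-specific A choice": mat(lambda pi, si, pj, sj:
                                         pi == pj
                                         and side(si) == "A" and side(sj) == "A"),
    }
    return RDMSet(matrices=matrices, labels=labels)


@dataclass
class RDMRegressionResult:
    betas: dict[str, float]       # includes "constant"
    cpd: dict[str, float]         # model RDMs only


def rdm_regression(rsa: RSAMatrix, rdms: RDMSet) -> RDMRegressionResult:
    """OLS of the vectorized RSA matrix on the model RDMs plus a constant.

    Diagonals are deleted (strict lower triangles are used; all matrices are
    symmetric) and the CPD of each RDM is its unique variance share.
    """
    if rsa.labels != rdms.labels:
        raise ValueError("RSA and RDM condition orderings differ")
    n = rsa.values.shape[0]
    tri = np.tril_indices(n, k=-1)
    y = rsa.values[tri]
    names = rdms.names()
    cols = [np.ones(len(y))] + [rdms.matrices[k][tri] for k in names]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for a in range(1, X.shape[1]):
            for b in range(a + 1, X.shape[1]):
                sub = X[:, [0, a, b]]
                if np.linalg.matrix_rank(sub) < 3:
                    raise ValueError(
                        f"collinear RDMs after vectorization: "
                        f"{names[a - 1]!r} and {names[b - 1]!r}")
        raise ValueError("collinear RDM set after vectorization")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sse_full = float(resid @ resid)
    eps = 1e-12 * float(y @ y)
    cpd = {}
    for k, name in enumerate(names, start=1):
        Xr = np.delete(X, k, axis=1)
        br, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        rr = y - Xr @ br
        sse_red = float(rr @ rr)
        cpd[name] = (sse_red - sse_full) / sse_red if sse_red > eps else 0.0
    betas = {"constant": float(beta[0])}
    betas.update({name: float(beta[k]) for k, name in enumerate(names, start=1)})
    return RDMRegressionResult(betas=betas, cpd=cpd)


def rsa_timecourse(
    spike_trains: list[np.ndarray],
    trials: pd.DataFrame,
    layouts: list[LayoutSpec],
    offsets: np.ndarray | None = None,
    half_width: float = 0.020,
) -> pd.DataFrame:
    """RDM-regression CPDs as the choice windows slide 0 -> 0.76 s.

    Returns a tidy frame with columns ``offset``, ``rdm``, ``cpd``, ``beta``.
    Initiation windows stay fixed at port entry throughout.
    """
    if offsets is None:
        offsets = np.arange(0.0, 0.7601, 0.04)
    rdms = build_rdms(layouts)
    rows = []
    for off in offsets:
        cond = condition_vectors(spike_trains, trials, choice_offset=float(off),
                                 half_width=half_width)
        res = rdm_regression(rsa_matrix(cond), rdms)
        for name in rdms.names():
            rows.append({"offset": float(off), "rdm": name,
                         "cpd": res.cpd[name], "beta": res.betas[name]})
    return pd.DataFrame(rows)
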