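"""Cross-problem decoding of trial stage and the confusion-error summary.

A linear support vector classifier is trained to identify the seven trial
stages (Initiation, A/B choice, A/B reward, A/B no-reward) from windowed
population rates in one problem and tested on another. Because the
initiation and B choice ports interchange between layout types 2 and 3, the
pattern of cross-problem errors separates three coding schemes:

* abstract state — diagonal cells (correct stage across problems);
* sequence position — errors to the other choice at the same position in
  the trial (A choice <-> B choice, A reward <-> B reward, ...);
* physical port — Initiation <-> B-choice errors, scored only on problem
  pairs where those ports actually interchange.

Neurons from different sessions are combined into pseudotrials: for each
labelled pseudotrial, one event is sampled per neuron independently with
replacement (neurons were not recorded simultaneously, so only the marginal
event statistics are meaningful).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from revgen.io_core import LayoutSpec

__all__ = [
    "STAGE_LABELS",
    "StageDataset",
    "ConfusionSummary",
    "stage_event_rates",
    "make_stage_dataset",
    "cross_problem_decode",
    "error_pattern_summary",
]

STAGE_LABELS = ["Init", "A-choice", "B-choice",
                "A-rew", "B-rew", "A-om", "B-om"]

# (row stage, column stage) pairs indicating same-sequence-position errors
_SEQUENCE_SWAPS = [("A-choice", "B-choice"), ("B-choice", "A-choice"),
                   ("A-rew", "B-rew"), ("B-rew", "A-rew"),
                   ("A-om", "B-om"), ("B-om", "A-om")]


@dataclass
class StageDataset:
    """Pseudotrial features (rows) with stage labels for one problem."""

    X: np.ndarray
    y: np.ndarray                 # stage label strings
    problem: int
    neuron_ids: np.ndarray

    def __post_init__(self) -> None:
        for lab in np.unique(self.y):
            if (self.y == lab).sum() < 2:
                raise ValueError(f"label {lab} has fewer than 2 pseudotrials")


@dataclass
class ConfusionSummary:
    p_abstract: float
    p_sequence: float
    p_port: float | None          # None when no interchanging layout pair
    n_port_matrices: int


def stage_event_rates(
    spike_trains: list[np.ndarray],
    trials: pd.DataFrame,
    problem: int,
    half_width: float = 0.020,
    outcome_offset: float = 0.25,
) -> dict[str, np.ndarray]:
    """Per-stage event-window rates, one (n_events, n_neurons) array each.

    Choice-stage windows are +/-half_width around choice port entry;
    outcome-stage windows sit ``outcome_offset`` later (after cue end);
    initiation windows are around the initiation poke.
    """
    t = trials[trials["problem_index"] == problem]
    out: dict[str, np.ndarray] = {}

    def rates(times: np.ndarray) -> np.ndarray:
        lo, hi = times - half_width, times + half_width
        m = np.empty((len(times), len(spike_trains)))
        for n, train in enumerate(spike_trains):
            m[:, n] = (np.searchsorted(train, hi) - np.searchsorted(train, lo))
        return m / (2.0 * half_width)

    out["Init"] = rates(t["initiation_time"].to_numpy(float))
    for side in ("A", "B"):
        sel = t["choice"] == side
        out[f"{side}-choice"] = rates(t.loc[sel, "choice_time"].to_numpy(float))
        for oc, tag in (("reward", "rew"), ("omission", "om")):
            s2 = sel & (t["outcome"] == oc)
            times = t.loc[s2, "choice_time"].to_numpy(float) + outcome_offset
            out[f"{side}-{tag}"] = rates(times)
    for lab in STAGE_LABELS:
        if out[lab].shape[0] == 0:
            raise ValueError(f"stage {lab} absent in problem {problem}")
    return out


def make_stage_dataset(
    spike_trains_per_session: list[list[np.ndarray]],
    trials_per_session: list[pd.DataFrame],
    problem: int,
    n_pseudotrials: int = 100,
    seed: int | np.random.Generator = 0,
    half_width: float = 0.020,
    outcome_offset: float = 0.25,
    pseudo: bool = True,
) -> StageDataset:
    """Assemble the pseudopopulation stage dataset for one problem.

    With ``pseudo=False`` (single simultaneously recorded session) the rows
    are the real events of each stage, truncated to the smallest stage count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_session = [
        stage_event_rates(trains, trials, problem, half_width, outcome_offset)
        for trains, trials in zip(spike_trains_per_session, trials_per_session)
    ]
    n_neurons = sum(len(t) for t in spike_trains_per_session)

    X_rows, y_rows = [], []
    if pseudo:
        for lab in STAGE_LABELS:
            block = np.empty((n_pseudotrials, n_neurons))
            col = 0
            for s, rates in enumerate(per_session):
                ev = rates[lab]
                for n in range(ev.shape[1]):
                    idx = rng.integers(0, ev.shape[0], size=n_pseudotrials)
                    block[:, col] = ev[idx, n]
                    col += 1
            X_rows.append(block)
            y_rows.append(np.full(n_pseudotrials, lab, dtype=object))
    else:
        if len(per_session) != 1:
            raise ValueError("pseudo=False requires a single session")
        rates = per_session[0]
        k = min(v.shape[0] for v in rates.values())
        for lab in STAGE_LABELS:
            X_rows.append(rates[lab][:k])
            y_rows.append(np.full(k, lab, dtype=object))

    ids = np.concatenate([np.arange(len(t)) for t in spike_trains_per_session])
    return StageDataset(X=np.vstack(X_rows), y=np.concatenate(y_rows),
                        problem=problem, neuron_ids=ids)


def cross_problem_decode(
    train: StageDataset,
    test: StageDataset,
    C: float = 1.0,
) -> pd.DataFrame:
    """Train a linear SVC on one problem, test on another; row-normalized
    confusion matrix (rows = true stage, columns = decoded stage).

    Features are z-scored using training statistics only.
    """
    if train.X.shape[1] != test.X.shape[1]:
        raise ValueError("train and test neuron sets differ")
    mu = train.X.mean(axis=0)
    sd = train.X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    clf = SVC(kernel="linear", C=C, decision_function_shape="ovr")
    clf.fit((train.X - mu) / sd, train.y.astype(str))
    pred = clf.predict((test.X - mu) / sd)

    conf = pd.DataFrame(0.0, index=STAGE_LABELS, columns=STAGE_LABELS)
    for true_lab in STAGE_LABELS:
        sel = test.y == true_lab
        if not sel.any():
            continue
        for p_lab, cnt in zip(*np.unique(pred[sel], return_counts=True)):
            conf.loc[true_lab, p_lab] = cnt / sel.sum()
    return conf


def error_pattern_summary(
    confusions: dict[tuple[int, int], pd.DataFrame],
    layouts: list[LayoutSpec],
) -> ConfusionSummary:
    """Abstract-state / sequence-position / physical-port probabilities.

    ``confusions`` maps (train problem, test problem) to a row-normalized
    confusion matrix. The port probability uses Initiation <-> B-choice
    cells and only the problem pairs whose initiation and B ports
    interchange.
    """
    lay = {l.problem_index: l for l in layouts}
    p_abs, p_seq, p_port = [], [], []
    for (tr_p, te_p), conf in confusions.items():
        p_abs.append(float(np.mean(np.diag(conf.to_numpy()))))
        p_seq.append(float(np.mean([conf.loc[r, c] for r, c in _SEQUENCE_SWAPS])))
        cells = []
        # true Init in the test problem lives at the train problem's B port
        if lay[te_p].initiation_port == lay[tr_p].choice_B_port:
            cells.append(conf.loc["Init", "B-choice"])
        # true B choice in the test problem lives at the train problem's I port
        if lay[te_p].choice_B_port == lay[tr_p].initiation_port:
            cells.append(conf.loc["B-choice", "Init"])
        if cells:
            p_port.append(float(np.mean(cells)))
    return ConfusionSummary(
        p_abstract=float(np.mean(p_abs)),
        p_sequence=float(np.mean(p_seq)),
        p_port=float(np.mean(p_port)) if p_port else None,
        n_port_matrices=len(p_port),
    )
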