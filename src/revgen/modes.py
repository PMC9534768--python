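"""SVD cellular/temporal modes and cross-problem transfer curves.

The activity matrix D of one problem half stacks, per neuron, the demeaned
trial-averaged firing rate over four concatenated trial types (rewarded A,
unrewarded A, rewarded B, unrewarded B), each spanning the full warp grid.
The thin SVD D = U S V^T splits it into cellular modes (columns of U, cell
assemblies) paired with temporal modes (rows of V^T, their time courses).

Transfer asks how well the modes of a *source* half explain a *target* half:

* temporal:  M = D_target V_source, variance per mode summed over neurons —
  generalizes whenever the same trial events are represented, by any cells;
* cellular:  M = U_source^T D_target, summed over timepoints — generalizes
  when the same cell assemblies covary, whatever they represent;
* paired:    diag(U_source^T D_target V_source)^2 cumulative — generalizes
  only when the same assemblies play the same roles.

Within-problem curves (first half <-> second half of one problem) control
for drift; the cross-problem comparison uses the second half of one problem
against the first half of the next. The generalization gap is the area
between the mean within- and cross-problem curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from revgen.alignment import AlignedRates

__all__ = [
    "TRIAL_TYPES",
    "ActivityMatrix",
    "ModeDecomposition",
    "TransferCurve",
    "activity_matrix",
    "svd_modes",
    "transfer_curve",
    "problem_half_matrices",
    "transfer_curves_by_kind",
    "generalization_gap",
]

TRIAL_TYPES = [("A", "reward"), ("A", "omission"),
               ("B", "reward"), ("B", "omission")]


@dataclass
class ActivityMatrix:
    """Row-demeaned neuron x (4 x grid timepoints) trial-type averages."""

    D: np.ndarray
    problem: int
    half: str                     # "first" | "second"
    n_timepoints: int

    def __post_init__(self) -> None:
        if self.D.shape[1] != 4 * self.n_timepoints:
            raise ValueError("column count must be 4 x grid length")


@dataclass
class ModeDecomposition:
    U: np.ndarray
    S: np.ndarray
    Vt: np.ndarray

    @property
    def rank(self) -> int:
        return len(self.S)


@dataclass
class TransferCurve:
    """Cumulative explained fraction (or weight) vs number of source modes."""

    kind: str                     # "temporal" | "cellular" | "paired"
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cumulative) < -1e-9):
            raise ValueError("cumulative curve must be nondecreasing")


def activity_matrix(
    aligned: AlignedRates,
    problem: int,
    half: str,
) -> ActivityMatrix:
    """Trial-type averages for one (problem, half), row-demeaned.

    Halves split at the median trial index within the problem (an odd trial
    goes to the first half). Unrewarded averages include both correct and
    incorrect choices — the trial types condition only on choice x outcome.
    """
    sel = (aligned.trials["problem_index"] == problem).to_numpy()
    idx = np.where(sel)[0]
    if idx.size == 0:
        raise ValueError(f"no trials in problem {problem}")
    n_first = (idx.size + 1) // 2
    take = idx[:n_first] if half == "first" else idx[n_first:]
    if half not in ("first", "second"):
        raise ValueError("half must be 'first' or 'second'")

    t = aligned.trials.iloc[take]
    blocks = []
    for side, outcome in TRIAL_TYPES:
        m = ((t["choice"] == side) & (t["outcome"] == outcome)).to_numpy()
        if not m.any():
            raise ValueError(
                f"problem {problem} {half} half has no {side}/{outcome} trials")
        blocks.append(aligned.rates[:, take[m], :].mean(axis=1))
    D = np.hstack(blocks)
    D = D - D.mean(axis=1, keepdims=True)
    return ActivityMatrix(D=D, problem=problem, half=half,
                          n_timepoints=aligned.grid.n_timepoints)


def svd_modes(D: ActivityMatrix | np.ndarray) -> ModeDecomposition:
    """Thin SVD with a sign convention: the largest-magnitude element of
    each temporal mode is positive."""
    M = D.D if isinstance(D, ActivityMatrix) else np.asarray(D, float)
    if not np.all(np.isfinite(M)):
        raise ValueError("activity matrix contains non-finite entries")
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    return ModeDecomposition(U=U, S=S, Vt=Vt)


def transfer_curve(
    source: ModeDecomposition,
    target: ActivityMatrix | np.ndarray,
    kind: str,
) -> TransferCurve:
    """Cumulative variance of ``target`` explained by the source modes.

    Temporal and cellular curves are fractions of ||target||_F^2 and reach
    1 at full rank. The paired curve is the cumulative squared diagonal of
    U_src^T D V_src divided by the neuron count; normalization by the
    within-problem peak is applied when curves are assembled for comparison
    (see :func:`transfer_curves_by_kind`).
    """
    D = target.D if isinstance(target, ActivityMatrix) else np.asarray(target, float)
    total = float(np.sum(D * D))
    if kind == "temporal":
        if D.shape[1] != source.Vt.shape[1]:
            raise ValueError("timepoint axes of target and source modes differ")
        M = D @ source.Vt.T
        per_mode = np.sum(M * M, axis=0)
        cum = np.cumsum(per_mode) / total
    elif kind == "cellular":
        if D.shape[0] != source.U.shape[0]:
            raise ValueError("neuron axes of target and source modes differ")
        M = source.U.T @ D
        per_mode = np.sum(M * M, axis=1)
        cum = np.cumsum(per_mode) / total
    elif kind == "paired":
        if D.shape[0] != source.U.shape[0] or D.shape[1] != source.Vt.shape[1]:
            raise ValueError("target not conformable with source mode pairs")
        d = np.einsum("nk,nt,kt->k", source.U, D, source.Vt)
        cum = np.cumsum(d * d) / D.shape[0]
    else:
        raise ValueError(f"unknown transfer kind {kind!r}")
    return TransferCurve(kind=kind, cumulative=cum)


def problem_half_matrices(aligned: AlignedRates) -> dict[tuple[int, str], ActivityMatrix]:
    """Activity matrices for every (problem, half) of a dataset."""
    out = {}
    for p in sorted(aligned.trials["problem_index"].unique()):
        for half in ("first", "second"):
            out[(int(p), half)] = activity_matrix(aligned, int(p), half)
    return out


def _stack(mats: list[ActivityMatrix]) -> ActivityMatrix:
    return ActivityMatrix(D=np.vstack([m.D for m in mats]),
                          problem=mats[0].problem, half=mats[0].half,
                          n_timepoints=mats[0].n_timepoints)


def transfer_curves_by_kind(
    matrices: dict[tuple[int, str], ActivityMatrix] | list[dict],
    kind: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean within- and cross-problem transfer curves for one kind.

    ``matrices`` is a (problem, half) -> ActivityMatrix mapping, or a list
    of such mappings from several sessions whose matrices are stacked
    neuron-wise into a pseudopopulation first. Within-problem comparisons
    average both half orderings of each problem; cross-problem comparisons
    use the second half of problem i as source and the first half of
    problem i+1 as target. Paired curves are normalized by the peak of the
    mean within-problem curve.
    """
    if isinstance(matrices, list):
        keys = matrices[0].keys()
        matrices = {k: _stack([m[k] for m in matrices]) for k in keys}
    problems = sorted({p for p, _ in matrices})

    within, cross = [], []
    for p in problems:
        for src_h, tgt_h in (("second", "first"), ("first", "second")):
            modes = svd_modes(matrices[(p, src_h)])
            within.append(transfer_curve(modes, matrices[(p, tgt_h)], kind))
    for p in problems[:-1]:
        modes = svd_modes(matrices[(p, "second")])
        cross.append(transfer_curve(modes, matrices[(p + 1, "first")], kind))

    n_modes = min(len(c.cumulative) for c in within + cross)
    w = np.mean([c.cumulative[:n_modes] for c in within], axis=0)
    x = np.mean([c.cumulative[:n_modes] for c in cross], axis=0)
    if kind == "paired":
        peak = w.max()
        if peak > 0:
            w, x = w / peak, x / peak
    return w, x


def generalization_gap(within: np.ndarray, cross: np.ndarray) -> float:
    """Area (trapezoid rule over mode count) between the mean curves."""
    within = np.asarray(within, float)
    cross = np.asarray(cross, float)
    if within.shape != cross.shape:
        raise ValueError("within and cross curves must have equal length")
    return float(np.trapezoid(within - cross))
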