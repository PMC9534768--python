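"""Per-timepoint linear encoding models with CPD time courses.

At every timepoint of the warped grid, each neuron's rate across trials is
regressed on the trial variables (choice, outcome, choice x outcome, and
optionally the policy and policy x choice). The population coefficient of
partial determination of regressor r at timepoint t is

    CPD_r(t) = (SSE_without_r - SSE_full) / SSE_without_r

with sums of squared errors pooled (summed) across neurons, i.e. neurons are
weighted by their variance. Within-region significance comes from a trial-
roll null: firing rates are circularly shifted with respect to trial labels
(one shared offset per permutation, preserving cross-trial autocorrelation
and cross-neuron correlation) and the threshold is the percentile of the
per-permutation CPD peak over timepoints (family-wise control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from revgen.alignment import AlignedRates
from revgen.behavior import PolicyTrace

__all__ = [
    "DesignMatrix",
    "CPDResult",
    "build_design",
    "cpd_timecourse",
    "cpd_per_problem",
    "roll_null",
]


@dataclass
class DesignMatrix:
    """Trials x regressors matrix with a leading constant column."""

    X: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        if self.names[0] != "constant":
            raise ValueError("first column must be the constant")
        if self.X.shape[1] != len(self.names):
            raise ValueError("names do not match columns")

    @property
    def regressors(self) -> list[str]:
        return self.names[1:]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]


def build_design(
    trials: pd.DataFrame,
    policy: PolicyTrace | np.ndarray | None = None,
) -> DesignMatrix:
    """+/-1-coded design for one problem's trials.

    Columns: constant, choice (A=+1/B=-1), outcome (reward=+1/omission=-1),
    interaction (their product); with ``policy`` also the within-subset
    centered policy and policy x choice. Regressors constant within the
    subset are dropped with a warning.
    """
    c = np.where(trials["choice"].to_numpy() == "A", 1.0, -1.0)
    o = np.where(trials["outcome"].to_numpy() == "reward", 1.0, -1.0)
    cols = {"choice": c, "outcome": o, "interaction": c * o}
    if policy is not None:
        p = policy.p_choose_a if isinstance(policy, PolicyTrace) else np.asarray(policy, float)
        if len(p) != len(trials):
            raise ValueError("policy length does not match trials")
        if np.any(np.isnan(p)):
            raise ValueError("policy contains invalid trials; filter them first")
        pc = p - p.mean()
        cols["policy"] = pc
        cols["policy_x_choice"] = pc * c

    names, keep = ["constant"], [np.ones(len(trials))]
    for name, v in cols.items():
        if np.ptp(v) < 1e-12:
            warnings.warn(f"regressor {name!r} is constant within this subset; "
                          f"dropped", stacklevel=2)
            continue
        names.append(name)
        keep.append(v)
    return DesignMatrix(X=np.column_stack(keep), names=names)


@dataclass
class CPDResult:
    """cpd[regressor, timepoint] as fraction of variance; optional null info."""

    cpd: np.ndarray
    regressors: list[str]
    grid_times: np.ndarray | None = None
    threshold_95: np.ndarray | None = None   # per regressor, peak-corrected
    threshold_99: np.ndarray | None = None

    def series(self, name: str) -> np.ndarray:
        return self.cpd[self.regressors.index(name)]


def _residual_projector(X: np.ndarray) -> np.ndarray:
    return np.eye(X.shape[0]) - X @ np.linalg.pinv(X)


def _sse_pooled(R: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Sum over neurons of squared residuals at each timepoint.

    ``R``: (trials, trials) residual-maker; ``Y``: (trials, neurons, T).
    Returns (T,).
    """
    resid = np.tensordot(R, Y, axes=(1, 0))
    return np.einsum("int,int->t", resid, resid)


def cpd_timecourse(
    rates: AlignedRates | np.ndarray,
    design: DesignMatrix,
    pool_neurons: bool = True,
) -> CPDResult:
    """Population CPD of each regressor at every timepoint.

    ``rates`` may be an :class:`AlignedRates` or a raw (neurons, trials, T)
    array whose trial axis matches the design rows. With
    ``pool_neurons=False`` per-neuron CPDs are averaged instead of pooling
    SSEs.
    """
    Y3 = rates.rates if isinstance(rates, AlignedRates) else np.asarray(rates, float)
    grid_times = rates.grid.times if isinstance(rates, AlignedRates) else None
    if Y3.shape[1] != design.X.shape[0]:
        raise ValueError("trial axes of rates and design do not match")
    X = design.X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify a collinear pair for the error message
        bad = []
        for i in range(X.shape[1]):
            keep = np.delete(np.arange(X.shape[1]), i)
            if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
                bad.append(design.names[i])
        raise ValueError(f"rank-deficient design; collinear columns {bad}")

    Y = np.moveaxis(Y3, 0, 1)                      # (trials, neurons, T)
    R_full = _residual_projector(X)
    # a reduced-model SSE this far below the raw signal energy is numerical
    # zero (fully explained) rather than real unexplained variance
    if pool_neurons:
        sse_full = _sse_pooled(R_full, Y)
        eps = 1e-12 * np.einsum("int,int->t", Y, Y)
    else:
        resid = np.tensordot(R_full, Y, axes=(1, 0))
        sse_full = np.einsum("int,int->nt", resid, resid)
        eps = 1e-12 * np.einsum("int,int->nt", Y, Y)

    cpds = []
    for name in design.regressors:
        j = design.names.index(name)
        Xr = np.delete(X, j, axis=1)
        Rr = _residual_projector(Xr)
        if pool_neurons:
            sse_red = _sse_pooled(Rr, Y)
            with np.errstate(invalid="ignore", divide="ignore"):
                cpd = np.where(sse_red > eps, (sse_red - sse_full) / sse_red, 0.0)
        else:
            resid = np.tensordot(Rr, Y, axes=(1, 0))
            sse_red = np.einsum("int,int->nt", resid, resid)
            with np.errstate(invalid="ignore", divide="ignore"):
                per = np.where(sse_red > eps, (sse_red - sse_full) / sse_red, 0.0)
            cpd = per.mean(axis=0)
        cpds.append(np.clip(cpd, 0.0, 1.0))
    return CPDResult(cpd=np.vstack(cpds), regressors=list(design.regressors),
                     grid_times=grid_times)


def cpd_per_problem(
    aligned: AlignedRates,
    policy: np.ndarray | None = None,
    include_forced: bool = True,
    pool_neurons: bool = True,
) -> tuple[CPDResult, dict[int, CPDResult]]:
    """Run the CPD regression separately per problem and average.

    ``policy`` is a per-trial vector aligned with ``aligned.trials`` (nan on
    invalid trials, which are dropped together with their rates).
    Returns ``(average, per_problem)``; the average spans the regressors
    present in every problem.
    """
    per_problem: dict[int, CPDResult] = {}
    for pi in sorted(aligned.trials["problem_index"].unique()):
        mask = (aligned.trials["problem_index"] == pi).to_numpy()
        if not include_forced:
            mask &= ~aligned.trials["forced"].to_numpy().astype(bool)
        pol = None
        if policy is not None:
            pol = np.asarray(policy, float)[mask]
            ok = ~np.isnan(pol)
            idx = np.where(mask)[0][ok]
            mask = np.zeros(len(aligned.trials), dtype=bool)
            mask[idx] = True
            pol = pol[ok]
        sub = aligned.select_trials(mask)
        design = build_design(sub.trials, policy=pol)
        per_problem[int(pi)] = cpd_timecourse(sub, design, pool_neurons=pool_neurons)

    common = [r for r in next(iter(per_problem.values())).regressors
              if all(r in res.regressors for res in per_problem.values())]
    avg = np.mean([np.vstack([res.series(r) for r in common])
                   for res in per_problem.values()], axis=0)
    return (CPDResult(cpd=avg, regressors=common, grid_times=aligned.grid.times),
            per_problem)


def roll_null(
    rates: AlignedRates | np.ndarray,
    design: DesignMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    pool_neurons: bool = True,
) -> CPDResult:
    """Trial-roll null distribution and peak-corrected CPD thresholds.

    Each permutation rolls the trial axis of the rates by one shared random
    offset and recomputes the CPD; the 95th/99th percentiles of the
    per-permutation peak over timepoints give corrected thresholds.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y3 = rates.rates if isinstance(rates, AlignedRates) else np.asarray(rates, float)
    n_trials = Y3.shape[1]
    if n_trials < 3:
        raise ValueError("need at least 3 trials to roll")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = cpd_timecourse(Y3, design, pool_neurons=pool_neurons)
    peaks = np.empty((n_perm, len(design.regressors)))
    for p in range(n_perm):
        off = int(rng.integers(1, n_trials))
        rolled = np.roll(Y3, off, axis=1)
        res = cpd_timecourse(rolled, design, pool_neurons=pool_neurons)
        peaks[p] = res.cpd.max(axis=1)
    observed.threshold_95 = np.percentile(peaks, 95, axis=0)
    observed.threshold_99 = np.percentile(peaks, 99, axis=0)
    observed.grid_times = rates.grid.times if isinstance(rates, AlignedRates) else None
    return observed
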