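"""Cross-problem generalization of the neural policy representation.

For each problem, choice type (A or B trials analyzed separately — only the
B port moves between problems) and warp-grid timepoint, every neuron's rate
is regressed on the policy (centered within the fitted subset) and the trial
outcome, with a constant; the current-trial choice predictor is dropped
because the subset conditions on it. The vector of policy coefficients over
neurons is the policy representation at that (problem, timepoint).

Policy representations generalize across problems to the extent that these
beta vectors correlate across problem pairs; the timepoint x timepoint
correlation matrix (averaged over problem pairs) has a large diagonal sum
when the same neurons code policy with the same sign at the same trial
stage in every problem.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from revgen.alignment import AlignedRates

__all__ = [
    "BetaMap",
    "PolicyCorrelationMatrix",
    "policy_beta_maps",
    "policy_correlation",
    "diagonal_statistic",
]


@dataclass
class BetaMap:
    """beta[problem, timepoint, neuron] policy coefficients."""

    beta: np.ndarray
    problems: list[int]
    choice_type: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta map contains non-finite entries")


@dataclass
class PolicyCorrelationMatrix:
    """timepoint x timepoint correlations averaged over problem pairs."""

    values: np.ndarray            # nan where a beta vector had zero variance
    choice_type: str


def policy_beta_maps(
    aligned: AlignedRates,
    policy: np.ndarray,
    choice_type: str,
    min_trials: int = 10,
) -> BetaMap:
    """Per-problem, per-timepoint policy betas on one choice type.

    ``policy`` is a per-trial P(choose A) vector aligned with
    ``aligned.trials`` (nan marks trials without a valid estimate; they are
    excluded).
    """
    if choice_type not in ("A", "B"):
        raise ValueError("choice_type must be 'A' or 'B'")
    policy = np.asarray(policy, float)
    trials = aligned.trials
    problems = sorted(int(p) for p in trials["problem_index"].unique())
    T, n_neurons = aligned.grid.n_timepoints, aligned.n_neurons
    beta = np.zeros((len(problems), T, n_neurons))

    for k, p in enumerate(problems):
        mask = ((trials["problem_index"] == p)
                & (trials["choice"] == choice_type)).to_numpy()
        mask &= ~np.isnan(policy)
        n = int(mask.sum())
        if n < min_trials:
            raise ValueError(
                f"problem {p} has only {n} valid {choice_type} trials "
                f"(need >= {min_trials})")
        pol = policy[mask]
        if np.ptp(pol) < 1e-12:
            raise ValueError(f"policy constant within problem {p} "
                             f"{choice_type} trials")
        out = np.where(trials.loc[mask, "outcome"].to_numpy() == "reward",
                       1.0, -1.0)
        X = np.column_stack([np.ones(n), pol - pol.mean(), out])
        # rates: (neurons, n, T) -> solve all neurons x timepoints at once
        Y = aligned.rates[:, mask, :].reshape(n_neurons, n, T)
        Y2 = np.moveaxis(Y, 1, 0).reshape(n, n_neurons * T)
        coef, *_ = np.linalg.lstsq(X, Y2, rcond=None)
        beta[k] = coef[1].reshape(n_neurons, T).T
    return BetaMap(beta=beta, problems=problems, choice_type=choice_type)


def policy_correlation(maps: BetaMap) -> PolicyCorrelationMatrix:
    """Average across-problem-pair correlation of beta vectors.

    For every ordered problem pair (i, j), i != j, and every timepoint pair
    (t1, t2), the Pearson correlation across neurons of beta[i, t1] with
    beta[j, t2]; averaging over ordered pairs symmetrizes the matrix. Cells
    involving a zero-variance beta vector are nan.
    """
    B = maps.beta
    n_prob, T, n_neurons = B.shape
    if n_neurons < 3:
        raise ValueError("need at least 3 neurons")
    Bc = B - B.mean(axis=2, keepdims=True)
    sd = Bc.std(axis=2)
    acc = np.zeros((T, T))
    cnt = np.zeros((T, T))
    for i, j in permutations(range(n_prob), 2):
        cov = Bc[i] @ Bc[j].T / n_neurons
        denom = np.outer(sd[i], sd[j])
        ok = denom > 1e-15
        acc[ok] += (cov[ok] / denom[ok])
        cnt += ok
    with np.errstate(invalid="ignore"):
        vals = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return PolicyCorrelationMatrix(values=vals, choice_type=maps.choice_type)


def diagonal_statistic(matrix: PolicyCorrelationMatrix | np.ndarray) -> float:
    """Sum of the diagonal of the policy correlation matrix (nan-skipped)."""
    v = matrix.values if isinstance(matrix, PolicyCorrelationMatrix) else np.asarray(matrix)
    if v.ndim != 2 or v.shape[0] != v.shape[1]:
        raise ValueError("need a square matrix")
    d = np.diag(v)
    return float(np.nansum(d))
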