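"""Behavioral metrics, the choice-history logistic regression and the policy.

The choice-history regression predicts each free-choice trial's choice (A vs
B) from the previous ``n_lags`` trials' choices, outcomes and choice x
outcome interactions, all coded +/-1. Its in-sample predicted probability of
choosing A on each trial is the animal's *policy* — the cross-trial learning
signal used as a neural regressor downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

from revgen.synthetic import TaskConfig

__all__ = [
    "HistoryWeights",
    "PolicyTrace",
    "FitError",
    "history_design",
    "fit_choice_history",
    "estimate_policy",
    "performance_metrics",
    "fit_learning_curve",
    "LearningCurveFit",
]


class FitError(RuntimeError):
    pass


@dataclass
class HistoryWeights:
    """Fitted lag weights of the choice-history logistic regression."""

    n_lags: int
    intercept: float
    w_choice: np.ndarray        # lag 1 first
    w_outcome: np.ndarray
    w_interaction: np.ndarray
    log_likelihood: float
    n_trials: int

    @property
    def flat(self) -> np.ndarray:
        """[intercept, w_choice, w_outcome, w_interaction] as one vector."""
        return np.concatenate([[self.intercept], self.w_choice,
                               self.w_outcome, self.w_interaction])


@dataclass
class PolicyTrace:
    """Per-trial P(choose A); trials without full history are invalid."""

    p_choose_a: np.ndarray      # nan where invalid
    valid: np.ndarray           # bool mask

    def __post_init__(self) -> None:
        ok = self.p_choose_a[self.valid]
        if ok.size and (np.any(ok < 0) or np.any(ok > 1)):
            raise ValueError("policy probabilities must lie in [0, 1]")


def history_design(trials: pd.DataFrame, n_lags: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lagged +/-1 design for the history regression.

    Returns ``(X, y, valid)`` over all trials: ``X`` has columns
    [choice lags 1..L, outcome lags 1..L, interaction lags 1..L] (no
    constant), ``y`` is the current choice (1 = A), and ``valid`` flags
    trials with a complete history. History includes forced trials (they
    are real choices and outcomes).
    """
    c = np.where(trials["choice"].to_numpy() == "A", 1.0, -1.0)
    o = np.where(trials["outcome"].to_numpy() == "reward", 1.0, -1.0)
    n = len(trials)
    X = np.zeros((n, 3 * n_lags))
    for lag in range(1, n_lags + 1):
        X[lag:, lag - 1] = c[:-lag]
        X[lag:, n_lags + lag - 1] = o[:-lag]
        X[lag:, 2 * n_lags + lag - 1] = c[:-lag] * o[:-lag]
    valid = np.arange(n) >= n_lags
    y = (c > 0).astype(float)
    return X, y, valid


def fit_choice_history(
    trials: pd.DataFrame,
    n_lags: int = 12,
    free_only: bool = True,
    ridge: float = 0.0,
) -> HistoryWeights:
    """Maximum-likelihood fit of the choice-history logistic regression.

    Forced trials are excluded as the predicted trial when ``free_only``
    (default) but always enter the history. ``ridge`` adds an optional L2
    penalty (per-observation) for separable data.
    """
    X, y, valid = history_design(trials, n_lags)
    mask = valid.copy()
    if free_only and "forced" in trials:
        mask &= ~trials["forced"].to_numpy().astype(bool)
    n_used = int(mask.sum())
    n_params = 3 * n_lags + 1
    if n_used < 10 * n_params:
        warnings.warn(
            f"only {n_used} usable trials for {n_params} parameters; "
            f"coefficients may be poorly determined", stacklevel=2)
    Xd = sm.add_constant(X[mask], has_constant="add")
    model = sm.Logit(y[mask], Xd)
    try:
        if ridge > 0:
            res = model.fit_regularized(alpha=ridge * n_used, L1_wt=0.0, disp=0)
        else:
            res = model.fit(disp=0, maxiter=200)
    except Exception as e:  # pragma: no cover - statsmodels raises various types
        raise FitError(f"logistic fit failed ({e}); consider the ridge flag") from e
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
        raise FitError("fit diverged (perfect separation?); use the ridge flag")
    return HistoryWeights(
        n_lags=n_lags,
        intercept=float(params[0]),
        w_choice=params[1:n_lags + 1].copy(),
        w_outcome=params[n_lags + 1:2 * n_lags + 1].copy(),
        w_interaction=params[2 * n_lags + 1:].copy(),
        log_likelihood=float(res.llf) if hasattr(res, "llf") else np.nan,
        n_trials=n_used,
    )


def estimate_policy(trials: pd.DataFrame, weights: HistoryWeights) -> PolicyTrace:
    """Per-trial P(choose A) from fitted history weights (deterministic)."""
    X, _, valid = history_design(trials, weights.n_lags)
    z = weights.intercept + X @ np.concatenate(
        [weights.w_choice, weights.w_outcome, weights.w_interaction])
    p = 1.0 / (1.0 + np.exp(-z))
    p[~valid] = np.nan
    return PolicyTrace(p_choose_a=p, valid=valid)


def performance_metrics(
    trials: pd.DataFrame,
    pokes: pd.DataFrame,
    task: TaskConfig | None = None,
    layouts=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-block trials-to-threshold and per-trial out-of-sequence pokes.

    Trials-to-threshold re-runs the reversal EMA (reset to 0.5 at each block
    start) over the recorded choices and counts trials until the first
    threshold crossing. Out-of-sequence pokes are 'in' events at the choice
    port the animal did *not* choose, between that trial's outcome and the
    next initiation.
    """
    task = task or TaskConfig()
    alpha, thr = task.ema_alpha, task.threshold

    block_rows = []
    for (pi, bi), grp in trials.groupby(["problem_index", "block_index"]):
        ema, t2t = 0.5, None
        correct = (grp["choice"] == grp["good_side"]).to_numpy()
        for i, corr in enumerate(correct, start=1):
            ema += alpha * (float(corr) - ema)
            if ema >= thr:
                t2t = i
                break
        block_rows.append({"problem_index": pi, "block_index": bi,
                           "n_trials": len(grp),
                           "trials_to_threshold": t2t})
    blocks = pd.DataFrame(block_rows)

    poke_t = pokes.loc[pokes["event"] == "in", "time"].to_numpy()
    poke_p = pokes.loc[pokes["event"] == "in", "port"].to_numpy()
    init_times = trials["initiation_time"].to_numpy()
    counts = np.zeros(len(trials), dtype=int)
    if layouts is not None:
        lay_by_problem = {l.problem_index: l for l in layouts}
        for i, tr in enumerate(trials.itertuples(index=False)):
            lay = lay_by_problem[tr.problem_index]
            other = lay.choice_B_port if tr.choice == "A" else lay.choice_A_port
            t_hi = init_times[i + 1] if i + 1 < len(trials) else np.inf
            sel = (poke_t > tr.outcome_time) & (poke_t < t_hi) & (poke_p == other)
            counts[i] = int(sel.sum())
    per_trial = pd.DataFrame({
        "trial_index": trials["trial_index"].to_numpy(),
        "problem_index": trials["problem_index"].to_numpy(),
        "block_index": trials["block_index"].to_numpy(),
        "out_of_sequence_pokes": counts,
    })
    return blocks, per_trial


@dataclass
class LearningCurveFit:
    amplitude: float            # b in a + b exp(-k x)
    rate: float                 # k
    asymptote: float            # a
    log_time_constant: float    # log(1/k)
    converged: bool
    identifiable: bool          # False when the series is flat (k meaningless)
    residual_sd: float = np.nan


def fit_learning_curve(series: np.ndarray) -> LearningCurveFit:
    """Least-squares fit of ``a + b exp(-k x)`` to a per-reversal series."""
    y = np.asarray(series, dtype=float)
    x = np.arange(len(y), dtype=float)
    if len(y) < 4:
        raise FitError("need at least 4 points to fit an exponential")

    spread = y.max() - y.min()
    if spread < 1e-12 or np.std(y) < 1e-3 * max(1.0, abs(np.mean(y))):
        return LearningCurveFit(amplitude=0.0, rate=np.nan,
                                asymptote=float(np.mean(y)),
                                log_time_constant=np.nan,
                                converged=True, identifiable=False,
                                residual_sd=float(np.std(y)))

    def f(x, a, b, k):
        return a + b * np.exp(-k * x)

    p0 = (float(y[-1]), float(y[0] - y[-1]), 1.0 / max(1.0, len(y) / 3))
    try:
        popt, _ = curve_fit(f, x, y, p0=p0, maxfev=20_000)
    except RuntimeError as e:
        raise FitError(f"exponential fit did not converge: {e}") from e
    a, b, k = (float(v) for v in popt)
    resid = y - f(x, a, b, k)
    return LearningCurveFit(
        amplitude=b, rate=k, asymptote=a,
        log_time_constant=float(np.log(1.0 / k)) if k > 0 else np.nan,
        converged=True, identifiable=abs(b) > 1e-8 and k > 0,
        residual_sd=float(np.std(resid)),
    )
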