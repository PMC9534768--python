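"""Information-theoretic surprise at problem switches.

For a neuron with baseline mean mu and standard deviation sigma estimated on
a 'train' window of trials, the surprise of a test epoch is the squared
z-distance

    s = (mean(test rates) - mu)^2 / sigma^2        (test-mean reading)

or, trial-resolved,

    s_i = (x_i - mu)^2 / sigma^2                   (per-trial reading).

Within-problem surprise uses the ten trials before a switch as the test and
the ten trials before those as the train; between-problem surprise scores
the twenty trials after the switch against the same train window. Abrupt
remapping shows up as between-problem surprise exceeding the within-problem
level right at the switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SurpriseResult", "surprise_timecourse"]


@dataclass
class SurpriseResult:
    """Per-switch surprise, averaged across neurons.

    ``within``/``between`` are the neuron-averaged test-mean statistics per
    switch. ``per_trial_offsets`` and ``per_trial`` give the trial-resolved
    time course (neuron- and switch-averaged) at offsets relative to the
    switch (negative = within-problem test trials, nonnegative = after the
    switch).
    """

    within: np.ndarray
    between: np.ndarray
    per_trial_offsets: np.ndarray
    per_trial: np.ndarray
    skipped_switches: int = 0


def surprise_timecourse(
    trial_rates: np.ndarray,
    switch_points,
    train_n: int = 10,
    test_n: int = 10,
    post_n: int = 20,
    sigma_floor: float = 0.1,
) -> SurpriseResult:
    """Surprise at each problem switch.

    ``trial_rates`` is (n_neurons, n_trials) mean firing per trial;
    ``switch_points`` are trial indices of the first trial of each new
    problem. Switches without ``train_n + test_n`` preceding and ``post_n``
    following trials are skipped (counted in the result). Baseline standard
    deviations are floored at ``sigma_floor`` Hz.
    """
    R = np.atleast_2d(np.asarray(trial_rates, float))
    n_trials = R.shape[1]
    offsets = np.arange(-test_n, post_n)
    within, between = [], []
    per_trial_acc = np.zeros(len(offsets))
    n_used = 0
    skipped = 0

    for s in switch_points:
        s = int(s)
        if s - train_n - test_n < 0 or s + post_n > n_trials:
            skipped += 1
            continue
        train = R[:, s - train_n - test_n: s - test_n]
        mu = train.mean(axis=1)
        sigma = np.maximum(train.std(axis=1, ddof=1), sigma_floor)
        test_w = R[:, s - test_n: s]
        test_b = R[:, s: s + post_n]
        within.append(np.mean((test_w.mean(axis=1) - mu) ** 2 / sigma ** 2))
        between.append(np.mean((test_b.mean(axis=1) - mu) ** 2 / sigma ** 2))
        seg = R[:, s - test_n: s + post_n]
        per_trial_acc += np.mean((seg - mu[:, None]) ** 2 / sigma[:, None] ** 2,
                                 axis=0)
        n_used += 1

    if n_used:
        per_trial_acc /= n_used
    return SurpriseResult(
        within=np.asarray(within), between=np.asarray(between),
        per_trial_offsets=offsets, per_trial=per_trial_acc,
        skipped_switches=skipped,
    )
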