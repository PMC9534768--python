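"""Group-level permutation inference with peak-over-time correction.

Between-region contrasts are tested by shuffling recording *units* —
sessions, or animals for the stricter random-effects test — between the two
region labels, recomputing the statistic per shuffle. For time-series
statistics, each permutation contributes its peak over timepoints to the
null, which controls the family-wise error over timepoints. When the number
of distinct reassignments is small the test enumerates them exhaustively
(exact test); otherwise it Monte-Carlo samples with the add-one p-value so
p is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = ["PermutationResult", "group_permutation"]


@dataclass
class PermutationResult:
    observed: np.ndarray          # scalar (0-d) or time series
    observed_peak: float
    null_peaks: np.ndarray
    p_value: float
    n_perm: int
    exact: bool
    level: str
    sided: str

    @property
    def threshold_95(self) -> float:
        return float(np.percentile(self.null_peaks, 95))


def _peak(stat: np.ndarray, sided: str) -> float:
    a = np.atleast_1d(np.asarray(stat, float))
    if sided == "two":
        return float(np.nanmax(np.abs(a)))
    if sided == "greater":
        return float(np.nanmax(a))
    if sided == "less":
        return float(np.nanmax(-a))
    raise ValueError(f"sided must be 'two', 'greater' or 'less', got {sided!r}")


def group_permutation(
    stat_fn,
    units_a: list,
    units_b: list,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
    sided: str = "two",
    level: str = "session",
) -> PermutationResult:
    """Permutation test of ``stat_fn(units_a, units_b)`` under label shuffles.

    ``stat_fn`` maps two unit collections (lists of per-session or
    per-animal data) to a scalar or a time series; for time series the null
    is built from per-permutation peaks over timepoints. Units are shuffled
    between groups preserving group sizes. If the number of distinct
    assignments is at most ``n_perm`` the test is exact (all assignments
    enumerated, the observed one included); otherwise Monte-Carlo with
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    na, nb = len(units_a), len(units_b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 units per group")
    pool = list(units_a) + list(units_b)
    n = na + nb

    observed = np.asarray(stat_fn(units_a, units_b), float)
    obs_peak = _peak(observed, sided)

    n_assign = comb(n, na)
    min_p = 1.0 / n_assign
    if min_p > 0.05:
        warnings.warn(
            f"only {n_assign} distinct assignments at the {level} level; "
            f"minimum attainable p = {min_p:.3g} > 0.05", stacklevel=2)

    exact = n_assign <= n_perm
    null_peaks = []
    if exact:
        for idx_a in combinations(range(n), na):
            set_a = set(idx_a)
            ua = [pool[i] for i in idx_a]
            ub = [pool[i] for i in range(n) if i not in set_a]
            null_peaks.append(_peak(np.asarray(stat_fn(ua, ub), float), sided))
        null_peaks = np.asarray(null_peaks)
        p = float(np.mean(null_peaks >= obs_peak - 1e-12))
        n_used = n_assign
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        for _ in range(n_perm):
            order = rng.permutation(n)
            ua = [pool[i] for i in order[:na]]
            ub = [pool[i] for i in order[na:]]
            null_peaks.append(_peak(np.asarray(stat_fn(ua, ub), float), sided))
        null_peaks = np.asarray(null_peaks)
        p = float((1 + np.sum(null_peaks >= obs_peak - 1e-12)) / (1 + n_perm))
        n_used = n_perm

    return PermutationResult(
        observed=observed, observed_peak=obs_peak, null_peaks=null_peaks,
        p_value=p, n_perm=n_used, exact=exact, level=level, sided=sided,
    )
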