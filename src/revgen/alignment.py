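"""Time-in-trial alignment: linear warp and kernel firing-rate estimation.

Trials are self-paced, so the initiation-to-choice interval varies. Spike
times between initiation and choice are mapped linearly onto the median
interval; activity before initiation (anchored to initiation) and after
choice (anchored to choice) is shifted rigidly. Warped-interval spikes carry
weight median/actual — the time-scaling factor applied by the warp — so the
expected weighted count per trial equals rate x median interval regardless
of the trial's true duration. Rates are evaluated on a fixed 40-ms grid from
1 s before initiation to 1 s after outcome with a Gaussian kernel
(sigma = 40 ms, truncated at 4 sigma), in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["WarpGrid", "AlignedRates", "warp_and_rate", "spikes_by_neuron"]

_KERNEL_TRUNC = 4.0


@dataclass(frozen=True)
class WarpGrid:
    """Common warped-time grid with event anchors.

    Warped time 0 is trial initiation; choice sits at ``median_interval`` and
    outcome ``cue_duration_s`` later (the cue length is fixed, so the
    choice-to-outcome segment is never warped).
    """

    median_interval: float
    spacing: float = 0.040
    pre_s: float = 1.0
    post_s: float = 1.0
    cue_duration_s: float = 0.25

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.median_interval <= 0:
            raise ValueError("median interval must be positive")

    @property
    def times(self) -> np.ndarray:
        n = int(round((self.pre_s + self.median_interval
                       + self.cue_duration_s + self.post_s) / self.spacing)) + 1
        return -self.pre_s + self.spacing * np.arange(n)

    @property
    def n_timepoints(self) -> int:
        return len(self.times)

    def _nearest(self, t: float) -> int:
        return int(round((t + self.pre_s) / self.spacing))

    @property
    def initiation_index(self) -> int:
        return self._nearest(0.0)

    @property
    def choice_index(self) -> int:
        return self._nearest(self.median_interval)

    @property
    def outcome_index(self) -> int:
        return self._nearest(self.median_interval + self.cue_duration_s)


@dataclass
class AlignedRates:
    """rate[neuron, trial, timepoint] tensor (Hz) plus labels."""

    rates: np.ndarray
    grid: WarpGrid
    neuron_ids: np.ndarray
    trials: pd.DataFrame          # label rows aligned with axis 1

    def __post_init__(self) -> None:
        if self.rates.shape[1] != len(self.trials):
            raise ValueError("trial axis does not match label rows")
        if self.rates.shape[2] != self.grid.n_timepoints:
            raise ValueError("time axis does not match grid")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    def select_trials(self, mask: np.ndarray) -> "AlignedRates":
        return AlignedRates(self.rates[:, mask, :], self.grid,
                            self.neuron_ids, self.trials.loc[mask].reset_index(drop=True))


def spikes_by_neuron(spikes: pd.DataFrame, neuron_ids) -> list[np.ndarray]:
    """Split a long spike table into per-neuron sorted time arrays."""
    groups = {nid: grp["spike_time"].to_numpy()
              for nid, grp in spikes.groupby("neuron_id")}
    return [np.sort(groups.get(nid, np.empty(0))) for nid in neuron_ids]


def warp_and_rate(
    spikes: pd.DataFrame,
    trials: pd.DataFrame,
    neuron_ids=None,
    grid: WarpGrid | None = None,
    sigma: float = 0.040,
    spacing: float = 0.040,
    cue_duration_s: float = 0.25,
) -> AlignedRates:
    """Warp each trial onto the common grid and estimate kernel firing rates.

    ``grid`` may be passed explicitly (e.g. built from the pooled median of
    several sessions so pseudopopulations share a time base); otherwise the
    median initiation-to-choice interval of ``trials`` defines it. Trials
    with a non-positive interval are excluded with a warning.
    """
    if neuron_ids is None:
        neuron_ids = np.unique(spikes["neuron_id"])
    neuron_ids = np.asarray(neuron_ids)
    trains = spikes_by_neuron(spikes, neuron_ids)

    init = trials["initiation_time"].to_numpy(float)
    choice = trials["choice_time"].to_numpy(float)
    intervals = choice - init
    keep = intervals > 0
    if not np.all(keep):
        import warnings
        warnings.warn(f"excluding {int((~keep).sum())} trials with "
                      f"non-positive initiation-to-choice interval", stacklevel=2)
    trials = trials.loc[keep].reset_index(drop=True)
    init, choice, intervals = init[keep], choice[keep], intervals[keep]

    if grid is None:
        grid = WarpGrid(median_interval=float(np.median(intervals)),
                        spacing=spacing, cue_duration_s=cue_duration_s)
    gt = grid.times
    med = grid.median_interval
    halo = _KERNEL_TRUNC * sigma
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))

    n_neurons, n_trials, n_t = len(neuron_ids), len(trials), len(gt)
    rates = np.zeros((n_neurons, n_trials, n_t))

    for k in range(n_trials):
        t_i, t_c, L = init[k], choice[k], intervals[k]
        stretch = med / L
        lo = t_i - grid.pre_s - halo
        hi = t_c + grid.cue_duration_s + grid.post_s + halo
        seg_t, seg_w, seg_n = [], [], []
        for n, train in enumerate(trains):
            a, b = np.searchsorted(train, (lo, hi))
            if b <= a:
                continue
            s = train[a:b]
            warped = np.where(
                s <= t_i, s - t_i,
                np.where(s <= t_c, (s - t_i) * stretch, med + (s - t_c)))
            w = np.where((s > t_i) & (s <= t_c), stretch, 1.0)
            seg_t.append(warped)
            seg_w.append(w)
            seg_n.append(np.full(len(s), n))
        if not seg_t:
            continue
        st = np.concatenate(seg_t)
        sw = np.concatenate(seg_w)
        sn = np.concatenate(seg_n)
        d = gt[None, :] - st[:, None]
        contrib = np.where(np.abs(d) <= halo,
                           np.exp(-0.5 * (d / sigma) ** 2), 0.0)
        contrib *= norm * sw[:, None]
        np.add.at(rates[:, k, :], sn, contrib)

    return AlignedRates(rates=rates, grid=grid, neuron_ids=neuron_ids,
                        trials=trials)
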