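"""Trajectory cleaning and kinematic residualization of firing rates.

Tracking artifacts (occlusions at ports) are removed in three passes:
low-likelihood samples, samples adjacent to implausible position jumps
(larger than ten robust standard deviations of the inter-frame displacement,
estimated from the 16th/84th percentile spread), and samples not in
contiguous runs of at least five frames. Gaps are filled by minimizing a
quadratic cost — the summed squared nose derivatives (favoring linear
interpolation) plus a more strongly weighted penalty on the difference
between nose and ear derivatives (the ears are rarely occluded, and their
motion tracks the nose).

Because firing may depend nonlinearly on 2D position (place fields), the
position confound is captured by Gaussian radial-basis occupancy functions
(sigma = 1 cm, centers sampled from visited coordinates), reduced to their
leading orthogonal components; residualizing rates on these components plus
speed and acceleration removes linear position/kinematics influences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

__all__ = [
    "Trajectory",
    "OccupancyBasis",
    "prepare_trajectory",
    "occupancy_components",
    "residualize",
    "residualize_aligned",
    "TrajectoryError",
]


class TrajectoryError(ValueError):
    pass


@dataclass
class Trajectory:
    time: np.ndarray
    xy: np.ndarray                # (n, 2) cm, gaps filled
    speed: np.ndarray             # cm/s
    acceleration: np.ndarray      # cm/s^2 (derivative of speed)
    valid_fraction: float         # fraction of frames kept before filling


@dataclass
class OccupancyBasis:
    centers: np.ndarray           # (n_basis, 2)
    sigma_cm: float
    components: np.ndarray        # (n_frames, n_components) orthogonal scores
    explained_variance_ratio: np.ndarray

    @property
    def explained_total(self) -> float:
        return float(self.explained_variance_ratio.sum())


def _clean_mask(xy: np.ndarray, likelihood: np.ndarray,
                likelihood_min: float, jump_mult: float,
                min_run: int) -> np.ndarray:
    ok = likelihood >= likelihood_min
    d = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    d_ok = d[ok[:-1] & ok[1:]]
    if d_ok.size >= 10:
        q16, q84 = np.percentile(d_ok, [16, 84])
        robust_sd = (q84 - q16) / 2.0
        # floor at half the median step so perfectly smooth motion (zero
        # displacement spread) does not flag every frame as a jump
        scale = max(robust_sd, 0.5 * float(np.median(d_ok)))
        jump = d > jump_mult * scale if scale > 0 else np.zeros_like(d, bool)
        bad = np.zeros(len(xy), dtype=bool)
        bad[:-1] |= jump
        bad[1:] |= jump
        ok &= ~bad
    # keep only contiguous runs of at least min_run frames
    runs = np.split(np.arange(len(ok)), np.where(np.diff(ok))[0] + 1)
    for run in runs:
        if ok[run[0]] and len(run) < min_run:
            ok[run] = False
    return ok


def _fill_gaps(xy: np.ndarray, ok: np.ndarray, ear: np.ndarray,
               smooth_weight: float = 1.0, ear_weight: float = 10.0) -> np.ndarray:
    """Fill missing samples by the quadratic derivative-matching cost."""
    n = len(xy)
    if ok.all():
        return xy.copy()
    D = sp.diags([-np.ones(n - 1), np.ones(n - 1)], [0, 1],
                 shape=(n - 1, n), format="csr")
    A_full = (smooth_weight + ear_weight) * (D.T @ D)
    out = xy.copy()
    free = np.where(~ok)[0]
    fixed = np.where(ok)[0]
    for dim in range(2):
        b_full = ear_weight * (D.T @ (D @ ear[:, dim]))
        A_ff = A_full[free][:, free]
        b = b_full[free] - A_full[free][:, fixed] @ xy[fixed, dim]
        out[free, dim] = spsolve(A_ff.tocsc(), b)
    return out


def prepare_trajectory(
    tracking: pd.DataFrame,
    likelihood_min: float = 0.9,
    jump_mult: float = 10.0,
    min_run: int = 5,
    smooth_weight: float = 1.0,
    ear_weight: float = 10.0,
    max_removed_fraction: float = 0.8,
) -> Trajectory:
    """Clean and gap-fill the nose trajectory; derive speed and acceleration."""
    t = tracking["time"].to_numpy(float)
    nose = tracking[["nose_x", "nose_y"]].to_numpy(float)
    ears = 0.5 * (tracking[["left_ear_x", "left_ear_y"]].to_numpy(float)
                  + tracking[["right_ear_x", "right_ear_y"]].to_numpy(float))
    lik = tracking["nose_likelihood"].to_numpy(float)

    ok = _clean_mask(nose, lik, likelihood_min, jump_mult, min_run)
    removed = 1.0 - ok.mean()
    if removed > max_removed_fraction:
        raise TrajectoryError(
            f"{removed:.0%} of samples removed by cleaning; review the "
            f"likelihood/jump thresholds")

    # ears may have their own dropouts: linear-interpolate them first
    ear_lik = np.minimum(tracking["left_ear_likelihood"].to_numpy(float),
                         tracking["right_ear_likelihood"].to_numpy(float))
    ear_ok = ear_lik >= likelihood_min
    ear_ref = ears.copy()
    if not ear_ok.all() and ear_ok.any():
        for dim in range(2):
            ear_ref[~ear_ok, dim] = np.interp(t[~ear_ok], t[ear_ok],
                                              ears[ear_ok, dim])

    filled = _fill_gaps(nose, ok, ear_ref, smooth_weight, ear_weight)

    dt = float(np.median(np.diff(t)))
    vel = np.gradient(filled, dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    accel = np.gradient(speed, dt)
    return Trajectory(time=t, xy=filled, speed=speed, acceleration=accel,
                      valid_fraction=float(ok.mean()))


def occupancy_components(
    xy: np.ndarray,
    n_basis: int = 200,
    sigma_cm: float = 1.0,
    n_components: int = 10,
    seed: int | np.random.Generator = 0,
) -> OccupancyBasis:
    """RBF occupancy activations reduced to orthogonal components."""
    if n_basis < n_components:
        raise ValueError("n_basis must be >= n_components")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xy = np.asarray(xy, float)
    idx = rng.choice(len(xy), size=min(n_basis, len(xy)), replace=False)
    centers = xy[idx]
    d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    act = np.exp(-0.5 * d2 / sigma_cm ** 2)

    centered = act - act.mean(axis=0, keepdims=True)
    # principal components via SVD of the centered activation matrix
    U, S, _ = np.linalg.svd(centered, full_matrices=False)
    var = S ** 2
    ratio = var / var.sum()
    k = min(n_components, len(S))
    scores = U[:, :k] * S[:k]
    return OccupancyBasis(centers=centers, sigma_cm=sigma_cm,
                          components=scores,
                          explained_variance_ratio=ratio[:k])


def _kinematic_design(basis: OccupancyBasis, speed, acceleration) -> np.ndarray:
    return np.column_stack([
        basis.components,
        np.asarray(speed, float),
        np.asarray(acceleration, float),
        np.ones(len(basis.components)),
    ])


def residualize(
    rates: np.ndarray,
    basis: OccupancyBasis,
    speed: np.ndarray,
    acceleration: np.ndarray,
    ridge_fallback: float = 1e-8,
) -> np.ndarray:
    """OLS residuals of each signal on [occupancy components, speed,
    acceleration, constant]; rows are signals, columns time samples."""
    R = np.atleast_2d(np.asarray(rates, float))
    X = _kinematic_design(basis, speed, acceleration)
    if R.shape[1] != X.shape[0]:
        raise ValueError("rates and predictors are not time-aligned")
    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1e12:
        warnings.warn("collinear kinematic predictors; applying tiny ridge",
                      stacklevel=2)
        XtX = XtX + ridge_fallback * np.trace(XtX) / XtX.shape[0] * np.eye(XtX.shape[0])
    beta = np.linalg.solve(XtX, X.T @ R.T)
    return R - (X @ beta).T


def residualize_aligned(aligned, trials, trajectory: Trajectory,
                        basis: OccupancyBasis):
    """Remove kinematic confounds from an aligned-rate tensor in place of
    the raw rates.

    Each warped grid point of each trial is mapped back to its session time
    (inverting the warp), the kinematic predictors are sampled there, and
    every neuron's rate over all (trial, timepoint) samples is residualized
    jointly. Returns a new AlignedRates with the same labels and grid.
    """
    from revgen.alignment import AlignedRates

    grid = aligned.grid
    gt = grid.times
    med = grid.median_interval
    init = trials["initiation_time"].to_numpy(float)
    choice = trials["choice_time"].to_numpy(float)
    L = choice - init

    # actual session time of each (trial, warped timepoint)
    tau = gt[None, :]
    t_actual = np.where(
        tau <= 0, init[:, None] + tau,
        np.where(tau <= med, init[:, None] + tau * (L[:, None] / med),
                 choice[:, None] + (tau - med)))
    flat_t = t_actual.ravel()

    tt = trajectory.time
    preds = [np.interp(flat_t, tt, basis.components[:, k])
             for k in range(basis.components.shape[1])]
    preds.append(np.interp(flat_t, tt, trajectory.speed))
    preds.append(np.interp(flat_t, tt, trajectory.acceleration))
    preds.append(np.ones(flat_t.size))
    X = np.column_stack(preds)

    n_neurons = aligned.n_neurons
    Y = aligned.rates.reshape(n_neurons, -1).T       # (samples, neurons)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = (Y - X @ beta).T.reshape(aligned.rates.shape)
    return AlignedRates(rates=resid, grid=grid, neuron_ids=aligned.neuron_ids,
                        trials=aligned.trials)
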