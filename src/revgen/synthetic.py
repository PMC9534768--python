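"""Synthetic session generator with known ground truth.

Three pieces compose a session:

* task logic — serial probabilistic reversal learning: three problems per
  session (one per port layout type), four reversal blocks per problem,
  reward probabilities 0.8/0.2, reversals triggered 5-15 trials after an
  exponential-moving-average (tau = 8 trials) of correct choices crosses
  75%, and one in four trials forced-choice;
* behavioral agent — a logistic policy over the recent history of choices,
  outcomes and choice x outcome interactions, the same functional form the
  analysis-side behavioral regression estimates;
* neural populations — inhomogeneous-Poisson neurons tuned to trial events,
  physical ports, problem x port interactions (remapping), outcome and the
  agent's policy, with every generative parameter stored in the neuron
  metadata so analyses can be scored against ground truth.

The ``pfc_like`` profile draws tuning once and reuses it in every problem
(problem-general coding); the ``ca1_like`` profile re-draws the port and
policy gains independently per problem (problem-specific coding).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from revgen.io_core import (
    LayoutSpec,
    SessionRecord,
    TRIAL_COLUMNS,
)

__all__ = [
    "TaskConfig",
    "AgentConfig",
    "PopulationConfig",
    "SimulationError",
    "STANDARD_LAYOUTS",
    "PORT_COORDS_CM",
    "simulate_behavior",
    "generate_population",
    "generate_spikes",
    "generate_tracking",
    "simulate_session",
]


class SimulationError(RuntimeError):
    pass


#: Concrete port assignments for the three layout types (ports 0-8 row-major
#: on the 3x3 wall). The A choice port is shared by all three; layout type 3
#: reuses the type-1 initiation port (I3 = I1) and the type-2 initiation port
#: as its B choice (B3 = I2).
STANDARD_LAYOUTS: dict[int, dict[str, int]] = {
    1: {"I": 1, "A": 3, "B": 5},
    2: {"I": 7, "A": 3, "B": 2},
    3: {"I": 1, "A": 3, "B": 7},
}

#: Physical port coordinates (cm) in the port-wall plane, 5 cm pitch.
PORT_COORDS_CM: dict[int, tuple[float, float]] = {
    p: (5.0 * (p % 3), 5.0 * (2 - p // 3)) for p in range(9)
}


@dataclass
class TaskConfig:
    reward_probs: tuple[float, float] = (0.8, 0.2)   # (good, bad)
    threshold: float = 0.75
    ema_tau: float = 8.0
    reversal_delay_range: tuple[int, int] = (5, 15)
    blocks_per_problem: int = 4
    problems_per_session: int = 3
    forced_fraction: float = 0.25
    cue_duration_s: float = 0.25
    iti_s: float = 2.0
    consume_s: float = 1.0            # time in port after outcome before ITI
    oos_poke_prob: float = 0.05       # out-of-sequence poke per trial
    layout_sequence: tuple[int, ...] | None = None   # None -> random order
    max_trials: int = 10_000

    def __post_init__(self) -> None:
        good, bad = self.reward_probs
        if not (0.0 < bad < good < 1.0):
            raise ValueError("reward_probs must satisfy 0 < bad < good < 1")
        lo, hi = self.reversal_delay_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer)) and lo <= hi):
            raise ValueError("reversal_delay_range must be integers low <= high")

    @property
    def ema_alpha(self) -> float:
        return 1.0 - float(np.exp(-1.0 / self.ema_tau))


def _default_interaction_weights(n_lags: int) -> np.ndarray:
    # exponentially decaying credit assignment; strong enough that the agent
    # tracks the good port at ~85-90% correct under 0.8/0.2 schedules
    lags = np.arange(1, n_lags + 1)
    return 1.2 * np.exp(-(lags - 1) / 2.5)


@dataclass
class AgentConfig:
    """History-logistic behavioral agent.

    ``w_choice``/``w_outcome``/``w_interaction`` are lag-indexed (lag 1 first)
    and enter the choice logit with +/-1 coded history. The initiation-to-
    choice latency is log-normal (median ``latency_median_s``) truncated at
    ``latency_max_s``.
    """

    n_lags: int = 12
    w_choice: np.ndarray | None = None
    w_outcome: np.ndarray | None = None
    w_interaction: np.ndarray | None = None
    bias: float = 0.0
    latency_median_s: float = 0.5
    latency_sigma_log: float = 0.4
    latency_max_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n_lags < 1:
            raise ValueError("n_lags must be >= 1")
        if self.latency_median_s <= 0:
            raise ValueError("latency distribution must be strictly positive")
        L = self.n_lags
        if self.w_choice is None:
            w = np.zeros(L)
            w[0] = 0.3
            self.w_choice = w
        if self.w_outcome is None:
            self.w_outcome = np.zeros(L)
        if self.w_interaction is None:
            self.w_interaction = _default_interaction_weights(L)
        for name in ("w_choice", "w_outcome", "w_interaction"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (L,):
                raise ValueError(f"{name} must have length n_lags={L}")
            setattr(self, name, v)

    def choice_logit(self, choices: list[int], outcomes: list[int]) -> float:
        """Logit of P(choose A) given +/-1 coded history (most recent last)."""
        z = self.bias
        L = self.n_lags
        for lag in range(1, min(L, len(choices)) + 1):
            c, o = choices[-lag], outcomes[-lag]
            z += (self.w_choice[lag - 1] * c
                  + self.w_outcome[lag - 1] * o
                  + self.w_interaction[lag - 1] * c * o)
        return z

    def sample_latency(self, rng: np.random.Generator) -> float:
        mu = np.log(self.latency_median_s)
        while True:
            lat = float(rng.lognormal(mu, self.latency_sigma_log))
            if lat <= self.latency_max_s:
                return lat


def _session_layouts(task: TaskConfig, rng: np.random.Generator) -> list[LayoutSpec]:
    if task.layout_sequence is not None:
        order = list(task.layout_sequence)
    else:
        order = list(rng.permutation([1, 2, 3]))
    if len(order) < task.problems_per_session:
        order = (order * task.problems_per_session)[: task.problems_per_session]
    order = order[: task.problems_per_session]
    layouts = []
    for i, lt in enumerate(order, start=1):
        ports = STANDARD_LAYOUTS[int(lt)]
        layouts.append(LayoutSpec(
            problem_index=i, initiation_port=ports["I"],
            choice_A_port=ports["A"], choice_B_port=ports["B"],
            layout_type=int(lt),
        ))
    return layouts


def simulate_behavior(
    task: TaskConfig,
    agent: AgentConfig,
    seed: int | np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, list[LayoutSpec]]:
    """Simulate one session of behavior.

    Returns ``(trials, pokes, layouts)``. The trial table carries an extra
    ``policy_true`` column with the agent's P(choose A) on every trial — the
    generative policy signal used by the neural simulator and the target of
    policy-recovery analyses.

    Raises :class:`SimulationError` if the session does not complete within
    ``task.max_trials`` trials (an agent that never reaches threshold).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layouts = _session_layouts(task, rng)
    good_p, bad_p = task.reward_probs
    alpha = task.ema_alpha

    hist_c: list[int] = []   # +1 = A, -1 = B
    hist_o: list[int] = []   # +1 = reward, -1 = omission

    rows = []
    poke_rows = []
    t_clock = task.iti_s
    trial_index = 0

    for lay in layouts:
        good = "A" if rng.random() < 0.5 else "B"
        for block in range(task.blocks_per_problem):
            ema = 0.5
            crossed = False
            countdown = -1
            while True:
                if trial_index >= task.max_trials:
                    raise SimulationError(
                        f"session did not complete within the trial cap "
                        f"({task.max_trials} trials); agent never sustains "
                        f"threshold performance"
                    )
                p_a = 1.0 / (1.0 + np.exp(-agent.choice_logit(hist_c, hist_o)))
                forced = rng.random() < task.forced_fraction
                if forced:
                    forced_side = "A" if rng.random() < 0.5 else "B"
                    choice = forced_side
                else:
                    forced_side = ""
                    choice = "A" if rng.random() < p_a else "B"
                p_rew = good_p if choice == good else bad_p
                rewarded = rng.random() < p_rew

                correct = float(choice == good)
                ema += alpha * (correct - ema)

                hist_c.append(+1 if choice == "A" else -1)
                hist_o.append(+1 if rewarded else -1)

                init_t = t_clock
                choice_t = init_t + agent.sample_latency(rng)
                outcome_t = choice_t + task.cue_duration_s
                leave_t = outcome_t + task.consume_s
                t_clock = leave_t + task.iti_s

                init_port = lay.initiation_port
                choice_port = lay.choice_A_port if choice == "A" else lay.choice_B_port
                other_port = lay.choice_B_port if choice == "A" else lay.choice_A_port
                poke_rows.append((init_t, init_port, "in"))
                poke_rows.append((init_t + 0.15, init_port, "out"))
                poke_rows.append((choice_t, choice_port, "in"))
                poke_rows.append((leave_t, choice_port, "out"))
                if rng.random() < task.oos_poke_prob:
                    t_oos = leave_t + rng.uniform(0.2, task.iti_s - 0.2)
                    poke_rows.append((t_oos, other_port, "in"))
                    poke_rows.append((t_oos + 0.1, other_port, "out"))

                rows.append((
                    trial_index, lay.problem_index, block, good,
                    forced, forced_side, choice,
                    "reward" if rewarded else "omission",
                    init_t, choice_t, outcome_t, p_a,
                ))
                trial_index += 1

                if not crossed and ema >= task.threshold:
                    crossed = True
                    lo, hi = task.reversal_delay_range
                    countdown = int(rng.integers(lo, hi + 1))
                if crossed:
                    countdown -= 1
                    if countdown < 0:
                        break
            good = "B" if good == "A" else "A"

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS + ["policy_true"])
    pokes = pd.DataFrame(sorted(poke_rows), columns=["time", "port", "event"])
    return trials, pokes, layouts


# ---------------------------------------------------------------------------
# Neural populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationConfig:
    """Hyper-parameters of the tuning distributions for one profile.

    Gains are log-normal: a ``*_sd`` of 0 pins the gain at 1. Event kernels
    are Gaussian bumps anchored to initiation, choice or outcome; their
    effective amplitude is multiplied by the port and remap gains of the
    anchor port, so problem-specific profiles remap their event responses.
    """

    baseline_log_mean: float = np.log(4.0)
    baseline_log_sd: float = 0.4
    port_gain_sd: float = 0.1           # log-normal sd of per-port gain
    remap_gain_sd: float = 0.0          # per (problem, port); 0 -> no remapping
    redraw_per_problem: bool = False    # re-draw remap & policy gains per problem
    n_kernels_range: tuple[int, int] = (1, 3)
    kernel_width_range: tuple[float, float] = (0.06, 0.15)
    kernel_amp_range: tuple[float, float] = (1.0, 3.0)   # x baseline
    outcome_gain_sd: float = 0.2        # epoch gain, reward vs omission
    policy_gain_sd: float = 0.6
    n_problems: int = 3


PFC_LIKE = PopulationConfig(
    port_gain_sd=0.10, remap_gain_sd=0.0, redraw_per_problem=False,
    outcome_gain_sd=0.25, policy_gain_sd=0.6,
)
CA1_LIKE = PopulationConfig(
    port_gain_sd=0.80, remap_gain_sd=0.80, redraw_per_problem=True,
    n_kernels_range=(0, 2), kernel_amp_range=(0.5, 2.0),
    outcome_gain_sd=0.4, policy_gain_sd=0.6,
)

_PROFILES = {"pfc_like": PFC_LIKE, "ca1_like": CA1_LIKE}

_ANCHORS = ("initiation", "choice", "outcome")


def _draw_neuron_tuning(cfg: PopulationConfig, rng: np.random.Generator) -> dict:
    baseline = float(rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd))
    port_gain = {str(p): float(rng.lognormal(0.0, cfg.port_gain_sd)) for p in range(9)}

    n_draws = cfg.n_problems if cfg.redraw_per_problem else 1
    remap, policy_gain = [], []
    for _ in range(n_draws):
        remap.append({str(p): float(rng.lognormal(0.0, cfg.remap_gain_sd))
                      for p in range(9)})
        policy_gain.append(float(rng.normal(0.0, cfg.policy_gain_sd)))
    if n_draws == 1:
        remap = remap * cfg.n_problems
        policy_gain = policy_gain * cfg.n_problems

    n_k = int(rng.integers(cfg.n_kernels_range[0], cfg.n_kernels_range[1] + 1))
    kernels = []
    for _ in range(n_k):
        anchor = _ANCHORS[int(rng.integers(0, 3))]
        if anchor == "outcome":
            center = float(rng.uniform(0.05, 0.45))
        else:
            center = float(np.clip(rng.normal(0.0, 0.15), -0.5, 0.5))
        width = float(rng.uniform(*cfg.kernel_width_range))
        amp = baseline * float(rng.uniform(*cfg.kernel_amp_range))
        k = {"anchor": anchor, "center": center, "width": width, "amp": amp}
        if anchor == "outcome":
            # reward/omission differential amplitude; u near 0 or 1 gives
            # outcome-selective responses, shared across problems
            u = float(rng.uniform(0.0, 1.0))
            k["amp_reward"] = amp * 2.0 * u
            k["amp_omission"] = amp * 2.0 * (1.0 - u)
        kernels.append(k)

    outcome_gain = {
        "reward": float(rng.lognormal(0.0, cfg.outcome_gain_sd)),
        "omission": float(rng.lognormal(0.0, cfg.outcome_gain_sd)),
    }
    return {
        "baseline": baseline,
        "port_gain": port_gain,
        "remap_gain": remap,            # list indexed by problem-1
        "policy_gain": policy_gain,     # list indexed by problem-1
        "kernels": kernels,
        "outcome_gain": outcome_gain,
    }


def generate_population(
    n_neurons: int,
    profile: str | PopulationConfig = "pfc_like",
    seed: int | np.random.Generator = 0,
    region: str | None = None,
    animal_id: str = "synth",
    session_id: str = "s0",
) -> pd.DataFrame:
    """Draw neuron metadata (with full generative tuning) for one session.

    ``profile`` is ``"pfc_like"`` (tuning shared across problems, weak port
    gains), ``"ca1_like"`` (strong port gains, remap and policy gains
    re-drawn per problem) or a custom :class:`PopulationConfig`.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    if isinstance(profile, PopulationConfig):
        cfg, label = profile, "custom"
    else:
        try:
            cfg = _PROFILES[profile]
        except KeyError:
            raise ValueError(f"unknown profile {profile!r}; "
                             f"expected one of {sorted(_PROFILES)} or a "
                             f"PopulationConfig") from None
        label = profile
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for i in range(n_neurons):
        tuning = _draw_neuron_tuning(cfg, rng)
        rows.append({
            "neuron_id": f"{session_id}_n{i:03d}",
            "region": region or label,
            "animal_id": animal_id,
            "session_id": session_id,
            "tuning": json.dumps(tuning),
        })
    return pd.DataFrame(rows)


# epoch geometry (s, relative to the anchoring event)
_INIT_EPOCH = (-0.25, 0.15)
_CHOICE_EPOCH_PRE = 0.15        # before choice poke
_CHOICE_EPOCH_POST = 0.80       # after outcome
_OUTCOME_EPOCH = 0.60


def _neuron_intensity(
    tuning: dict,
    bins: np.ndarray,
    dt: float,
    trials: pd.DataFrame,
    layouts: list[LayoutSpec],
) -> np.ndarray:
    """Intensity (Hz) of one neuron on the session time grid.

    lambda(t) = clip0( policy_mod x (baseline x epoch gains + event kernels) )
    where epoch gains apply while the animal occupies a port (port gain x
    problem remap gain, plus an outcome gain during reward consumption) and
    kernel amplitudes inherit the gains of their anchor port.
    """
    lay_by_problem = {l.problem_index: l for l in layouts}
    lam = np.full(bins.shape, tuning["baseline"], dtype=float)
    pg = tuning["port_gain"]
    n_bins = len(bins)

    def sl(t0, t1):
        i0 = max(0, int(np.floor((t0 - bins[0]) / dt)))
        i1 = min(n_bins, int(np.ceil((t1 - bins[0]) / dt)))
        return slice(i0, max(i0, i1))

    for tr in trials.itertuples(index=False):
        lay = lay_by_problem[tr.problem_index]
        j = tr.problem_index - 1
        rg = tuning["remap_gain"][j]
        init_port = lay.initiation_port
        choice_port = lay.choice_A_port if tr.choice == "A" else lay.choice_B_port
        t_i, t_c, t_o = tr.initiation_time, tr.choice_time, tr.outcome_time

        gain_i = pg[str(init_port)] * rg[str(init_port)]
        gain_c = pg[str(choice_port)] * rg[str(choice_port)]
        lam[sl(t_i + _INIT_EPOCH[0], t_i + _INIT_EPOCH[1])] *= gain_i
        lam[sl(t_c - _CHOICE_EPOCH_PRE, t_o + _CHOICE_EPOCH_POST)] *= gain_c
        lam[sl(t_o, t_o + _OUTCOME_EPOCH)] *= tuning["outcome_gain"][tr.outcome]

        for k in tuning["kernels"]:
            if k["anchor"] == "initiation":
                t_a, port = t_i, init_port
                amp = k["amp"]
            elif k["anchor"] == "choice":
                t_a, port = t_c, choice_port
                amp = k["amp"]
            else:
                t_a, port = t_o, choice_port
                amp = k["amp_reward"] if tr.outcome == "reward" else k["amp_omission"]
            amp_eff = amp * pg[str(port)] * rg[str(port)]
            if amp_eff == 0.0:
                continue
            w = k["width"]
            s = sl(t_a + k["center"] - 4 * w, t_a + k["center"] + 4 * w)
            if s.stop > s.start:
                x = bins[s] - (t_a + k["center"])
                lam[s] += amp_eff * np.exp(-0.5 * (x / w) ** 2)

        g_pol = tuning["policy_gain"][j]
        if g_pol != 0.0:
            s = sl(t_i - 1.0, t_o + 1.0)
            lam[s] *= max(0.0, 1.0 + g_pol * (tr.policy_true - 0.5))

    np.clip(lam, 0.0, None, out=lam)
    if not np.all(np.isfinite(lam)):
        raise SimulationError("non-finite intensity for neuron")
    return lam


def generate_spikes(
    trials: pd.DataFrame,
    layouts: list[LayoutSpec],
    neurons: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    dt: float = 0.005,
) -> pd.DataFrame:
    """Realize Poisson spike trains for every neuron in ``neurons``.

    The intensity is evaluated on a ``dt``-spaced grid (much finer than any
    kernel width) and spikes are drawn bin-wise with uniform jitter, an exact
    sampler for the piecewise-constant approximation of the intensity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_end = float(trials["outcome_time"].iloc[-1]) + 3.0
    bins = np.arange(0.0, t_end, dt)

    out_ids, out_times = [], []
    for row in neurons.itertuples(index=False):
        tuning = json.loads(row.tuning)
        try:
            lam = _neuron_intensity(tuning, bins, dt, trials, layouts)
        except SimulationError as e:
            raise SimulationError(f"{e} (neuron {row.neuron_id})") from None
        counts = rng.poisson(lam * dt)
        nz = np.nonzero(counts)[0]
        reps = counts[nz]
        starts = np.repeat(bins[nz], reps)
        times = starts + rng.uniform(0.0, dt, size=starts.size)
        times.sort()
        out_ids.append(np.full(times.size, row.neuron_id, dtype=object))
        out_times.append(times)

    return pd.DataFrame({
        "neuron_id": np.concatenate(out_ids) if out_ids else [],
        "spike_time": np.concatenate(out_times) if out_times else [],
    })


def generate_tracking(
    trials: pd.DataFrame,
    layouts: list[LayoutSpec],
    seed: int | np.random.Generator = 0,
    frame_rate: float = 50.0,
    noise_cm: float = 0.15,
) -> pd.DataFrame:
    """Synthetic nose/ear trajectory visiting the engaged ports.

    The nose moves between the initiation and choice ports of each trial
    (smoothed piecewise-linear path plus Gaussian jitter); the ears ride at
    fixed offsets behind the nose. Likelihoods are near 1 with occasional
    drops, giving the cleaning stage realistic work to do.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lay_by_problem = {l.problem_index: l for l in layouts}
    t_end = float(trials["outcome_time"].iloc[-1]) + 3.0
    times = np.arange(0.0, t_end, 1.0 / frame_rate)

    # waypoints: (time, x, y)
    wp_t, wp_xy = [0.0], [np.array([5.0, 2.0])]
    for tr in trials.itertuples(index=False):
        lay = lay_by_problem[tr.problem_index]
        choice_port = lay.choice_A_port if tr.choice == "A" else lay.choice_B_port
        pi = np.array(PORT_COORDS_CM[lay.initiation_port])
        pc = np.array(PORT_COORDS_CM[choice_port])
        for t, xy in [
            (tr.initiation_time - 0.4, pi + rng.normal(0, 0.3, 2)),
            (tr.initiation_time + 0.1, pi),
            (tr.choice_time, pc),
            (tr.outcome_time + 1.0, pc + rng.normal(0, 0.3, 2)),
        ]:
            if t > wp_t[-1]:
                wp_t.append(t)
                wp_xy.append(xy)
    wp_t = np.asarray(wp_t)
    wp_xy = np.vstack(wp_xy)

    nose = np.column_stack([
        np.interp(times, wp_t, wp_xy[:, 0]),
        np.interp(times, wp_t, wp_xy[:, 1]),
    ]) + rng.normal(0.0, noise_cm, (len(times), 2))

    # ears trail the nose; approximate heading from the smoothed velocity
    vel = np.gradient(nose, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    heading = np.where(speed[:, None] > 1e-6, vel / np.maximum(speed, 1e-6)[:, None], 0.0)
    normal = np.column_stack([-heading[:, 1], heading[:, 0]])
    left = nose - 1.0 * heading + 0.8 * normal + rng.normal(0, noise_cm, (len(times), 2))
    right = nose - 1.0 * heading - 0.8 * normal + rng.normal(0, noise_cm, (len(times), 2))

    lik = np.ones((len(times), 3))
    drop = rng.random((len(times), 3)) < 0.02
    lik[drop] = rng.uniform(0.0, 0.5, size=drop.sum())

    return pd.DataFrame({
        "time": times,
        "nose_x": nose[:, 0], "nose_y": nose[:, 1],
        "left_ear_x": left[:, 0], "left_ear_y": left[:, 1],
        "right_ear_x": right[:, 0], "right_ear_y": right[:, 1],
        "nose_likelihood": lik[:, 0],
        "left_ear_likelihood": lik[:, 1],
        "right_ear_likelihood": lik[:, 2],
    })


def simulate_session(
    task: TaskConfig | None = None,
    agent: AgentConfig | None = None,
    n_neurons: int = 30,
    profile: str | PopulationConfig = "pfc_like",
    seed: int = 0,
    region: str | None = None,
    animal_id: str = "synth",
    session_id: str = "s0",
    with_tracking: bool = False,
) -> SessionRecord:
    """Simulate a complete session (behavior + spikes, optional tracking)."""
    task = task or TaskConfig()
    agent = agent or AgentConfig()
    rng = np.random.default_rng(seed)
    trials, pokes, layouts = simulate_behavior(task, agent, rng)
    neurons = generate_population(n_neurons, profile, rng, region=region,
                                  animal_id=animal_id, session_id=session_id)
    spikes = generate_spikes(trials, layouts, neurons, rng)
    tracking = generate_tracking(trials, layouts, rng) if with_tracking else None
    provenance = {
        "seed": seed,
        "task": {k: list(v) if isinstance(v, tuple) else v
                 for k, v in asdict(task).items()},
        "animal_id": animal_id,
        "session_id": session_id,
        "region": region or (profile if isinstance(profile, str) else "custom"),
    }
    return SessionRecord(
        layouts=layouts, trials=trials, pokes=pokes, spikes=spikes,
        neurons=neurons, tracking=tracking, provenance=provenance,
    ).validate()
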