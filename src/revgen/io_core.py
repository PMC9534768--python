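"""On-disk session format and in-memory data model.

A session directory contains plain-text tabular files::

    layouts.json    port layout of each problem (see :class:`LayoutSpec`)
    trials.tsv      one row per trial (events, choice, outcome, timestamps)
    pokes.tsv       raw port in/out events
    spikes.tsv      (neuron_id, spike_time) long format
    neurons.tsv     neuron metadata (region, animal, optional tuning JSON)
    tracking.tsv    optional nose/ear tracking in port-wall cm
    meta.json       session-level metadata and synthetic provenance

Ports are numbered 0-8 row-major on the 3x3 port wall::

    0 1 2
    3 4 5
    6 7 8

All times are seconds from session start. Tables are TSV with a header row,
UTF-8, "." decimal separator.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "LayoutSpec",
    "SessionRecord",
    "SessionValidationError",
    "SessionLoadError",
    "read_session",
    "write_session",
]

TRIAL_COLUMNS = [
    "trial_index",
    "problem_index",
    "block_index",
    "good_side",
    "forced",
    "forced_side",
    "choice",
    "outcome",
    "initiation_time",
    "choice_time",
    "outcome_time",
]

POKE_COLUMNS = ["time", "port", "event"]
SPIKE_COLUMNS = ["neuron_id", "spike_time"]
NEURON_COLUMNS = ["neuron_id", "region", "animal_id", "session_id", "tuning"]
TRACKING_COLUMNS = [
    "time",
    "nose_x", "nose_y",
    "left_ear_x", "left_ear_y",
    "right_ear_x", "right_ear_y",
    "nose_likelihood", "left_ear_likelihood", "right_ear_likelihood",
]

_FLOAT_FMT = "%.6f"


class SessionLoadError(IOError):
    """A required session file is missing or unreadable."""


class SessionValidationError(ValueError):
    """A session violates a structural invariant; message locates the offender."""


@dataclass(frozen=True)
class LayoutSpec:
    """Port layout of one problem.

    The three layout types used within a session share the A choice port,
    while the initiation and B choice ports move; when all three types are
    present the identities I3 = I1 and B3 = I2 hold (the same physical port
    plays different roles in different problems).
    """

    problem_index: int
    initiation_port: int
    choice_A_port: int
    choice_B_port: int
    layout_type: int

    def __post_init__(self) -> None:
        ports = (self.initiation_port, self.choice_A_port, self.choice_B_port)
        if len(set(ports)) != 3:
            raise SessionValidationError(
                f"layout for problem {self.problem_index}: ports {ports} not distinct"
            )
        if not all(0 <= p <= 8 for p in ports):
            raise SessionValidationError(
                f"layout for problem {self.problem_index}: ports {ports} outside 0-8"
            )
        if self.layout_type not in (1, 2, 3):
            raise SessionValidationError(
                f"layout for problem {self.problem_index}: "
                f"layout_type {self.layout_type} not in {{1,2,3}}"
            )

    def port_of_role(self, role: str) -> int:
        return {
            "I": self.initiation_port,
            "A": self.choice_A_port,
            "B": self.choice_B_port,
        }[role]


@dataclass
class SessionRecord:
    """One session: layouts, trials, pokes, spikes, neuron metadata, tracking.

    ``trials``, ``pokes``, ``spikes``, ``neurons`` and ``tracking`` are pandas
    DataFrames with the column sets defined at module level. ``provenance``
    carries the generating configuration and seed for synthetic sessions.
    """

    layouts: list[LayoutSpec]
    trials: pd.DataFrame
    pokes: pd.DataFrame
    spikes: pd.DataFrame
    neurons: pd.DataFrame
    tracking: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=dict)

    # -- derived conveniences -------------------------------------------------
    def layout_for(self, problem_index: int) -> LayoutSpec:
        for lay in self.layouts:
            if lay.problem_index == problem_index:
                return lay
        raise KeyError(f"no layout for problem {problem_index}")

    @property
    def neuron_ids(self) -> np.ndarray:
        return self.neurons["neuron_id"].to_numpy()

    def spike_times(self, neuron_id) -> np.ndarray:
        s = self.spikes
        return s.loc[s["neuron_id"] == neuron_id, "spike_time"].to_numpy()

    # -- validation -----------------------------------------------------------
    def validate(self, cue_duration_s: float | None = None) -> "SessionRecord":
        """Check every structural invariant; raise a located error on failure."""
        problems = {lay.problem_index for lay in self.layouts}
        if len(problems) != len(self.layouts):
            raise SessionValidationError("duplicate problem_index in layouts")

        t = self.trials
        missing = [c for c in TRIAL_COLUMNS if c not in t.columns]
        if missing:
            raise SessionValidationError(f"trials missing columns {missing}")
        for row in t.itertuples(index=False):
            ti = row.trial_index
            if row.problem_index not in problems:
                raise SessionValidationError(
                    f"trial {ti}: problem_index {row.problem_index} has no layout"
                )
            if not (row.initiation_time < row.choice_time < row.outcome_time):
                raise SessionValidationError(
                    f"trial {ti}: event times not ordered "
                    f"(init={row.initiation_time}, choice={row.choice_time}, "
                    f"outcome={row.outcome_time})"
                )
            if cue_duration_s is not None and not np.isclose(
                row.outcome_time - row.choice_time, cue_duration_s, atol=1e-6
            ):
                raise SessionValidationError(
                    f"trial {ti}: outcome-choice interval != cue duration"
                )
            if row.good_side not in ("A", "B") or row.choice not in ("A", "B"):
                raise SessionValidationError(f"trial {ti}: side labels must be A/B")
            if row.outcome not in ("reward", "omission"):
                raise SessionValidationError(f"trial {ti}: bad outcome {row.outcome!r}")
            if bool(row.forced) and row.choice != row.forced_side:
                raise SessionValidationError(
                    f"trial {ti}: forced to {row.forced_side} but chose {row.choice}"
                )
        # block index increments only at reversals (never decreases, steps of <=1)
        for pi, grp in t.groupby("problem_index"):
            steps = np.diff(grp["block_index"].to_numpy())
            if np.any(steps < 0) or np.any(steps > 1):
                raise SessionValidationError(
                    f"problem {pi}: block_index must increment by 0 or 1"
                )

        if len(self.pokes) and np.any(np.diff(self.pokes["time"].to_numpy()) < 0):
            raise SessionValidationError("poke times not nondecreasing")

        known = set(self.neurons["neuron_id"])
        if self.neurons["neuron_id"].duplicated().any():
            dup = self.neurons.loc[self.neurons["neuron_id"].duplicated(), "neuron_id"]
            raise SessionValidationError(f"duplicate neuron_id {dup.iloc[0]!r}")
        unknown = set(self.spikes["neuron_id"]) - known
        if unknown:
            raise SessionValidationError(
                f"spikes reference unknown neuron_id {sorted(unknown)[:3]}"
            )
        st = self.spikes["spike_time"].to_numpy()
        if len(st) and (np.any(st < 0) or not np.all(np.isfinite(st))):
            raise SessionValidationError("spike times must be finite and nonnegative")
        for nid, grp in self.spikes.groupby("neuron_id"):
            v = grp["spike_time"].to_numpy()
            if np.any(np.diff(v) < 0):
                raise SessionValidationError(f"neuron {nid}: spike times not sorted")

        if self.tracking is not None and len(self.tracking) > 1:
            dt = np.diff(self.tracking["time"].to_numpy())
            if np.any(dt <= 0):
                raise SessionValidationError("tracking frame times not increasing")
        return self


def _require(path: Path) -> Path:
    if not path.exists():
        raise SessionLoadError(f"missing session file: {path.name} (in {path.parent})")
    return path


def write_session(record: SessionRecord, path: str | Path) -> None:
    """Write ``record`` to a session directory (created if needed).

    Idempotent: writing the same record twice produces identical bytes.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    layouts = [dataclasses.asdict(l) for l in record.layouts]
    (path / "layouts.json").write_text(json.dumps(layouts, indent=1) + "\n")

    meta = dict(record.provenance)
    meta["has_tracking"] = record.tracking is not None
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")

    record.trials.to_csv(path / "trials.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
    record.pokes.to_csv(path / "pokes.tsv", sep="\t", index=False,
                        float_format=_FLOAT_FMT)
    record.spikes.to_csv(path / "spikes.tsv", sep="\t", index=False,
                         float_format=_FLOAT_FMT)
    record.neurons.to_csv(path / "neurons.tsv", sep="\t", index=False)
    if record.tracking is not None:
        record.tracking.to_csv(path / "tracking.tsv", sep="\t", index=False,
                               float_format=_FLOAT_FMT)


def read_session(path: str | Path, validate: bool = True) -> SessionRecord:
    """Load and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    if not path.is_dir():
        raise SessionLoadError(f"not a session directory: {path}")

    layouts_raw = json.loads(_require(path / "layouts.json").read_text())
    layouts = [LayoutSpec(**d) for d in layouts_raw]

    trials = pd.read_csv(_require(path / "trials.tsv"), sep="\t",
                         dtype={"good_side": str, "choice": str, "outcome": str})
    trials["forced"] = trials["forced"].astype(bool)
    trials["forced_side"] = trials["forced_side"].fillna("").astype(str)
    pokes = pd.read_csv(_require(path / "pokes.tsv"), sep="\t")
    spikes = pd.read_csv(_require(path / "spikes.tsv"), sep="\t")
    neurons = pd.read_csv(_require(path / "neurons.tsv"), sep="\t")

    meta_path = path / "meta.json"
    provenance = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    tracking = None
    if provenance.pop("has_tracking", False) or (path / "tracking.tsv").exists():
        tracking = pd.read_csv(_require(path / "tracking.tsv"), sep="\t")

    record = SessionRecord(
        layouts=layouts, trials=trials, pokes=pokes, spikes=spikes,
        neurons=neurons, tracking=tracking, provenance=provenance,
    )
    if validate:
        record.validate()
    return record
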