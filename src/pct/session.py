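"""Core session data structures and structural validation.

A recording session couples sorted-unit metadata, trial metadata (condition
labels and event times) and spike event times.  Spikes are stored as flat
parallel arrays (unit index, trial index, time) so that windowing and binning
are vectorised over all events at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "BODY_PARTS",
    "SIDES",
    "FORMATS",
    "TASKS",
    "ConditionLabel",
    "NULL_CONDITION",
    "UnitMeta",
    "Trial",
    "SessionRecording",
    "ValidationError",
    "validate_session",
]

#: Recognised body-part labels. ``site1``..``site9`` are the nine collinear
#: probe locations of the receptive-field gradient task; ``null`` marks the
#: no-stimulus control condition.
BODY_PARTS = (
    "forehead",
    "vertex",
    "back_head",
    "cheek",
    "neck",
    "shoulder",
    "hand",
    "site1",
    "site2",
    "site3",
    "site4",
    "site5",
    "site6",
    "site7",
    "site8",
    "site9",
    "null",
)

SIDES = ("left", "right", "midline", "none")
FORMATS = ("actual", "imagery", "null")
TASKS = ("touch_map", "latency", "rf_gradient", "imagery")

#: Body parts that lie on the body midline and therefore carry side="midline".
_MIDLINE_PARTS = ("forehead", "vertex")


class ValidationError(ValueError):
    """A session violated a structural invariant."""


@dataclass(frozen=True, order=True)
class ConditionLabel:
    """Stimulus condition: body part x body side x presentation format."""

    body_part: str
    side: str
    format: str

    def __post_init__(self) -> None:
        if self.body_part not in BODY_PARTS:
            raise ValidationError(f"unknown body_part {self.body_part!r}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}")
        if self.format not in FORMATS:
            raise ValidationError(f"unknown format {self.format!r}")
        if (self.format == "null") != (self.body_part == "null"):
            raise ValidationError("format='null' if and only if body_part='null'")
        if self.side == "midline" and self.body_part not in _MIDLINE_PARTS:
            raise ValidationError(
                f"side='midline' only valid for {_MIDLINE_PARTS}, got {self.body_part!r}"
            )

    def __str__(self) -> str:
        return f"{self.body_part}:{self.side}:{self.format}"

    @classmethod
    def parse(cls, text: str) -> "ConditionLabel":
        parts = text.split(":")
        if len(parts) != 3:
            raise ValidationError(f"cannot parse condition label {text!r}")
        return cls(*parts)


NULL_CONDITION = ConditionLabel("null", "none", "null")


@dataclass(frozen=True)
class UnitMeta:
    """Metadata for one sorted unit (single- or multi-unit)."""

    unit_id: str
    channel: int
    snr: float
    mean_rate: float
    isolation: str = "single"

    def __post_init__(self) -> None:
        if self.isolation not in ("single", "multi"):
            raise ValidationError(f"isolation must be 'single' or 'multi', got {self.isolation!r}")
        if not np.isfinite(self.snr) or self.snr < 0:
            raise ValidationError(f"unit {self.unit_id}: snr must be finite and >= 0")
        if not np.isfinite(self.mean_rate) or self.mean_rate < 0:
            raise ValidationError(f"unit {self.unit_id}: mean_rate must be finite and >= 0")


@dataclass(frozen=True)
class Trial:
    """One trial: condition label, named event times (trial-relative, s), duration."""

    trial_id: int
    condition: ConditionLabel
    events: dict
    duration: float

    def __post_init__(self) -> None:
        ev = self.events
        for name in ("cue_onset", "go_onset"):
            if name not in ev:
                raise ValidationError(f"trial {self.trial_id}: missing required event {name!r}")
        for name, t in ev.items():
            if not (0.0 <= t <= self.duration):
                raise ValidationError(
                    f"trial {self.trial_id}: event {name!r}={t} outside [0, {self.duration}]"
                )
        if ev["cue_onset"] > ev["go_onset"]:
            raise ValidationError(f"trial {self.trial_id}: cue_onset > go_onset")
        if "contact_time" in ev and ev["contact_time"] < ev["go_onset"]:
            raise ValidationError(f"trial {self.trial_id}: contact_time < go_onset")


@dataclass
class SessionRecording:
    """Units + trials + spike events for one recording session.

    Spike events are stored as three parallel arrays: ``spike_units`` and
    ``spike_trials`` hold integer indices into ``units`` and ``trials``;
    ``spike_times`` holds trial-relative times in seconds.
    """

    session_id: str
    task: str
    units: list  # list[UnitMeta]
    trials: list  # list[Trial]
    spike_units: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    spike_trials: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.float64))

    # ---- derived accessors -------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def unit_ids(self) -> list:
        return [u.unit_id for u in self.units]

    def conditions(self) -> list:
        """Distinct condition labels in stored trial order of first appearance."""
        seen = []
        for tr in self.trials:
            if tr.condition not in seen:
                seen.append(tr.condition)
        return seen

    def trial_labels(self) -> list:
        return [tr.condition for tr in self.trials]

    def event_times(self, name: str) -> np.ndarray:
        """Per-trial time of a named event; raises if any trial lacks it."""
        out = np.empty(self.n_trials)
        for i, tr in enumerate(self.trials):
            if name not in tr.events:
                raise ValidationError(f"trial {tr.trial_id} has no event {name!r}")
            out[i] = tr.events[name]
        return out

    def session_mean_rates(self) -> np.ndarray:
        """Mean firing rate per unit over all trial time, in Hz."""
        total_time = float(sum(tr.duration for tr in self.trials))
        counts = np.bincount(self.spike_units, minlength=self.n_units).astype(float)
        return counts / total_time if total_time > 0 else counts * np.nan

    def subset_units(self, keep: np.ndarray) -> "SessionRecording":
        """New session retaining units at boolean/integer index ``keep``."""
        keep_idx = np.flatnonzero(keep) if np.asarray(keep).dtype == bool else np.asarray(keep)
        remap = -np.ones(self.n_units, dtype=np.int64)
        remap[keep_idx] = np.arange(len(keep_idx))
        mask = remap[self.spike_units] >= 0
        return replace(
            self,
            units=[self.units[i] for i in keep_idx],
            spike_units=remap[self.spike_units[mask]],
            spike_trials=self.spike_trials[mask].copy(),
            spike_times=self.spike_times[mask].copy(),
        )

    def spike_train(self, unit_idx: int, trial_idx: int) -> np.ndarray:
        """Sorted spike times (s) of one unit on one trial."""
        mask = (self.spike_units == unit_idx) & (self.spike_trials == trial_idx)
        return np.sort(self.spike_times[mask])


def validate_session(session: SessionRecording) -> None:
    """Check all structural invariants; raise ValidationError on the first breach."""
    if session.task not in TASKS:
        raise ValidationError(f"unknown task {session.task!r}")
    ids = session.unit_ids
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate unit_id(s): {dup}")
    trial_ids = [tr.trial_id for tr in session.trials]
    if len(set(trial_ids)) != len(trial_ids):
        raise ValidationError("duplicate trial_id(s)")

    su, st, ts = session.spike_units, session.spike_trials, session.spike_times
    if not (len(su) == len(st) == len(ts)):
        raise ValidationError("spike arrays have mismatched lengths")
    if len(su):
        if su.min() < 0 or su.max() >= session.n_units:
            bad = int(np.flatnonzero((su < 0) | (su >= session.n_units))[0])
            raise ValidationError(f"spike row {bad} references unknown unit index {int(su[bad])}")
        if st.min() < 0 or st.max() >= session.n_trials:
            bad = int(np.flatnonzero((st < 0) | (st >= session.n_trials))[0])
            raise ValidationError(f"spike row {bad} references unknown trial index {int(st[bad])}")
        durations = np.array([tr.duration for tr in session.trials])
        lo_bad = ts < 0
        hi_bad = ts > durations[st]
        if lo_bad.any() or hi_bad.any():
            bad = int(np.flatnonzero(lo_bad | hi_bad)[0])
            raise ValidationError(
                f"spike row {bad}: time {ts[bad]:.6f} outside trial duration"
            )

    counts: dict = {}
    for tr in session.trials:
        counts[tr.condition] = counts.get(tr.condition, 0) + 1
    for cond, n in counts.items():
        if n < 2:
            raise ValidationError(f"condition {cond} has {n} trial(s); need >= 2")
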