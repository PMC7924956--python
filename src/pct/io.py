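"""Session directory format and analysis configuration.

A session lives in a directory containing ``manifest.json`` (session id and
task), ``units.csv``, ``trials.csv`` and ``spikes.csv``.  All times are
seconds, trial-relative.  The layout is plain text so sessions diff cleanly
and need no binary dependencies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .session import (
    ConditionLabel,
    SessionRecording,
    Trial,
    UnitMeta,
    ValidationError,
    validate_session,
)

__all__ = ["read_session", "write_session", "AnalysisConfig", "load_config"]

_RESERVED_TRIAL_COLS = ("trial_id", "body_part", "side", "format", "duration")


def write_session(session: SessionRecording, path) -> None:
    """Write a validated session to ``path`` (a directory, created if needed)."""
    validate_session(session)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    with open(path / "manifest.json", "w") as fh:
        json.dump({"session_id": session.session_id, "task": session.task}, fh, indent=2)
        fh.write("\n")

    units = pd.DataFrame(
        [
            {
                "unit_id": u.unit_id,
                "channel": u.channel,
                "snr": u.snr,
                "mean_rate": u.mean_rate,
                "isolation": u.isolation,
            }
            for u in session.units
        ],
        columns=["unit_id", "channel", "snr", "mean_rate", "isolation"],
    )
    units.to_csv(path / "units.csv", index=False, float_format="%.17g")

    event_names = sorted({name for tr in session.trials for name in tr.events})
    rows = []
    for tr in session.trials:
        row = {
            "trial_id": tr.trial_id,
            "body_part": tr.condition.body_part,
            "side": tr.condition.side,
            "format": tr.condition.format,
            "duration": tr.duration,
        }
        for name in event_names:
            row[name] = tr.events.get(name, "")
        rows.append(row)
    trials = pd.DataFrame(rows, columns=list(_RESERVED_TRIAL_COLS) + event_names)
    trials.to_csv(path / "trials.csv", index=False)

    unit_ids = np.array(session.unit_ids, dtype=object)
    trial_ids = np.array([tr.trial_id for tr in session.trials])
    spikes = pd.DataFrame(
        {
            "unit_id": unit_ids[session.spike_units],
            "trial_id": trial_ids[session.spike_trials],
            "time": np.round(session.spike_times, 6),
        }
    )
    spikes.to_csv(path / "spikes.csv", index=False)


def read_session(path) -> SessionRecording:
    """Read and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    for fname in ("manifest.json", "units.csv", "trials.csv", "spikes.csv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"session file missing: {path / fname}")

    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)

    units_df = pd.read_csv(path / "units.csv", dtype={"unit_id": str}, float_precision="round_trip")
    units = [
        UnitMeta(
            unit_id=row.unit_id,
            channel=int(row.channel),
            snr=float(row.snr),
            mean_rate=float(row.mean_rate),
            isolation=row.isolation,
        )
        for row in units_df.itertuples()
    ]

    # keep_default_na: the literal strings "null"/"none" are condition labels
    trials_df = pd.read_csv(path / "trials.csv", keep_default_na=False)
    event_names = [c for c in trials_df.columns if c not in _RESERVED_TRIAL_COLS]
    trials = []
    for row in trials_df.itertuples():
        events = {}
        for name in event_names:
            val = getattr(row, name)
            if val == "" or (isinstance(val, float) and math.isnan(val)):
                continue
            events[name] = float(val)
        trials.append(
            Trial(
                trial_id=int(row.trial_id),
                condition=ConditionLabel(row.body_part, row.side, row.format),
                events=events,
                duration=float(row.duration),
            )
        )

    spikes_df = pd.read_csv(path / "spikes.csv", dtype={"unit_id": str})
    unit_index = {u.unit_id: i for i, u in enumerate(units)}
    trial_index = {tr.trial_id: i for i, tr in enumerate(trials)}
    su = np.empty(len(spikes_df), dtype=np.int64)
    st = np.empty(len(spikes_df), dtype=np.int64)
    for row_num, (uid, tid) in enumerate(zip(spikes_df["unit_id"], spikes_df["trial_id"])):
        if uid not in unit_index:
            raise ValidationError(f"spikes.csv row {row_num}: unknown unit_id {uid!r}")
        if tid not in trial_index:
            raise ValidationError(f"spikes.csv row {row_num}: unknown trial_id {tid!r}")
        su[row_num] = unit_index[uid]
        st[row_num] = trial_index[tid]

    session = SessionRecording(
        session_id=str(manifest["session_id"]),
        task=str(manifest["task"]),
        units=units,
        trials=trials,
        spike_units=su,
        spike_trials=st,
        spike_times=spikes_df["time"].to_numpy(dtype=float),
    )
    validate_session(session)
    return session


@dataclass
class AnalysisConfig:
    """Analysis defaults.

    Thresholds and window placements follow the study conventions: unit
    inclusion at mean rate > 0.5 Hz and SNR > 0.5; stimulus-phase rates in
    [0.5, 2.5) s after go; baseline rates in the 1.5 s before the cue;
    250 split-half resamples for cross-validated correlations; 2000 shuffles
    for permutation tests; 1000 bootstrap resamples; 0.5 s analysis windows
    stepped at 0.1 s for the sliding-window dynamics.
    """

    min_rate: float = 0.5
    min_snr: float = 0.5
    fdr_q: float = 0.05
    stim_window: tuple = (0.5, 2.5)
    baseline_window: tuple = (-1.5, 0.0)
    n_corr_splits: int = 250
    n_perm: int = 2000
    n_boot: int = 1000
    dyn_window: float = 0.5
    dyn_step: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_rate", "min_snr"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.fdr_q < 1):
            raise ValueError("fdr_q must lie in (0, 1)")
        for name in ("stim_window", "baseline_window"):
            lo, hi = getattr(self, name)
            setattr(self, name, (float(lo), float(hi)))
            if not lo < hi:
                raise ValueError(f"{name}: start must be < end")
        for name in ("n_corr_splits", "n_perm", "n_boot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dyn_window <= 0 or self.dyn_step <= 0:
            raise ValueError("dyn_window and dyn_step must be > 0")


def load_config(path) -> AnalysisConfig:
    """Load a YAML or JSON config file; unknown keys are an error (fail fast)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    for key in ("stim_window", "baseline_window"):
        if key in data:
            data[key] = tuple(data[key])
    return AnalysisConfig(**data)
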