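"""Unit selection, windowed firing rates and event-aligned spike binning.

All windows are half-open ``[start, end)`` relative to a named trial event,
so every spike belongs to exactly one bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import SessionRecording, ValidationError

__all__ = ["FiringRateMatrix", "BinnedTensor", "select_units", "window_rates", "bin_spikes"]


@dataclass
class FiringRateMatrix:
    """Mean firing rates (Hz), shape (units, trials), over one named window."""

    rates: np.ndarray
    unit_ids: list
    labels: list  # ConditionLabel per trial (column)
    window: tuple  # (event_name, start_s, end_s)

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]

    def conditions(self) -> list:
        seen = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def condition_trials(self, cond) -> np.ndarray:
        return np.flatnonzero([lab == cond for lab in self.labels])

    def subset_conditions(self, conds) -> "FiringRateMatrix":
        keep = np.flatnonzero([lab in conds for lab in self.labels])
        return FiringRateMatrix(
            rates=self.rates[:, keep],
            unit_ids=list(self.unit_ids),
            labels=[self.labels[i] for i in keep],
            window=self.window,
        )


@dataclass
class BinnedTensor:
    """Spike counts, shape (units, trials, bins), aligned to a named event."""

    counts: np.ndarray
    unit_ids: list
    labels: list
    bin_size: float
    align_event: str
    t_start: float
    t_end: float

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def bin_centers(self) -> np.ndarray:
        return self.t_start + self.bin_size * (np.arange(self.n_bins) + 0.5)

    def rates(self) -> np.ndarray:
        """Counts converted to rates in Hz."""
        return self.counts / self.bin_size


def select_units(
    session: SessionRecording,
    min_rate: float = 0.5,
    min_snr: float = 0.5,
    isolation: str | None = None,
) -> SessionRecording:
    """Retain units with session-wide mean rate > min_rate and SNR > min_snr.

    Both thresholds are strict inequalities.  ``isolation`` optionally
    restricts to ``"single"`` or ``"multi"`` units for robustness re-runs.
    Spikes of dropped units are removed; the result may have zero units.
    """
    rates = session.session_mean_rates()
    keep = np.array(
        [
            (rates[i] > min_rate)
            and (u.snr > min_snr)
            and (isolation is None or u.isolation == isolation)
            for i, u in enumerate(session.units)
        ],
        dtype=bool,
    )
    return session.subset_units(keep)


def window_rates(
    session: SessionRecording,
    align_event: str,
    start: float,
    end: float,
) -> FiringRateMatrix:
    """Mean rate per unit x trial in the half-open window [event+start, event+end)."""
    if not start < end:
        raise ValueError("window start must be < end")
    event = session.event_times(align_event)  # raises naming the trial if missing
    rel = session.spike_times - event[session.spike_trials]
    in_win = (rel >= start) & (rel < end)
    flat = session.spike_units[in_win] * session.n_trials + session.spike_trials[in_win]
    counts = np.bincount(flat, minlength=session.n_units * session.n_trials)
    rates = counts.reshape(session.n_units, session.n_trials) / (end - start)
    return FiringRateMatrix(
        rates=rates.astype(float),
        unit_ids=session.unit_ids,
        labels=session.trial_labels(),
        window=(align_event, float(start), float(end)),
    )


def bin_spikes(
    session: SessionRecording,
    align_event: str,
    t_start: float,
    t_end: float,
    bin_size: float,
) -> BinnedTensor:
    """Spike counts in half-open bins of ``bin_size`` aligned to an event.

    The span must be an integer number of bins (to 1e-9 relative precision);
    the default latency-analysis grid (-0.150, 0.252, 0.002) yields 201 bins.
    """
    n_bins_f = (t_end - t_start) / bin_size
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 * max(1.0, abs(n_bins_f)) or n_bins < 1:
        raise ValueError(
            f"window ({t_start}, {t_end}) is not an integer number of {bin_size}s bins"
        )
    event = session.event_times(align_event)
    rel = session.spike_times - event[session.spike_trials]
    in_win = (rel >= t_start) & (rel < t_end)
    bins = np.floor((rel[in_win] - t_start) / bin_size).astype(np.int64)
    bins = np.clip(bins, 0, n_bins - 1)  # guard against float edge rounding
    flat = (
        session.spike_units[in_win] * (session.n_trials * n_bins)
        + session.spike_trials[in_win] * n_bins
        + bins
    )
    counts = np.bincount(flat, minlength=session.n_units * session.n_trials * n_bins)
    return BinnedTensor(
        counts=counts.reshape(session.n_units, session.n_trials, n_bins).astype(float),
        unit_ids=session.unit_ids,
        labels=session.trial_labels(),
        bin_size=float(bin_size),
        align_event=align_event,
        t_start=float(t_start),
        t_end=float(t_end),
    )
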