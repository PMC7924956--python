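"""Ground-truth Poisson spike-train simulator for the four task paradigms.

Each simulated unit is an inhomogeneous Poisson process whose rate is a
baseline plus condition- and epoch-specific gain terms that switch on with a
short linear ramp after an onset latency:

    lambda_i(t) = b_i + G_{i,c,epoch} * ramp((t - t_on - L_i) / rise)

During the stimulus epoch the gain is the actual-touch gain ``g`` (actual
format), the imagery gain ``m`` (imagery format) or zero (null condition and
the insensate hands under actual touch).  On imagery trials the cue-delay
epoch additionally carries cue-coding gains ``u``.  Imagery gains are built as
a mixture ``m = kappa * g + (1 - kappa) * unique`` so the degree of shared
actual/imagery coding is a known ground-truth parameter; cue gains share a
fraction ``alpha`` with the imagery gains in the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import (
    NULL_CONDITION,
    ConditionLabel,
    SessionRecording,
    Trial,
    UnitMeta,
)

__all__ = [
    "TaskSpec",
    "make_task_spec",
    "UnitGroundTruth",
    "PopulationSpec",
    "make_population",
    "simulate_session",
    "LATERAL_PARTS",
    "RF_SITE_SPACING_CM",
]

#: Body parts tested on both body sides in the touch-mapping task.
LATERAL_PARTS = ("back_head", "cheek", "neck", "shoulder")
#: Spacing of the nine collinear probe sites in the gradient task (cm).
RF_SITE_SPACING_CM = 2.0


@dataclass(frozen=True)
class TaskSpec:
    """Trial structure of one task paradigm.

    Epoch layout per trial (seconds): ``pre`` of silence, ``cue`` beginning at
    ``pre``, a ``delay``, the go signal, a ``stim`` epoch, then ``iti``.
    """

    task: str
    conditions: tuple
    trials_per_condition: int
    pre: float
    cue: float
    delay: float
    stim: float
    iti: float
    contact_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.trials_per_condition < 2:
            raise ValueError("trials_per_condition must be >= 2")
        for name in ("pre", "cue", "delay", "stim", "iti"):
            if getattr(self, name) <= 0:
                raise ValueError(f"epoch duration {name} must be > 0")

    @property
    def cue_onset(self) -> float:
        return self.pre

    @property
    def go_onset(self) -> float:
        return self.pre + self.cue + self.delay

    @property
    def duration(self) -> float:
        return self.pre + self.cue + self.delay + self.stim + self.iti


def _touch_map_conditions() -> tuple:
    conds = [
        ConditionLabel("forehead", "midline", "actual"),
        ConditionLabel("vertex", "midline", "actual"),
    ]
    for part in LATERAL_PARTS + ("hand",):
        for side in ("left", "right"):
            conds.append(ConditionLabel(part, side, "actual"))
    conds.append(NULL_CONDITION)
    return tuple(conds)


def make_task_spec(name: str) -> TaskSpec:
    """Preset trial structures for the four paradigms.

    touch_map: 13 conditions x 10 trials (bilateral body map + insensate
    hands + null).  latency: 6 conditions x 8 trials with a capacitive-probe
    contact event.  rf_gradient: 9 collinear right-side sites + null, 10
    trials.  imagery: 6 actual + 3 right-side imagined conditions + null,
    8 trials, with a short auditory cue and long delay.
    """
    if name == "touch_map":
        return TaskSpec(
            task="touch_map",
            conditions=_touch_map_conditions(),
            trials_per_condition=10,
            pre=1.5,
            cue=1.5,
            delay=1.0,
            stim=3.0,
            iti=1.0,
        )
    if name == "latency":
        conds = tuple(
            ConditionLabel(part, side, "actual")
            for part in ("cheek", "shoulder", "hand")
            for side in ("left", "right")
        )
        return TaskSpec(
            task="latency",
            conditions=conds,
            trials_per_condition=8,
            pre=1.5,
            cue=1.5,
            delay=1.0,
            stim=3.0,
            iti=1.0,
            contact_jitter=0.3,
        )
    if name == "rf_gradient":
        conds = tuple(
            ConditionLabel(f"site{k}", "right", "actual") for k in range(1, 10)
        ) + (NULL_CONDITION,)
        return TaskSpec(
            task="rf_gradient",
            conditions=conds,
            trials_per_condition=10,
            pre=1.5,
            cue=1.5,
            delay=1.0,
            stim=3.0,
            iti=1.0,
        )
    if name == "imagery":
        conds = tuple(
            ConditionLabel(part, side, "actual")
            for part in ("cheek", "shoulder", "hand")
            for side in ("left", "right")
        )
        conds = conds + tuple(
            ConditionLabel(part, "right", "imagery")
            for part in ("cheek", "shoulder", "hand")
        )
        conds = conds + (NULL_CONDITION,)
        return TaskSpec(
            task="imagery",
            conditions=conds,
            trials_per_condition=8,
            pre=1.5,
            cue=0.5,
            delay=2.0,
            stim=3.0,
            iti=1.5,
        )
    raise ValueError(f"unknown task preset {name!r}")


@dataclass
class UnitGroundTruth:
    """Generative parameters of one simulated unit.

    ``stim_gains`` maps (body_part, side) to the actual-touch gain in Hz;
    ``imagery_gains`` and ``cue_gains`` map body_part to the right-side
    imagery-epoch and cue-delay-epoch gains.  The insensate hand and the null
    condition always carry zero actual-touch gain.
    """

    baseline_rate: float
    stim_gains: dict = field(default_factory=dict)
    imagery_gains: dict = field(default_factory=dict)
    cue_gains: dict = field(default_factory=dict)
    latency: float = 0.05
    ramp_rise: float = 0.02
    snr: float = 1.5
    mean_rate_nominal: float = 5.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        all_gains = (
            list(self.stim_gains.values())
            + list(self.imagery_gains.values())
            + list(self.cue_gains.values())
        )
        if all_gains and self.baseline_rate + min(all_gains) < 0:
            raise ValueError("baseline plus smallest gain would yield a negative rate")
        if self.stim_gains.get(("hand", "left"), 0.0) or self.stim_gains.get(("hand", "right"), 0.0):
            raise ValueError("actual-touch hand gains must be zero (insensate control)")


@dataclass
class PopulationSpec:
    """Population-level ground-truth parameters.

    tuned_fraction: fraction of units with nonzero actual-touch gains.
    mirror_sigma: SD (Hz) of the left-right gain asymmetry; 0 gives exactly
    mirror-symmetric bilateral gains.  independent_sides=True instead draws
    the two sides' gains independently (maximally asymmetric control).
    imagery_share (kappa): shared fraction of actual and imagery coding for
    the sensate parts; cue_share (alpha): shared fraction of cue-delay and
    imagery-epoch coding.  hand_imagery_scale scales an independent imagery
    gain for the insensate hand (the actual/imagery dissociation); set to 0
    to make imagery gains exactly kappa-mixtures everywhere.
    """

    n_units: int = 100
    tuned_fraction: float = 0.7
    mirror_sigma: float = 0.5
    independent_sides: bool = False
    imagery_share: float = 0.6
    cue_share: float = 0.5
    hand_imagery_scale: float = 1.0
    latency_mean: float = 0.05
    latency_jitter: float = 0.005
    ramp_rise: float = 0.015
    baseline_mean: float = 5.0
    gain_mean: float = 35.0
    part_prob: float = 0.55
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tuned_fraction <= 1:
            raise ValueError("tuned_fraction must lie in [0, 1]")
        for name in ("imagery_share", "cue_share"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mirror_sigma < 0 or self.latency_jitter < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.baseline_mean < 0 or self.gain_mean < 0:
            raise ValueError("rate parameters must be >= 0")


_IMAGERY_PARTS = ("cheek", "shoulder", "hand")
#: Gamma shape for baseline and gain draws; scale follows from the mean.
_GAMMA_SHAPE = 2.0


def _draw_gain(rng: np.random.Generator, mean: float) -> float:
    return float(rng.gamma(_GAMMA_SHAPE, mean / _GAMMA_SHAPE))


def make_population(spec: PopulationSpec) -> list:
    """Draw a reproducible population of ground-truth units.

    Exactly ``round(tuned_fraction * n_units)`` units receive nonzero
    actual-touch gains.  Tuned units get, per body part, a Bernoulli
    participation draw times a Gamma-distributed gain; right-side gains are
    mirrored to the left with additive N(0, mirror_sigma) asymmetry (or drawn
    independently).  Gradient-task site gains follow a Gaussian spatial
    profile over the nine collinear sites.
    """
    rng = np.random.default_rng(spec.seed)
    n_tuned = int(round(spec.tuned_fraction * spec.n_units))
    tuned_idx = set(rng.choice(spec.n_units, size=n_tuned, replace=False).tolist())

    site_x = RF_SITE_SPACING_CM * np.arange(1, 10)
    units = []
    for i in range(spec.n_units):
        b = float(rng.gamma(_GAMMA_SHAPE, spec.baseline_mean / _GAMMA_SHAPE))
        L = max(0.0, float(rng.normal(spec.latency_mean, spec.latency_jitter)))
        snr = float(rng.uniform(0.6, 3.0))
        g: dict = {}
        m: dict = {}
        u: dict = {}
        if i in tuned_idx:
            # Midline parts: one gain each.
            for part in ("forehead", "vertex"):
                if rng.random() < spec.part_prob:
                    g[(part, "midline")] = _draw_gain(rng, spec.gain_mean)
            # Lateral parts: right-side draw, left mirrored or independent.
            for part in LATERAL_PARTS:
                right = (
                    _draw_gain(rng, spec.gain_mean)
                    if rng.random() < spec.part_prob
                    else 0.0
                )
                if spec.independent_sides:
                    left = (
                        _draw_gain(rng, spec.gain_mean)
                        if rng.random() < spec.part_prob
                        else 0.0
                    )
                else:
                    left = right
                    if spec.mirror_sigma > 0 and right > 0:
                        left = max(0.0, right + float(rng.normal(0, spec.mirror_sigma)))
                if right > 0:
                    g[(part, "right")] = right
                if left > 0:
                    g[(part, "left")] = left
            if not g:  # tuned units must carry at least one field
                part = ("cheek", "neck", "shoulder", "back_head")[int(rng.integers(4))]
                gain = _draw_gain(rng, spec.gain_mean)
                g[(part, "right")] = gain
                if not spec.independent_sides:
                    g[(part, "left")] = (
                        max(0.0, gain + float(rng.normal(0, spec.mirror_sigma)))
                        if spec.mirror_sigma > 0
                        else gain
                    )
            # Gradient-task sites: Gaussian spatial profile.
            center = float(rng.uniform(site_x[0], site_x[-1]))
            width = float(rng.uniform(1.5, 4.0))
            amp = _draw_gain(rng, spec.gain_mean)
            profile = amp * np.exp(-0.5 * ((site_x - center) / width) ** 2)
            for k, val in enumerate(profile, start=1):
                if val > 1e-3:
                    g[(f"site{k}", "right")] = float(val)
            # Imagery gains: kappa-shared with right-side actual gains.
            kappa = spec.imagery_share
            for part in ("cheek", "shoulder"):
                unique = _draw_gain(rng, spec.gain_mean)
                m[part] = kappa * g.get((part, "right"), 0.0) + (1 - kappa) * unique
            hand_unique = _draw_gain(rng, spec.gain_mean)
            m["hand"] = spec.hand_imagery_scale * hand_unique
            # Cue-delay gains: alpha-shared with imagery gains.
            alpha = spec.cue_share
            for part in _IMAGERY_PARTS:
                unique = _draw_gain(rng, spec.gain_mean)
                u[part] = alpha * m[part] + (1 - alpha) * unique
        units.append(
            UnitGroundTruth(
                baseline_rate=b,
                stim_gains=g,
                imagery_gains=m,
                cue_gains=u,
                latency=L,
                ramp_rise=spec.ramp_rise,
                snr=snr,
                mean_rate_nominal=b,
            )
        )
    return units


def _stim_gain(unit: UnitGroundTruth, cond: ConditionLabel) -> float:
    if cond.format == "actual":
        if cond.body_part == "hand":
            return 0.0
        return unit.stim_gains.get((cond.body_part, cond.side), 0.0)
    if cond.format == "imagery":
        return unit.imagery_gains.get(cond.body_part, 0.0)
    return 0.0


def _cue_gain(unit: UnitGroundTruth, cond: ConditionLabel) -> float:
    # Only the imagery task's auditory cue is informative; cue-delay coding is
    # applied on imagery-format trials alone.
    if cond.format == "imagery":
        return unit.cue_gains.get(cond.body_part, 0.0)
    return 0.0


def simulate_session(
    pop: list,
    task: TaskSpec,
    seed: int,
    session_id: str | None = None,
) -> SessionRecording:
    """Simulate one session by thinning an inhomogeneous Poisson process.

    Spike times are exact draws from the piecewise-linear rate model: for each
    unit x trial a homogeneous process at the rate ceiling is drawn and thinned
    by lambda(t)/lambda_max.  The same seed always yields the same session.
    """
    if seed is None:
        raise ValueError("simulate_session requires an explicit seed")
    rng = np.random.default_rng(seed)
    n_units = len(pop)

    # Trial table: round-robin over conditions.
    trials = []
    for rep in range(task.trials_per_condition):
        for cond in task.conditions:
            events = {"cue_onset": task.cue_onset, "go_onset": task.go_onset}
            if task.contact_jitter > 0:
                events["contact_time"] = task.go_onset + float(
                    rng.uniform(0, task.contact_jitter)
                )
            trials.append(
                Trial(
                    trial_id=len(trials),
                    condition=cond,
                    events=events,
                    duration=task.duration,
                )
            )
    n_trials = len(trials)

    # Per (unit, trial) rate-model parameters, flattened unit-major.
    b = np.repeat([u.baseline_rate for u in pop], n_trials)
    L = np.repeat([u.latency for u in pop], n_trials)
    rise = np.repeat([u.ramp_rise for u in pop], n_trials)
    gs = np.empty(n_units * n_trials)
    gc = np.empty(n_units * n_trials)
    onset = np.empty(n_units * n_trials)
    for j, tr in enumerate(trials):
        onset[j::n_trials] = tr.events.get("contact_time", tr.events["go_onset"])
    for i, unit in enumerate(pop):
        row = slice(i * n_trials, (i + 1) * n_trials)
        gs[row] = [_stim_gain(unit, tr.condition) for tr in trials]
        gc[row] = [_cue_gain(unit, tr.condition) for tr in trials]

    cue_t = task.cue_onset
    go_t = task.go_onset
    stim_end = task.go_onset + task.stim
    T = task.duration

    lam_max = b + np.maximum(gs, gc)
    counts = rng.poisson(lam_max * T)
    total = int(counts.sum())
    pair_idx = np.repeat(np.arange(n_units * n_trials), counts)
    t = rng.random(total) * T

    # lambda(t) at every candidate spike.
    lam = b[pair_idx].copy()
    ramp_c = np.clip((t - cue_t - L[pair_idx]) / rise[pair_idx], 0.0, 1.0)
    lam += gc[pair_idx] * ramp_c * (t < go_t)
    ramp_s = np.clip((t - onset[pair_idx] - L[pair_idx]) / rise[pair_idx], 0.0, 1.0)
    lam += gs[pair_idx] * ramp_s * (t < stim_end)
    accept = rng.random(total) * lam_max[pair_idx] < lam
    pair_idx = pair_idx[accept]
    t = t[accept]

    order = np.lexsort((t, pair_idx))
    pair_idx = pair_idx[order]
    t = t[order]
    spike_units = pair_idx // n_trials
    spike_trials = pair_idx % n_trials

    # Unit metadata: empirical session-wide mean rate, ground-truth SNR.
    total_time = n_trials * T
    emp_counts = np.bincount(spike_units, minlength=n_units)
    units_meta = [
        UnitMeta(
            unit_id=f"u{i:04d}",
            channel=i // 2,
            snr=pop[i].snr,
            mean_rate=float(emp_counts[i] / total_time),
            isolation="single" if i % 3 else "multi",
        )
        for i in range(n_units)
    ]

    return SessionRecording(
        session_id=session_id or f"{task.task}-seed{seed}",
        task=task.task,
        units=units_meta,
        trials=trials,
        spike_units=spike_units.astype(np.int64),
        spike_trials=spike_trials.astype(np.int64),
        spike_times=t,
    )
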