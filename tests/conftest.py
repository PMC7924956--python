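import numpy as np
import pytest

import pct


@pytest.fixture(scope="session")
def touch_population():
    return pct.make_population(pct.PopulationSpec(n_units=30, seed=11))


@pytest.fixture(scope="session")
def touch_session(touch_population):
    """A small touch-mapping session with known ground truth."""
    return pct.simulate_session(touch_population, pct.make_task_spec("touch_map"), seed=12)


@pytest.fixture(scope="session")
def imagery_session():
    pop = pct.make_population(pct.PopulationSpec(n_units=30, seed=21))
    return pct.simulate_session(pop, pct.make_task_spec("imagery"), seed=22)


@pytest.fixture(scope="session")
def latency_session():
    pop = pct.make_population(pct.PopulationSpec(n_units=60, seed=31))
    return pct.simulate_session(pop, pct.make_task_spec("latency"), seed=32)


def tiny_session(n_units=2, n_trials=2, spikes=(), duration=10.0, task="touch_map"):
    """Hand-built session: spikes is a list of (unit_idx, trial_idx, time)."""
    conds = [
        pct.ConditionLabel("cheek", "right", "actual"),
        pct.ConditionLabel("shoulder", "right", "actual"),
    ]
    units = [
        pct.UnitMeta(unit_id=f"u{i}", channel=i, snr=1.0, mean_rate=1.0) for i in range(n_units)
    ]
    trials = [
        pct.Trial(
            trial_id=t,
            condition=conds[t % len(conds)],
            events={"cue_onset": 1.0, "go_onset": 2.0},
            duration=duration,
        )
        for t in range(n_trials)
    ]
    spikes = list(spikes)
    su = np.array([s[0] for s in spikes], dtype=np.int64)
    st = np.array([s[1] for s in spikes], dtype=np.int64)
    ts = np.array([s[2] for s in spikes], dtype=float)
    return pct.SessionRecording(
        session_id="tiny",
        task=task,
        units=units,
        trials=trials,
        spike_units=su,
        spike_trials=st,
        spike_times=ts,
    )
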