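import numpy as np
import pytest
from hypothesis import settings

from rlddm import (
    BehavioralRun,
    RLDDMParams,
    StimulusSet,
    Trial,
    TrialSchedule,
    IntervalParams,
    generate_stimulus_sets,
    generate_trial_schedule,
    preprocess_run,
    simulate_run,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stimulus_sets():
    return generate_stimulus_sets(seed=1)


@pytest.fixture(scope="session")
def schedule(stimulus_sets):
    return generate_trial_schedule(stimulus_sets["AV"], seed=2)


@pytest.fixture(scope="session")
def params():
    return RLDDMParams(eta=0.2, a=2.5, tau=1.0, vmod=3.0)


@pytest.fixture(scope="session")
def sim_run(schedule, params):
    return preprocess_run(simulate_run(schedule, params, seed=3))


def make_repeated_pair_run(n_trials=2, responses=None, rewards=None, rts=None):
    """A hand-built run where every trial shows the same cue and symbol pair
    (matching symbol on the left), for worked-example latent propagation."""
    sset = StimulusSet(
        modality="AV",
        cues=("a1", "a2", "a3", "a4"),
        cue_complexity=("low", "medium", "medium", "high"),
        visual_symbols=("v1", "v2", "v3", "v4"),
        symbol_complexity=("low", "medium", "medium", "high"),
        matching={"a1": "v1", "a2": "v2", "a3": "v3", "a4": "v4"},
    )
    trials = []
    clock = 0.0
    for i in range(n_trials):
        stim = clock + 1.5
        fb = stim + 2.0 + 3.0
        clock = fb + 1.8
        trials.append(
            Trial(index=i + 1, cue_id="a1", left_symbol="v1", right_symbol="v2",
                  correct_side="left", feedback_reversed=False,
                  stim_onset=stim, fb_onset=fb, iti=1.5, isi=3.0)
        )
    schedule = TrialSchedule(
        run_id="worked-example", modality="AV", trials=trials,
        reversal_rate=0.0, interval_params=IntervalParams(),
        stimulus_set=sset, seed=0,
    )
    responses = responses or ["left"] * n_trials
    rts = np.asarray(rts if rts is not None else [1.5] * n_trials, dtype=float)
    rewards = np.asarray(rewards if rewards is not None else [1.0] * n_trials, dtype=float)
    rts = np.where([r is None for r in responses], np.nan, rts)
    rewards = np.where([r is None for r in responses], np.nan, rewards)
    return BehavioralRun(schedule=schedule, responses=list(responses), rts=rts, rewards=rewards)
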