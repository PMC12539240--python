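"""Task generation: stimulus sets, schedules, feedback plans, intervals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rlddm import (
    generate_feedback_plan,
    generate_stimulus_sets,
    generate_trial_schedule,
    minimum_familiarisation_trials,
    sample_intervals,
    N_COMBINATIONS,
)
from rlddm.task import ConfigurationError


class TestStimulusSets:
    def test_counts_and_complexity_classes(self, stimulus_sets):
        for modality, sset in stimulus_sets.items():
            assert len(sset.cues) == 4 and len(sset.visual_symbols) == 4
            assert sorted(sset.symbol_complexity) == ["high", "low", "medium", "medium"]
        assert sorted(stimulus_sets["AV"].cue_complexity) == ["high", "low", "medium", "medium"]
        # tactile sets: two constant-frequency patterns are the low-complexity pair
        assert sorted(stimulus_sets["TV"].cue_complexity) == ["high", "low", "low", "medium"]

    def test_deterministic_per_seed(self):
        assert generate_stimulus_sets(1) == generate_stimulus_sets(1)
        assert generate_stimulus_sets(1)["AV"].matching != generate_stimulus_sets(5)["AV"].matching

    def test_combination_space(self, stimulus_sets):
        sset = stimulus_sets["AV"]
        combos = {(c, s) for c in sset.cues for s in sset.visual_symbols}
        assert len(combos) == N_COMBINATIONS == 16


class TestTrialSchedule:
    def test_default_schedule_structure(self, schedule):
        assert schedule.n_trials == 44
        counts = {}
        for t in schedule.trials:
            counts[t.cue_id] = counts.get(t.cue_id, 0) + 1
            assert t.left_symbol != t.right_symbol
        assert sorted(counts.values()) == [11, 11, 11, 11]

    def test_all_16_pairings_occur(self, schedule):
        seen = set()
        for t in schedule.trials:
            seen.add((t.cue_id, t.left_symbol))
            seen.add((t.cue_id, t.right_symbol))
        assert len(seen) == 16

    def test_no_long_cue_runs(self, stimulus_sets):
        for seed in range(30):
            sch = generate_trial_schedule(stimulus_sets["AV"], seed=seed)
            cues = [t.cue_id for t in sch.trials]
            for i in range(3, len(cues)):
                assert len(set(cues[i - 3 : i + 1])) > 1

    def test_side_counterbalanced_within_one(self, schedule):
        for cue in schedule.stimulus_set.cues:
            sides = [t.correct_side for t in schedule.trials if t.cue_id == cue]
            assert abs(sides.count("left") - sides.count("right")) <= 1

    def test_minimal_run_one_trial_per_cue(self, stimulus_sets):
        sch = generate_trial_schedule(stimulus_sets["AV"], n_trials=4, seed=0)
        assert sorted(t.cue_id for t in sch.trials) == sorted(stimulus_sets["AV"].cues)

    def test_infeasible_frequencies_raise(self, stimulus_sets):
        cues = stimulus_sets["AV"].cues
        with pytest.raises(ConfigurationError, match="frequencies"):
            generate_trial_schedule(
                stimulus_sets["AV"], n_trials=44,
                cue_frequencies={c: 10 for c in cues}, seed=0,
            )

    def test_validator_over_many_seeds(self, stimulus_sets):
        for seed in range(1000):
            sch = generate_trial_schedule(stimulus_sets["AV"], seed=seed)
            sch.validate()  # raises on any structural violation

    def test_serialization_deterministic_and_roundtrips(self, schedule, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        schedule.write(p1)
        schedule.write(p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = type(schedule).read(p1)
        assert back.to_frame()["cue"].tolist() == schedule.to_frame()["cue"].tolist()
        assert back.stimulus_set.matching == dict(schedule.stimulus_set.matching)
        np.testing.assert_allclose(
            back.to_frame()["stim_onset"], schedule.to_frame()["stim_onset"], atol=1e-6
        )

    def test_timeline_bookkeeping(self, schedule):
        prev_end = 0.0
        for t in schedule.trials:
            assert t.stim_onset == pytest.approx(prev_end + t.iti, abs=1e-9)
            assert t.fb_onset == pytest.approx(t.stim_onset + 2.0 + t.isi, abs=1e-9)
            prev_end = t.fb_onset + 1.8


class TestFeedbackPlan:
    @pytest.mark.parametrize(
        "rate,expected_total",
        [(0.0, 0), (0.05, 2), (0.10, 4), (0.20, 9)],
    )
    def test_reversal_counts(self, rate, expected_total):
        cues = ["c1", "c2", "c3", "c4"] * 11
        for seed in range(20):
            flags = generate_feedback_plan(cues, rate, seed=seed)
            assert flags.sum() == expected_total
            per_cue = [sum(flags[i] for i in range(44) if cues[i] == c) for c in set(cues)]
            assert max(per_cue) - min(per_cue) <= 1

    @given(st.integers(min_value=0, max_value=10_000))
    def test_even_spread_property(self, seed):
        cues = ["c1", "c2", "c3", "c4"] * 11
        flags = generate_feedback_plan(cues, 0.20, seed=seed)
        per_cue = [sum(flags[i] for i in range(44) if cues[i] == c) for c in ("c1", "c2", "c3", "c4")]
        assert sum(per_cue) == 9 and max(per_cue) - min(per_cue) <= 1

    def test_invalid_rate(self):
        with pytest.raises(ConfigurationError):
            generate_feedback_plan(["c1"] * 4, 1.0, seed=0)


class TestIntervals:
    @pytest.mark.parametrize("mean,bounds", [(1.87, (0.76, 3.45)), (3.45, (2.28, 4.83))])
    def test_truncation_and_mean(self, mean, bounds):
        s = sample_intervals(100_000, mean, bounds, seed=1)
        assert s.min() >= bounds[0] and s.max() <= bounds[1]
        assert abs(s.mean() - mean) < 0.05

    def test_invalid_bounds(self):
        with pytest.raises(ConfigurationError):
            sample_intervals(10, 5.0, (0.76, 3.45), seed=0)


def test_minimum_familiarisation_trials():
    # guided instruction + first practice + one full run per modality, plus
    # response-box practice: the protocol floor before scanning
    assert minimum_familiarisation_trials() == 134
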