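"""Rescorla-Wagner updating, latent propagation, and run simulation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rlddm import (
    RLDDMParams,
    ValueTable,
    compute_latents,
    compute_rpe,
    drift_rate,
    normalize_pair,
    preprocess_run,
    simulate_run,
    trial_loglik,
    update_value,
    wfpt_density,
)
from conftest import make_repeated_pair_run

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestElementaryOperations:
    @pytest.mark.parametrize(
        "reward,value,expected",
        [(1, 0.5, 0.5), (0, 0.5, -0.5), (1, 1.0, 0.0)],
    )
    def test_rpe(self, reward, value, expected):
        assert compute_rpe(reward, value) == pytest.approx(expected)

    def test_rpe_undefined_for_neutral_feedback(self):
        with pytest.raises(ValueError, match="omission"):
            compute_rpe(float("nan"), 0.5)

    @pytest.mark.parametrize(
        "value,reward,eta,expected",
        [(0.5, 1, 0.2, 0.6), (0.5, 1, 0.0, 0.5), (0.5, 1, 1.0, 1.0)],
    )
    def test_delta_rule(self, value, reward, eta, expected):
        assert update_value(value, reward, eta) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "vl,vr,expected",
        [(0.5, 0.5, (0.5, 0.5)), (0.6, 0.2, (0.75, 0.25))],
    )
    def test_normalization(self, vl, vr, expected):
        assert normalize_pair(vl, vr) == pytest.approx(expected)

    def test_degenerate_pair_warns_and_returns_half(self):
        with pytest.warns(RuntimeWarning):
            assert normalize_pair(0.0, 0.0) == (0.5, 0.5)

    @pytest.mark.parametrize(
        "vbl,vbr,vmod,expected",
        [(0.5, 0.5, 7.0, 0.0), (0.75, 0.25, 2.0, 1.0), (0.25, 0.75, 2.0, -1.0)],
    )
    def test_drift_rate(self, vbl, vbr, vmod, expected):
        assert drift_rate(vbl, vbr, vmod) == pytest.approx(expected)

    @given(unit, unit, st.floats(min_value=0.0, max_value=20.0))
    def test_drift_antisymmetry(self, vl, vr, vmod):
        vbl, vbr = normalize_pair(max(vl, 1e-6), max(vr, 1e-6))
        assert drift_rate(vbl, vbr, vmod) == pytest.approx(-drift_rate(vbr, vbl, vmod))

    @given(unit, unit)
    def test_normalized_pair_sums_to_one_exactly(self, vl, vr):
        vbl, vbr = normalize_pair(max(vl, 1e-6), max(vr, 1e-6))
        assert vbl + vbr == 1.0

    @given(st.lists(st.sampled_from([0.0, 1.0]), min_size=1, max_size=200), unit)
    def test_values_stay_bounded(self, rewards, eta):
        v = 0.5
        for r in rewards:
            v = update_value(v, r, eta)
            assert 0.0 <= v <= 1.0


class TestTrialLoglik:
    def test_symmetry_at_zero_drift(self, params):
        p = RLDDMParams(eta=0.2, a=2.0, tau=0.5, vmod=1.0)
        assert trial_loglik("left", 1.5, 0.0, p) == pytest.approx(
            trial_loglik("right", 1.5, 0.0, p)
        )

    def test_matches_density_definitionally(self):
        p = RLDDMParams(eta=0.2, a=2.0, tau=0.5, vmod=1.0)
        v = 0.8
        ll = trial_loglik("left", 1.7, v, p)
        assert ll == pytest.approx(np.log(wfpt_density(1.2, v, 2.0, 0.5, "upper")))
        ll = trial_loglik("right", 1.7, v, p)
        assert ll == pytest.approx(np.log(wfpt_density(1.2, v, 2.0, 0.5, "lower")))

    def test_infeasible_rt_returns_neg_inf(self):
        p = RLDDMParams(eta=0.2, a=2.0, tau=0.5, vmod=1.0)
        assert trial_loglik("left", 0.49, 1.0, p) == -np.inf


class TestValueTable:
    def test_initialized_at_half(self, schedule):
        vt = ValueTable.for_schedule(schedule)
        sset = schedule.stimulus_set
        assert all(vt[c, s] == 0.5 for c in sset.cues for s in sset.visual_symbols)

    def test_update_returns_rpe_and_moves_value(self, schedule):
        vt = ValueTable.for_schedule(schedule)
        cue = schedule.stimulus_set.cues[0]
        sym = schedule.stimulus_set.visual_symbols[0]
        rpe = vt.update(cue, sym, 1.0, 0.2)
        assert rpe == pytest.approx(0.5)
        assert vt[cue, sym] == pytest.approx(0.6)


class TestLatents:
    def test_first_trial_is_uniform(self, sim_run, params):
        lat = compute_latents(sim_run, params)
        assert lat["vbar_left"].iloc[0] == 0.5
        assert lat["vbar_right"].iloc[0] == 0.5
        assert lat["drift"].iloc[0] == 0.0

    def test_two_trial_worked_example(self):
        run = make_repeated_pair_run(n_trials=2)
        p = RLDDMParams(eta=0.2, a=2.0, tau=0.5, vmod=1.0)
        lat = compute_latents(run, p)
        # after one rewarded left choice: V_left 0.5 -> 0.6, V_right 0.5
        assert lat["vbar_left"].iloc[1] == pytest.approx(0.6 / 1.1, abs=1e-12)
        assert lat["drift"].iloc[1] == pytest.approx(0.1 / 1.1, abs=1e-12)
        assert lat["v_chosen_norm"].iloc[1] == pytest.approx(0.6 / 1.1, abs=1e-12)
        assert lat["rpe"].iloc[1] == pytest.approx(1.0 - 0.6, abs=1e-12)

    def test_full_updating_reaches_reward(self):
        run = make_repeated_pair_run(n_trials=3)
        p = RLDDMParams(eta=1.0, a=2.0, tau=0.5, vmod=1.0)
        lat = compute_latents(run, p)
        # eta=1 jumps the chosen raw value to 1.0 after the first update
        assert lat["vbar_left"].iloc[1] == pytest.approx(1.0 / 1.5, abs=1e-12)
        assert lat["rpe"].iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_omission_has_no_rpe_and_no_update(self):
        run = make_repeated_pair_run(
            n_trials=3, responses=["left", None, "left"], rewards=[1.0, None, 1.0]
        )
        p = RLDDMParams(eta=0.2, a=2.0, tau=0.5, vmod=1.0)
        lat = compute_latents(run, p)
        assert np.isnan(lat["rpe"].iloc[1]) and np.isnan(lat["v_chosen_norm"].iloc[1])
        # trial 3 sees the same values as trial 2: the omission updated nothing
        assert lat["vbar_left"].iloc[2] == lat["vbar_left"].iloc[1]

    def test_normalization_invariant(self, sim_run, params):
        lat = compute_latents(sim_run, params)
        assert np.all(lat["vbar_left"] + lat["vbar_right"] == 1.0)


class TestSimulateRun:
    def test_deterministic(self, schedule, params):
        r1 = simulate_run(schedule, params, seed=5)
        r2 = simulate_run(schedule, params, seed=5)
        assert r1.responses == r2.responses
        np.testing.assert_array_equal(r1.rts, r2.rts)

    def test_zero_learning_rate_keeps_values_flat(self, schedule):
        p = RLDDMParams(eta=0.0, a=2.5, tau=0.8, vmod=5.0)
        run = simulate_run(schedule, p, seed=6)
        lat = compute_latents(run, p)
        assert np.all(lat["drift"] == 0.0)
        assert np.all(lat["vbar_left"] == 0.5)

    def test_feedback_follows_reversal_plan(self, schedule, params):
        run = simulate_run(schedule, params, seed=7)
        for t, trial in enumerate(schedule.trials):
            if run.responses[t] is None:
                assert np.isnan(run.rewards[t])
                continue
            correct = run.responses[t] == trial.correct_side
            expected = (not correct) if trial.feedback_reversed else correct
            assert run.rewards[t] == float(expected)

    def test_learning_improves_late_accuracy(self, stimulus_sets):
        from rlddm import bin_metrics, generate_trial_schedule

        p = RLDDMParams(eta=0.2, a=2.5, tau=1.0, vmod=5.0)
        rng = np.random.default_rng(8)
        acc = []
        for _ in range(60):
            sch = generate_trial_schedule(stimulus_sets["AV"], seed=int(rng.integers(2**31 - 1)))
            run = preprocess_run(simulate_run(sch, p, seed=int(rng.integers(2**31 - 1))))
            acc.append(bin_metrics(run).bin_accuracy)
        acc = np.asarray(acc, dtype=float)
        assert np.nanmean(acc[:, 3]) > np.nanmean(acc[:, 0])

    def test_run_serialization_roundtrip(self, sim_run, tmp_path):
        path = tmp_path / "run.tsv"
        sim_run.write(path)
        back = type(sim_run).read(path)
        assert back.responses == sim_run.responses
        assert back.flags == sim_run.flags
        np.testing.assert_allclose(back.rts, sim_run.rts, atol=1e-6)
        np.testing.assert_array_equal(np.isnan(back.rewards), np.isnan(sim_run.rewards))
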