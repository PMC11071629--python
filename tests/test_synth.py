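import numpy as np
import pandas as pd
import pytest

from seqchoice import behavior as beh
from seqchoice.reference import ACTION_COUNTS_REFERENCE, RT_REFERENCE
from seqchoice.synth import (
    evaluate_rate,
    read_session,
    simulate_choice_session,
    simulate_fixation_session,
    simulate_spike_train,
    synthesize_eye_trace,
    write_session,
)
from seqchoice.task import BehaviorPolicy, NeuronArchetype, ResponseKernel


def _degenerate_policy(policy_c):
    """Accept every good object, return every bad object."""
    probs = {}
    for key in policy_c.action_probs:
        value, _ = key
        probs[key] = {a: 0.0 for a in policy_c.action_probs[key]}
        probs[key]["Accept" if value == "good" else "Return"] = 1.0
    return BehaviorPolicy(
        rt_mean=policy_c.rt_mean, rt_sd=policy_c.rt_sd, action_probs=probs
    )


class TestChoiceSession:
    def test_degenerate_policy_forces_actions(self, task, policy_c, archetypes):
        pol = _degenerate_policy(policy_c)
        s = simulate_choice_session(
            task, pol, archetypes["cluster1_good"], n_trials=10, seed=1,
            with_eye=False,
        )
        assert len(s.trials) == 10
        good = s.trials[s.trials["value"] == "good"]
        bad = s.trials[s.trials["value"] == "bad"]
        assert (good["action"] == "Accept").all()
        assert (bad["action"] == "Return").all()

    def test_return_fraction_matches_policy_within_3se(self, task, policy_c, archetypes):
        # bad-object Return probability for subject C scene 1 is 1113/1479
        n = 1479
        s = simulate_choice_session(
            task, policy_c, archetypes["cluster2_bad"], n_trials=4 * n, seed=7,
            with_eye=False,
        )
        bad1 = s.trials[(s.trials["value"] == "bad") & (s.trials["scene"] == 1)]
        p = 1113 / 1479
        frac = (bad1["action"] == "Return").mean()
        se = np.sqrt(p * (1 - p) / len(bad1))
        assert abs(frac - p) < 3 * se

    def test_good_rt_mean_matches_reference_within_3se(self, task, policy_c, archetypes):
        n_ref, mean_ref, sd_ref = RT_REFERENCE[("C", 1, "good")]  # 1428, 160.9, 21.6
        s = simulate_choice_session(
            task, policy_c, archetypes["cluster1_good"], n_trials=6000, seed=11,
            with_eye=False,
        )
        good1 = s.trials[
            (s.trials["value"] == "good") & (s.trials["scene"] == 1)
        ]["rt_ms"].dropna()
        assert len(good1) > 500
        se = sd_ref / np.sqrt(len(good1))
        assert abs(good1.mean() - mean_ref) < 3 * se

    def test_determinism_identical_seed(self, task, policy_c, archetypes):
        a = simulate_choice_session(task, policy_c, archetypes["cluster2_bad"],
                                    n_trials=25, seed=99)
        b = simulate_choice_session(task, policy_c, archetypes["cluster2_bad"],
                                    n_trials=25, seed=99)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        assert np.array_equal(a.spikes, b.spikes)
        pd.testing.assert_frame_equal(a.eye, b.eye)

    def test_negative_trial_count_rejected(self, task, policy_c, archetypes):
        with pytest.raises(ValueError):
            simulate_choice_session(task, policy_c, archetypes["cluster2_bad"],
                                    n_trials=-3, seed=1)

    def test_event_times_strictly_increasing(self, small_session):
        for row in small_session.trials.itertuples(index=False):
            ev = [row.t_scene_ms, row.t_fp_ms, row.t_target_ms,
                  row.t_saccade_go_ms, row.t_saccade_back_ms]
            ev = [e for e in ev if np.isfinite(e)]
            assert np.all(np.diff(ev) > 0)


class TestEyeTrace:
    def test_no_commands_zero_speed(self, task):
        trials = pd.DataFrame({
            "trial_id": [0], "scene": [1], "value": ["bad"], "direction": ["contra"],
            "angle_deg": [0.0], "t_scene_ms": [2000.0], "t_fp_ms": [3000.0],
            "t_target_ms": [3700.0], "t_saccade_go_ms": [np.nan],
            "t_saccade_back_ms": [np.nan], "action": ["Stay"], "rt_ms": [np.nan],
            "reward": [False], "rt_z": [0.0],
        })
        eye = synthesize_eye_trace(trials, task, noise_sd=0.0)
        assert beh.eye_speed(eye).max() <= 1e-9

    def test_single_saccade_detected_at_commanded_time(self, task):
        t_cmd = 3900.0
        trials = pd.DataFrame({
            "trial_id": [0], "scene": [1], "value": ["good"], "direction": ["contra"],
            "angle_deg": [0.0], "t_scene_ms": [2000.0], "t_fp_ms": [3000.0],
            "t_target_ms": [3700.0], "t_saccade_go_ms": [t_cmd],
            "t_saccade_back_ms": [np.nan], "action": ["Accept"], "rt_ms": [200.0],
            "reward": [True], "rt_z": [0.0],
        })
        eye = synthesize_eye_trace(trials, task, noise_sd=0.0)
        onset = beh.detect_saccade(eye, 3700.0)
        assert onset is not None
        assert abs(onset - t_cmd) <= 2.0

    def test_return_trial_classified_return(self, task):
        trials = pd.DataFrame({
            "trial_id": [0], "scene": [1], "value": ["bad"], "direction": ["contra"],
            "angle_deg": [0.0], "t_scene_ms": [2000.0], "t_fp_ms": [3000.0],
            "t_target_ms": [3700.0], "t_saccade_go_ms": [3930.0],
            "t_saccade_back_ms": [4170.0], "action": ["Return"], "rt_ms": [230.0],
            "reward": [False], "rt_z": [0.0],
        })
        eye = synthesize_eye_trace(trials, task, noise_sd=0.0)
        action = beh.classify_action(eye, (15.0, 0.0), 3700.0, t_fp=3000.0)
        assert action == "Return"


class TestSpikeTrain:
    def test_flat_rate_poisson_count_calibration(self):
        arch = NeuronArchetype(
            label="flat", baseline_rate=5.0,
            kernels={("good", "contra"): (ResponseKernel(amplitude=0.0),)},
        )
        trials = pd.DataFrame({"t_scene_ms": [], "t_fp_ms": [], "t_target_ms": [],
                               "t_saccade_go_ms": [], "t_saccade_back_ms": [],
                               "value": [], "direction": [], "rt_z": []})
        spikes = simulate_spike_train(trials, arch, seed=5, t_end=100_000.0)
        assert abs(len(spikes) - 500) < 3 * np.sqrt(500)

    def test_expected_count_matches_rate_integral(self, task, policy_c, archetypes):
        arch = archetypes["cluster2_bad"]
        s = simulate_choice_session(task, policy_c, arch, n_trials=200, seed=21,
                                    with_eye=False)
        # analytic expected count over the session at 1-ms discretization
        t_end = float(np.nanmax(s.trials["t_saccade_back_ms"].fillna(
            s.trials["t_target_ms"]))) + 1000.0
        centers = np.arange(int(t_end)) + 0.5
        expected = evaluate_rate(centers, s.trials, arch).sum() / 1000.0
        observed = np.sum(s.spikes < t_end)
        assert abs(observed - expected) < 3 * np.sqrt(expected)

    def test_bad_exceeds_good_for_rejection_archetype(self, task, policy_c, archetypes):
        from seqchoice import spikes as spk

        s = simulate_choice_session(task, policy_c, archetypes["cluster2_bad"],
                                    n_trials=200, seed=31, with_eye=False)
        act = spk.neuron_condition_activity(s, by=("value", "direction"))
        act = act.set_index(["value", "direction"])["NeuronalActivity"]
        assert act[("bad", "contra")] > act[("good", "contra")]

    def test_spike_train_determinism(self, small_session, task, policy_c, archetypes):
        a = simulate_spike_train(small_session.trials, archetypes["cluster2_bad"], seed=3)
        b = simulate_spike_train(small_session.trials, archetypes["cluster2_bad"], seed=3)
        assert np.array_equal(a, b)

    def test_zero_rate_warns_and_returns_empty(self):
        arch = NeuronArchetype(label="x", baseline_rate=1e-9, kernels={})
        trials = pd.DataFrame({"t_scene_ms": [], "t_fp_ms": [], "t_target_ms": [],
                               "t_saccade_go_ms": [], "t_saccade_back_ms": [],
                               "value": [], "direction": [], "rt_z": []})
        spikes = simulate_spike_train(trials, arch, seed=1, t_end=1000.0)
        assert len(spikes) == 0


class TestFixationSession:
    def test_presentation_counts_between_2_and_4(self, task, archetypes):
        s = simulate_fixation_session(task, archetypes["cluster2_bad"],
                                      n_trials=50, seed=3)
        counts = s.trials.groupby("trial_id").size()
        assert counts.between(1, 4).all()  # fix-break trials may truncate
        full = s.trials.groupby("trial_id")["action"].apply(
            lambda a: (a == "FixBreak").sum() == 0
        )
        assert counts[full].between(2, 4).all()

    def test_zero_attenuation_gives_no_evoked_response(self, task, archetypes):
        from dataclasses import replace

        from seqchoice import spikes as spk

        arch = replace(archetypes["cluster2_bad"], fixation_attenuation=0.0)
        s = simulate_fixation_session(task, arch, n_trials=100, seed=9)
        labeled = spk.per_trial_activity(s, align="target_onset")
        z = labeled["z"].to_numpy()
        assert abs(z.mean()) < 3 * z.std(ddof=1) / np.sqrt(len(z))

    def test_full_strength_matches_choice_response(self, task, policy_c, archetypes):
        """With attenuation 1 the fixation object response is statistically
        indistinguishable from the choice-task target response."""
        from dataclasses import replace

        from scipy import stats

        from seqchoice import spikes as spk

        arch = replace(archetypes["cluster2_bad"], fixation_attenuation=1.0)
        fx = simulate_fixation_session(task, arch, n_trials=120, seed=13)
        ch = simulate_choice_session(task, policy_c, arch, n_trials=160, seed=14,
                                     with_eye=False)
        zf = spk.per_trial_activity(
            fx, trial_mask=(fx.trials["value"] == "bad") & (fx.trials["direction"] == "contra")
        )["z"]
        zc = spk.per_trial_activity(
            ch, trial_mask=(ch.trials["value"] == "bad") & (ch.trials["direction"] == "contra")
        )["z"]
        p = stats.ttest_ind(zf, zc, equal_var=False).pvalue
        assert p > 0.01


class TestSessionIO:
    def test_round_trip_reproduces_session(self, small_session, tmp_path):
        write_session(small_session, tmp_path / "s1")
        back = read_session(tmp_path / "s1")
        assert back.monkey_id == small_session.monkey_id
        assert back.task == small_session.task
        np.testing.assert_allclose(back.spikes, small_session.spikes, atol=0.05)
        pd.testing.assert_frame_equal(
            back.trials.drop(columns=["value", "action", "direction"]),
            small_session.trials.drop(columns=["value", "action", "direction"]),
            check_exact=False, atol=1e-4,
        )
        assert list(back.trials["action"]) == list(small_session.trials["action"])
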