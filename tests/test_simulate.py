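"""Synthetic-data generators: behavioral cohorts and ROI time series."""

import numpy as np
import pandas as pd
import pytest

from sfgpi import decoding, simulate, task
from sfgpi.simulate import (
    CohortConfig,
    NeuralConfig,
    expected_reuse_rate,
    policy_categories,
    simulate_cohort,
    simulate_roi_runs,
    simulate_session_one,
)

from conftest import make_participant_runs


class TestPolicyCategories:
    @pytest.mark.parametrize(
        "task_id, expected",
        [
            ("test_1", {"more_rewarding_training": 1, "less_rewarding_training": 4,
                        "objective_best": 3, "remaining": 2}),
            ("test_2", {"more_rewarding_training": 4, "less_rewarding_training": 1,
                        "objective_best": 2, "remaining": 3}),
        ],
    )
    def test_mapping(self, task_id, expected):
        assert policy_categories(task_id) == expected

    def test_partition_on_all_test_tasks(self):
        for tid in task.TEST_TASK_IDS:
            assert sorted(policy_categories(tid).values()) == [1, 2, 3, 4]

    def test_train_task_rejected(self):
        with pytest.raises(ValueError):
            policy_categories("train_1")


class TestCohort:
    def test_pure_sfgpi_reuses_always(self, schedules6):
        cfg = CohortConfig(
            n_participants=2, agent_mix={"SFGPI": 1.0}, exploration_trials=0, seed=1
        )
        data = simulate_cohort(cfg, schedules6)
        test = data.trials.query("trial_type == 'test'")
        assert test["choice_triplet"].isin([1, 4]).all()

    def test_random_cohort_mean_test_reward(self, schedules6):
        """Uniform choice over the 16 test rewards has mean 76.875."""
        cfg = CohortConfig(n_participants=20, agent_mix={"RANDOM": 1.0}, seed=5)
        data = simulate_cohort(cfg, schedules6)
        test = data.trials.query("trial_type == 'test'")
        per = test.groupby("participant")["reward"].mean()
        sem = per.std(ddof=1) / np.sqrt(len(per))
        assert abs(per.mean() - 76.875) < 4 * sem

    def test_determinism(self, schedules6):
        cfg = CohortConfig(n_participants=3, lapse_rate=0.1, omission_rate=0.05, seed=9)
        a = simulate_cohort(cfg, schedules6)
        b = simulate_cohort(cfg, schedules6)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.estimates, b.estimates)

    def test_rewards_match_reward_matrix(self, schedules6, rm_full):
        cfg = CohortConfig(n_participants=1, lapse_rate=0.3, seed=2)
        data = simulate_cohort(cfg, schedules6)
        answered = data.trials[~data.trials["omitted"]]
        expected = [
            rm_full.reward(t, int(c))
            for t, c in zip(answered["task_id"], answered["choice_triplet"])
        ]
        assert np.allclose(answered["reward"], expected)

    def test_omissions_carry_no_choice(self, schedules6):
        cfg = CohortConfig(n_participants=2, omission_rate=0.3, seed=3)
        data = simulate_cohort(cfg, schedules6)
        omitted = data.trials[data.trials["omitted"]]
        assert len(omitted) > 0
        assert omitted["choice_triplet"].isna().all()
        assert omitted["reward"].isna().all()

    def test_profile_converges_to_agent_profile(self, schedules6):
        """Empirical test-choice proportions approach the theoretical profile."""
        cfg = CohortConfig(
            n_participants=84, agent_mix={"SFGPI": 1.0}, exploration_trials=0, seed=4
        )
        data = simulate_cohort(cfg, schedules6)
        test = data.trials.query("trial_type == 'test'")
        assert len(test) >= 10_000
        props = test["choice_triplet"].value_counts(normalize=True)
        assert props.get(1, 0) == pytest.approx(0.5, abs=0.02)
        assert props.get(4, 0) == pytest.approx(0.5, abs=0.02)

    def test_expected_reuse_rate_oracle(self):
        cfg = CohortConfig(
            n_participants=10, agent_mix={"SFGPI": 0.6, "MB": 0.4}, lapse_rate=0.1
        )
        # 0.6 * (0.9 + 0.1/2) + 0.4 * (0.1/2)
        assert expected_reuse_rate(cfg) == pytest.approx(0.59)

    def test_invalid_mix(self):
        with pytest.raises(ValueError):
            CohortConfig(agent_mix={"SFGPI": 0.5, "MB": 0.2})

    def test_estimates_structure(self, sfgpi_cohort, schedules6):
        est = sfgpi_cohort.estimates
        assert est["estimate"].between(0, 250).all()
        assert est["confidence"].between(0, 100).all()
        final = schedules6[-1].config
        truth = est.query("participant == 1").set_index(["city", "position"])["truth"]
        idx = [r - 1 for r in final.permutation_rule]
        for city in task.CITIES:
            phi = task.PHI[final.city_to_triplet[city] - 1]
            assert [truth[(city, p)] for p in (1, 2, 3)] == [phi[i] for i in idx]


class TestRoiRuns:
    def test_separable_limit_recovers_choices(self, schedules2):
        """With strong patterns and weak noise the decoder recovers the chosen city."""
        ncfg = NeuralConfig(
            n_voxels=40, pattern_snr=10.0, noise_sd=0.1, seed=21
        )
        runs, behavioral, _ = make_participant_runs(schedules2, ncfg)
        dcfg = decoding.DecodingConfig(n_subsamples=2, seed=3)
        model = decoding.train_policy_decoder(runs[:3], dcfg)
        held = runs[3]
        data = decoding.clean_run(held)
        ev = held.events
        eligible = ev[ev["feedback"] & ev["choice_city"].notna()]
        X = np.array(
            [
                data[int(round((o + dcfg.lag_seconds) / dcfg.tr))]
                for o in eligible["feedback_onset"]
            ]
        )
        acc = (model.predict(X) == eligible["choice_city"].to_numpy()).mean()
        assert acc > 0.9

    def test_signal_free_data_gives_four_class_chance(self, schedules2):
        """With no signal at all, evidence settles at the 4-class chance of 0.25."""
        ncfg = NeuralConfig(n_voxels=40, pattern_snr=0.0, seed=22)
        runs, _, _ = make_participant_runs(schedules2, ncfg)
        dcfg = decoding.DecodingConfig(n_subsamples=2, seed=3)
        ptc = decoding.decode_test_trials(runs, dcfg)
        per_class = np.nanmean(ptc.probs, axis=(0, 1))
        assert np.allclose(per_class, 0.25, atol=0.05)

    def test_no_reactivation_no_category_advantage(self, schedules2):
        """Without planted reactivation no policy category stands out at the cue."""
        ncfg = NeuralConfig(
            n_voxels=40,
            pattern_snr=1.0,
            response_activation=0.0,
            reactivation={},
            seed=22,
        )
        runs, _, _ = make_participant_runs(schedules2, ncfg)
        dcfg = decoding.DecodingConfig(n_subsamples=2, seed=3)
        ptc = decoding.decode_test_trials(runs, dcfg)
        mappings = {s.config.block_index: s.config.city_to_triplet for s in schedules2}
        wm = decoding.window_average(
            decoding.categorize_evidence(ptc, mappings), dcfg
        )
        assert wm.max() - wm.min() < 0.08
        assert wm["more_rewarding_training"] < 0.3

    def test_planted_reactivation_dominates(self, schedules2):
        ncfg = NeuralConfig(
            n_voxels=40,
            pattern_snr=2.0,
            response_activation=0.0,
            reactivation={"more_rewarding_training": 1.0},
            seed=23,
        )
        runs, _, _ = make_participant_runs(schedules2, ncfg)
        dcfg = decoding.DecodingConfig(n_subsamples=2, seed=3)
        ptc = decoding.decode_test_trials(runs, dcfg)
        mappings = {
            s.config.block_index: s.config.city_to_triplet for s in schedules2
        }
        ce = decoding.categorize_evidence(ptc, mappings)
        wm = decoding.window_average(ce, dcfg)
        others = [
            wm["less_rewarding_training"], wm["objective_best"], wm["remaining"]
        ]
        assert wm["more_rewarding_training"] > max(others)

    def test_choice_alignment_required(self, schedules2):
        ncfg = NeuralConfig(n_voxels=10, seed=1)
        with pytest.raises(ValueError):
            simulate_roi_runs(schedules2[0], ["sydney"] * 10, ncfg)

    def test_run_geometry(self, schedules2):
        ncfg = NeuralConfig(n_voxels=16, seed=2)
        choices = ["sydney"] * 68
        runs, truth = simulate_roi_runs(schedules2[0], choices, ncfg)
        assert len(runs) == 2
        for run in runs:
            last = run.events.iloc[-1]
            assert run.data.shape[0] >= int(last["onset"] / ncfg.tr)
            assert run.data.shape == (len(run.data), 16)
            assert run.motion_confounds.shape == (len(run.data), ncfg.n_confounds)
        assert set(truth["patterns"]) == set(task.CITIES)


class TestSessionOne:
    def test_determinism(self):
        ncfg = NeuralConfig(n_voxels=12, seed=5)
        a, _ = simulate_session_one(ncfg, n_trials_per_target=2, seed=5, n_runs=1)
        b, _ = simulate_session_one(ncfg, n_trials_per_target=2, seed=5, n_runs=1)
        assert np.array_equal(a[0].data, b[0].data)
        pd.testing.assert_frame_equal(a[0].events, b[0].events)

    def test_labels_and_counts(self):
        ncfg = NeuralConfig(n_voxels=12, seed=6)
        runs, _ = simulate_session_one(ncfg, n_trials_per_target=2, seed=6, n_runs=2)
        ev = runs[0].events
        assert set(ev["trial_type"]) == {"city", "number"}
        counts = ev["target"].value_counts()
        assert (counts == 2).all()
        assert len(counts) == 16

    def test_separable_limit_12_classes(self):
        ncfg = NeuralConfig(n_voxels=60, pattern_snr=8.0, noise_sd=0.1, seed=7)
        runs, _ = simulate_session_one(ncfg, n_trials_per_target=3, seed=7, n_runs=2)
        dcfg = decoding.DecodingConfig(n_subsamples=2, seed=1)
        model = decoding.train_feature_decoder(runs[:1], dcfg)
        held = runs[1]
        data = decoding.clean_run(held)
        numbers = held.events.query("trial_type == 'number'")
        X = np.array(
            [
                data[int(round((o + dcfg.lag_seconds) / dcfg.tr))]
                for o in numbers["response_onset"]
            ]
        )
        acc = (model.predict(X) == numbers["target"].astype(int).to_numpy()).mean()
        assert acc > 0.9

    def test_min_trials_guard(self):
        with pytest.raises(ValueError):
            simulate_session_one(NeuralConfig(n_voxels=8), n_trials_per_target=1)


def test_peak_decodability_near_hrf_peak(schedules2):
    """Evidence for the feedback class peaks about one HRF lag after the event."""
    ncfg = NeuralConfig(n_voxels=40, pattern_snr=3.0, response_activation=0.0, seed=31)
    runs, _, _ = make_participant_runs(schedules2, ncfg)
    dcfg = decoding.DecodingConfig(n_subsamples=2, seed=3)
    model = decoding.train_policy_decoder(runs[:3], dcfg)
    held = runs[3]
    data = decoding.clean_run(held)
    ev = held.events
    eligible = ev[ev["feedback"] & ev["choice_city"].notna()]
    curves = []
    for _, row in eligible.iterrows():
        b = int(round(row["feedback_onset"] / dcfg.tr))
        offs = [b + o for o in range(9) if b + o < len(data)]
        if len(offs) < 9:
            continue
        e = model.evidence(data[offs])
        cls = int(np.flatnonzero(model.classes_ == row["choice_city"])[0])
        curves.append(e[:, cls])
    peak_offset = int(np.argmax(np.mean(curves, axis=0)))
    # HRF peak ~5 s = 4 TRs at 1.25 s
    assert abs(peak_offset - 4) <= 1
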