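"""MVPA pipeline: cleaning, decoders, categorization, grids, correlations."""

import numpy as np
import pandas as pd
import pytest

from sfgpi import decoding, simulate, task
from sfgpi.decoding import (
    CUE_OFFSETS,
    DecodingConfig,
    EvidenceDecoder,
    brain_behavior_correlation,
    categorize_evidence,
    clean_run,
    decode_test_trials,
    decode_with_model,
    excluded_reward_features,
    feature_evidence,
    prioritization,
    train_feature_decoder,
    train_policy_decoder,
    validation_grid,
    window_average,
)
from sfgpi.simulate import NeuralConfig, RoiRunData

from conftest import make_participant_runs


def noise_run(n_tr=120, n_vox=8, seed=0, data=None, confounds=None):
    rng = np.random.default_rng(seed)
    data = data if data is not None else rng.standard_normal((n_tr, n_vox))
    confounds = (
        confounds if confounds is not None else rng.standard_normal((n_tr, 3))
    )
    events = pd.DataFrame({"onset": [10.0], "trial_type": ["test"]})
    return RoiRunData(
        data=data, events=events, motion_confounds=confounds, run_id=1, block_id=1
    )


class TestCleanRun:
    def test_constant_column_becomes_zero(self):
        run = noise_run()
        run.data[:, 0] = 7.0
        run.motion_confounds[:] = 0.0
        cleaned = clean_run(run)
        assert np.allclose(cleaned[:, 0], 0.0)

    def test_injected_confound_removed(self):
        rng = np.random.default_rng(1)
        conf = rng.standard_normal((120, 2))
        data = rng.standard_normal((120, 5))
        data[:, 2] += 3.0 * conf[:, 0]
        run = noise_run(data=data, confounds=conf)
        cleaned = clean_run(run)
        for j in range(5):
            r = np.corrcoef(cleaned[:, j], conf[:, 0] - conf[:, 0].mean())[0, 1]
            assert abs(r) < 1e-10

    def test_idempotent(self):
        run = noise_run(seed=2)
        once = clean_run(run)
        again = clean_run(
            RoiRunData(
                data=once,
                events=run.events,
                motion_confounds=run.motion_confounds,
                run_id=1,
                block_id=1,
            )
        )
        assert np.allclose(once, again, atol=1e-8)

    def test_nan_rejected(self):
        run = noise_run(seed=3)
        run.data[0, 0] = np.nan
        with pytest.raises(ValueError):
            clean_run(run)

    def test_smoothing_levels(self):
        run = noise_run(seed=4)
        s0 = decoding.smooth_voxels(run.data, 0.0)
        s4 = decoding.smooth_voxels(run.data, 4.0)
        assert np.array_equal(s0, run.data)
        assert s4.std() < run.data.std()  # spatial averaging shrinks variance


class TestEvidenceDecoder:
    def test_balanced_subsampling_and_classes(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 6))
        y = np.array(["a"] * 25 + ["b"] * 10 + ["c"] * 5)
        model = EvidenceDecoder(n_subsamples=3, random_state=0).fit(X, y)
        assert list(model.classes_) == ["a", "b", "c"]
        assert model.subsample_size_ == 5

    def test_evidence_unnormalized(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(i, 0.1, (10, 4)) for i in range(3)])
        y = np.repeat(["a", "b", "c"], 10)
        model = EvidenceDecoder(n_subsamples=2, random_state=0).fit(X, y)
        ev = model.evidence(X)
        assert ev.shape == (30, 3)
        assert not np.allclose(ev.sum(axis=1), 1.0)
        assert ((ev >= 0) & (ev <= 1)).all()

    def test_needs_two_classes(self):
        with pytest.raises(ValueError):
            EvidenceDecoder().fit(np.ones((5, 2)), np.array(["a"] * 5))

    def test_sklearn_params_roundtrip(self):
        model = EvidenceDecoder(n_subsamples=7, C=0.5, random_state=3)
        params = model.get_params()
        clone = EvidenceDecoder().set_params(**params)
        assert clone.get_params() == params

    def test_shuffled_labels_near_chance(self, schedules2):
        """Label-shuffled training yields ~0.25 held-out evidence per class."""
        ncfg = NeuralConfig(n_voxels=30, pattern_snr=2.0, seed=41)
        runs, _, _ = make_participant_runs(schedules2, ncfg)
        dcfg = DecodingConfig(n_subsamples=2, seed=5)
        rng = np.random.default_rng(0)
        shuffled = []
        for run in runs[:3]:
            ev = run.events.copy()
            answered = ev["choice_city"].notna()
            ev.loc[answered, "choice_city"] = rng.permutation(
                ev.loc[answered, "choice_city"].to_numpy()
            )
            shuffled.append(
                RoiRunData(run.data, ev, run.motion_confounds, run.run_id, run.block_id)
            )
        model = train_policy_decoder(shuffled, dcfg)
        data = clean_run(runs[3])
        ev = model.evidence(data[::10])
        assert abs(ev.mean() - 0.25) < 0.06


class TestTrainingContract:
    def test_missing_class_raises(self, schedules2):
        ncfg = NeuralConfig(n_voxels=20, seed=42)
        cohort = simulate.CohortConfig(
            n_participants=1, agent_mix={"SFGPI": 1.0}, exploration_trials=0, seed=1
        )
        runs, _, _ = make_participant_runs(
            schedules2, ncfg, behavioral=simulate.simulate_cohort(cohort, schedules2)
        )
        with pytest.raises(ValueError, match="no training trials for classes"):
            train_policy_decoder(runs, DecodingConfig(n_subsamples=1))

    def test_loro_never_trains_on_held_out_run(self, schedules2):
        ncfg = NeuralConfig(n_voxels=20, pattern_snr=1.0, seed=43)
        runs, _, _ = make_participant_runs(schedules2, ncfg)
        seen = []

        def spy_builder(train_runs, cfg, cleaned=None):
            seen.append({r.run_id for r in train_runs})
            return train_policy_decoder(train_runs, cfg, cleaned=cleaned)

        decode_test_trials(runs, DecodingConfig(n_subsamples=1), model_builder=spy_builder)
        all_ids = {r.run_id for r in runs}
        held_out_with_tests = [
            r.run_id for r in runs if (r.events["trial_type"] == "test").any()
        ]
        assert len(seen) == len(runs)
        for train_ids, held in zip(
            [s for s in seen], [r.run_id for r in runs]
        ):
            assert held not in train_ids
            assert train_ids == all_ids - {held}

    def test_cue_offsets_count(self):
        assert len(CUE_OFFSETS) == 13  # TR_0 .. TR_+12 inclusive


@pytest.fixture(scope="module")
def simple_ptc():
    classes = np.array(sorted(task.CITIES))
    trials = pd.DataFrame(
        {
            "task_id": ["test_1", "test_1"],
            "block": [1, 1],
            "trial_index": [40, 45],
            "prev_choice_city": [None, "sydney"],
        }
    )
    probs = np.zeros((2, 3, 4))
    for j, c in enumerate(classes):
        probs[:, :, j] = j / 10.0
    return decoding.ProbabilityTimecourse(
        probs=probs, classes=classes, offsets=np.arange(3), trials=trials
    )


class TestCategorization:
    def test_mapping_and_exclusion(self, simple_ptc):
        mapping = {c: i + 1 for i, c in enumerate(task.CITIES)}
        ce = categorize_evidence(simple_ptc, {1: mapping})
        # test_1: more -> triplet 1 (sydney), less -> 4 (london),
        # best -> 3 (new_york), remaining -> 2 (tokyo)
        classes = list(simple_ptc.classes)
        assert ce.evidence[0, 0, 0] == classes.index("sydney") / 10.0
        assert ce.evidence[0, 0, 1] == classes.index("london") / 10.0
        assert ce.evidence[0, 0, 2] == classes.index("new_york") / 10.0
        assert ce.evidence[0, 0, 3] == classes.index("tokyo") / 10.0
        # second trial: previous choice was sydney = the "more" category city
        assert not ce.excluded[0].any()
        assert ce.excluded[1, 0] and not ce.excluded[1, 1:].any()

    def test_window_average_constant(self, simple_ptc):
        mapping = {c: i + 1 for i, c in enumerate(task.CITIES)}
        ce = categorize_evidence(simple_ptc, {1: mapping})
        ce.evidence[:] = 0.25
        wm = window_average(ce, DecodingConfig(window=(0, 2)))
        assert np.allclose(wm.to_numpy(), 0.25)

    def test_all_masked_category_is_missing(self, simple_ptc):
        mapping = {c: i + 1 for i, c in enumerate(task.CITIES)}
        ce = categorize_evidence(simple_ptc, {1: mapping})
        ce.excluded[:, 0] = True
        with pytest.warns(RuntimeWarning):
            wm = window_average(ce, DecodingConfig(window=(0, 2)))
        assert np.isnan(wm["more_rewarding_training"])
        assert not np.isnan(wm["objective_best"])


class TestPrioritization:
    def test_zero_for_equal_evidence(self):
        wm = pd.Series(
            {
                "more_rewarding_training": 0.3,
                "less_rewarding_training": 0.3,
                "objective_best": 0.3,
                "remaining": 0.3,
            }
        )
        assert (prioritization(wm) == 0).all()

    def test_antisymmetry(self):
        wm = pd.Series(
            {
                "more_rewarding_training": 0.4,
                "less_rewarding_training": 0.2,
                "objective_best": 0.25,
                "remaining": 0.25,
            }
        )
        p = prioritization(wm)
        swapped = wm.rename(
            {
                "more_rewarding_training": "less_rewarding_training",
                "less_rewarding_training": "more_rewarding_training",
            }
        )
        q = prioritization(swapped)
        assert p["more_minus_best"] == q["less_minus_best"]
        assert (p["more_minus_best"] - p["less_minus_best"]) == -(
            q["more_minus_best"] - q["less_minus_best"]
        )


class TestValidationGrid:
    def test_grid_size_and_lag_recovery(self, schedules2):
        """The grid's evidence score peaks at the HRF peak lag.

        Feedback-locked signal only, so the planted lag is the HRF peak
        (5 s).  Strong L2 keeps the probabilities unsaturated; only in that
        linear regime is window-averaged evidence monotone in the signal
        amplitude captured by the training volume, which is what makes lag
        selection identifiable.
        """
        ncfg = NeuralConfig(
            n_voxels=30, pattern_snr=1.0, response_activation=0.0, seed=51
        )
        runs, _, _ = make_participant_runs(schedules2, ncfg)
        res = validation_grid(
            runs, DecodingConfig(seed=1, regularization=0.01), n_subsamples=3
        )
        assert len(res["scores"]) == 9
        assert res["best_lag"] == 5.0
        assert not res["unstable"]

    def test_all_noise_flagged_unstable(self, schedules2):
        ncfg = NeuralConfig(n_voxels=30, pattern_snr=0.0, seed=52)
        runs, _, _ = make_participant_runs(schedules2, ncfg)
        res = validation_grid(runs, DecodingConfig(seed=1), n_subsamples=2)
        assert res["unstable"]


class TestFeatureDecoding:
    def test_reward_excluded_features(self):
        assert excluded_reward_features() == {20, 80, 140}

    @pytest.fixture()
    def feature_setup(self, schedules2):
        ncfg = NeuralConfig(
            n_voxels=50,
            pattern_snr=3.0,
            response_activation=0.0,
            feature_reactivation={"more_rewarding_training": 1.0},
            seed=53,
        )
        runs, behavioral, truth = make_participant_runs(schedules2, ncfg)
        loc_runs, _ = simulate.simulate_session_one(
            ncfg,
            n_trials_per_target=3,
            seed=53,
            n_runs=2,
            patterns=truth["patterns"],
            feature_patterns=truth["feature_patterns"],
        )
        dcfg = DecodingConfig(n_subsamples=2, seed=2)
        model12 = train_feature_decoder(loc_runs, dcfg)
        ptc12 = decode_with_model(model12, runs, dcfg)
        return ptc12

    def test_planted_feature_reactivation_recovered(self, feature_setup):
        fe = feature_evidence(feature_setup)
        keep_more = ~fe.excluded[:, 0]
        keep_less = ~fe.excluded[:, 1]
        more = np.nanmean(fe.evidence[keep_more, :, 0])
        less = np.nanmean(fe.evidence[keep_less, :, 1])
        assert more > 1 / 12
        assert more > less

    def test_null_feature_evidence_near_chance(self, schedules2):
        ncfg = NeuralConfig(n_voxels=40, pattern_snr=0.0, seed=54)
        runs, _, truth = make_participant_runs(schedules2, ncfg)
        loc_runs, _ = simulate.simulate_session_one(
            ncfg, n_trials_per_target=3, seed=54, n_runs=2
        )
        dcfg = DecodingConfig(n_subsamples=2, seed=2)
        model12 = train_feature_decoder(loc_runs, dcfg)
        ptc12 = decode_with_model(model12, runs, dcfg)
        fe = feature_evidence(ptc12)
        assert np.nanmean(fe.evidence) == pytest.approx(1 / 12, abs=0.02)


class TestBrainBehavior:
    def test_monotone_transform_rho_one(self):
        behavior = np.array([0.2, 0.5, 0.7, 0.9, 1.0])
        evidence = np.exp(behavior)
        rho, p = brain_behavior_correlation(evidence, behavior)
        assert rho == pytest.approx(1.0)

    def test_ties_use_average_ranks(self):
        rho, _ = brain_behavior_correlation([1, 1, 2, 3], [1, 1, 2, 3])
        assert rho == 1.0

    def test_underpowered_warns(self):
        with pytest.warns(RuntimeWarning):
            brain_behavior_correlation([1, 2, 3], [3, 2, 1])

    def test_null_calibration(self):
        """Independent noise: mean rho ~ 0 and type-I error ~ alpha."""
        rng = np.random.default_rng(8)
        rhos, rejections = [], 0
        n_sims = 300
        for _ in range(n_sims):
            a, b = rng.standard_normal(38), rng.standard_normal(38)
            rho, p = brain_behavior_correlation(a, b)
            rhos.append(rho)
            rejections += p < 0.05
        assert abs(np.mean(rhos)) < 0.02
        assert abs(rejections / n_sims - 0.05) < 0.035
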