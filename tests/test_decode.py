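"""Binarization rules, SVM training, sigmoid calibration, d'-corrected
accuracy and leave-one-trial-out cross-validation."""

import numpy as np
import pytest
from scipy.stats import norm

from mazedecode.decode import (
    Binarizer,
    BinaryLabeling,
    CalibrationSigmoid,
    SkipVariable,
    calibrate,
    calibration_bins,
    corrected_accuracy,
    leave_one_trial_out,
    predict_series,
    train_decoder,
)
from mazedecode.features import VariableSeries, VariableSet, variable_roster
from mazedecode.signal_prep import AlignedTrial


def _series(source, values, vid="v", valid=None):
    return VariableSeries(source, vid, np.asarray(values, float), valid=valid)


class TestBinarize:
    def test_motion_middle_third_masked(self):
        vals = np.arange(-45, 46, 1, dtype=float)  # symmetric rotation values
        s = _series("motion", vals)
        binz = Binarizer("motion").fit([s])
        lab = binz.transform(s, training=True)
        frac = lab.include.mean()
        assert 0.6 <= frac <= 0.72  # about two thirds retained
        assert np.all(lab.labels[lab.include & (vals < 0)] == -1)
        assert np.all(lab.labels[lab.include & (vals > 0)] == 1)

    def test_motion_zero_heavy_falls_back_to_sign_split(self):
        vals = np.concatenate([np.zeros(50), [-6, -6, 6, 6]])
        s = _series("motion", vals)
        lab = Binarizer("motion").fit([s]).transform(s, training=True)
        assert lab.include.sum() == 4
        assert sorted(lab.labels[lab.include]) == [-1, -1, 1, 1]

    def test_three_to_one_cap_on_reward(self):
        vals = np.concatenate([np.ones(10), np.zeros(100)])
        s = _series("reward", vals)
        binz = Binarizer("reward", rng=np.random.default_rng(0))
        lab = binz.transform(s, training=True)
        kept_no = (lab.include & (lab.labels == -1)).sum()
        assert kept_no == 30  # at most 3x the 10 "yes" points
        assert (lab.include & (lab.labels == 1)).sum() == 10
        # the cap never applies to held-out labelings
        lab_test = binz.transform(s, training=False)
        assert lab_test.include.all()

    def test_scene_median_split_fold_threshold_reused(self):
        train = _series("scene_rms", [1.0, 2.0, 3.0, 4.0])
        test = _series("scene_rms", [0.0, 10.0])
        binz = Binarizer("scene_rms").fit([train])
        lab = binz.transform(test)
        assert lab.labels.tolist() == [-1, 1]

    def test_constant_scene_square_skipped(self):
        s = _series("scene_temp", np.zeros(40))
        with pytest.raises(SkipVariable):
            Binarizer("scene_temp").fit([s])

    def test_quadrant_neither_quadrant_excluded(self):
        s = _series("quadrant", [1.0, 0.0, 0.5, 1.0],
                    valid=np.array([True, True, False, True]))
        lab = Binarizer("quadrant").transform(s)
        assert lab.labels[lab.include].tolist() == [1, -1, 1]
        assert not lab.include[2]


class TestTrainDecoder:
    def test_separable_two_voxel_toy_trains_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal([2, 2], 0.3, (20, 2)), rng.normal([-2, -2], 0.3, (20, 2))])
        y = np.array([1] * 20 + [-1] * 20)
        lab = BinaryLabeling(y, np.ones(40, bool), "toy")
        dec = train_decoder(X, lab)
        assert np.all(dec.predict_labels(X) == y)

    def test_duplicated_voxels_same_predictions(self):
        # on separable data the margin solution is insensitive to feature
        # duplication: weights split across copies, decision signs unchanged
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(1.5, 0.4, (25, 3)), rng.normal(-1.5, 0.4, (25, 3))])
        y = np.array([1] * 25 + [-1] * 25)
        lab = BinaryLabeling(y, np.ones(50, bool), "toy")
        d1 = train_decoder(X, lab)
        d2 = train_decoder(np.hstack([X, X]), lab)
        assert np.all(d1.predict_labels(X) == d2.predict_labels(np.hstack([X, X])))

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        lab = BinaryLabeling(np.ones(10, int), np.ones(10, bool), "toy")
        with pytest.raises(ValueError):
            train_decoder(X, lab)


class TestCalibration:
    def test_sigmoid_midpoint_formula(self):
        sig = CalibrationSigmoid(a=1.0, b=-0.5, c=0.1, d=0.2)
        assert np.isclose(sig(1.0), 0.1 + (1 - 0.1 - 0.2) / 2)

    def test_bins_of_twenty_with_partial_rule(self):
        dvs = np.linspace(-1, 1, 52)
        labels = np.where(dvs > 0, 1, -1)
        x, y = calibration_bins(dvs, labels)
        # 20 + 20 + 12 (partial bin kept: >= 10 points)
        assert len(x) == 3
        dvs = np.linspace(-1, 1, 45)
        labels = np.where(dvs > 0, 1, -1)
        x, _ = calibration_bins(dvs, labels)
        assert len(x) == 2  # trailing 5 points dropped

    def test_separated_dvs_monotone_and_saturating(self):
        rng = np.random.default_rng(2)
        dvs = np.concatenate([rng.normal(-3, 0.5, 60), rng.normal(3, 0.5, 60)])
        labels = np.where(dvs > 0, 1, -1)
        cal = calibrate(dvs, labels)
        grid = np.linspace(dvs.min(), dvs.max(), 50)
        vals = cal(grid)
        assert np.all(np.diff(vals) >= -1e-9)
        assert vals[0] < 0.1 and vals[-1] > 0.9

    def test_flat_when_labels_independent_of_dv(self):
        rng = np.random.default_rng(3)
        dvs = rng.normal(size=2000)
        labels = rng.choice([-1, 1], size=2000, p=[0.7, 0.3])
        cal = calibrate(dvs, labels)
        vals = cal(np.linspace(dvs.min(), dvs.max(), 50))
        assert vals.max() - vals.min() < 0.1
        assert abs(vals.mean() - 0.3) < 0.15

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            calibrate(np.zeros(5), np.ones(5, int))


class TestCorrectedAccuracy:
    def test_always_majority_classifier_scores_half(self):
        # 90% prevalence, classifier always answers the majority class:
        # H = F = 1, clipped to a common bound, d' = 0, P = 50%
        stats = corrected_accuracy(1.0, 1.0, n=100)
        assert stats.dprime == 0.0
        assert stats.P == 0.5

    def test_equal_hit_and_false_alarm_is_half(self):
        for p in (0.1, 0.5, 0.9):
            assert corrected_accuracy(p, p).P == 0.5

    def test_normal_cdf_oracle(self):
        stats = corrected_accuracy(norm.cdf(1.0), 0.5)
        assert np.isclose(stats.dprime, 1.0, atol=1e-6)
        assert np.isclose(stats.P, norm.cdf(0.5), atol=1e-6)
        assert np.isclose(stats.P, 0.691, atol=5e-4)

    def test_antisymmetry(self):
        s1 = corrected_accuracy(0.8, 0.3)
        s2 = corrected_accuracy(0.3, 0.8)
        assert np.isclose(s1.P, 1 - s2.P)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError):
            corrected_accuracy(1.2, 0.0)


def _toy_trials(n_trials=8, n_trs=24, n_vox=12, snr=4.0, seed=0, source="scene_rms",
                informative=True):
    """Aligned trials whose voxel pattern encodes one scene variable."""
    rng = np.random.default_rng(seed)
    roster = variable_roster()
    w = rng.normal(size=n_vox)
    trials = []
    for i in range(n_trials):
        series = []
        for src, vid in roster:
            series.append(VariableSeries(src, vid, rng.random(n_trs)))
        vs = VariableSet(series)
        v = vs.get(source, "sq00").values
        z = (v - v.mean()) / v.std()
        X = rng.normal(size=(n_trs, n_vox))
        if informative:
            X = X + snr * np.outer(z, w)
        trials.append(AlignedTrial(X=X, vars=vs, trial_index=i))
    return trials


class TestLeaveOneTrialOut:
    def test_each_trial_predicted_exactly_once(self):
        trials = _toy_trials()
        res = leave_one_trial_out(trials, "scene_rms", "sq00")
        assert sorted(p.trial_index for p in res.predictions) == list(range(8))
        assert all(len(p.values) == 24 for p in res.predictions)

    def test_informative_signal_decodes_above_90(self):
        res = leave_one_trial_out(_toy_trials(snr=6.0), "scene_rms", "sq00")
        assert res.accuracy.P > 0.9

    def test_permuted_labels_near_chance(self):
        # a null oracle: with no signal the pooled corrected accuracy stays
        # inside the binomial 95% interval around 0.5
        ps = []
        for seed in range(5):
            res = leave_one_trial_out(_toy_trials(seed=seed, informative=False),
                                      "scene_rms", "sq00", seed=seed)
            ps.append(res.accuracy.P)
        n = 8 * 24
        half_width = 1.96 * np.sqrt(0.25 / n)
        assert abs(np.mean(ps) - 0.5) < half_width

    def test_no_information_leak_from_heldout_trial(self):
        # shuffling the held-out trial's variable values must not change its
        # own fold's trained decoder (thresholds, weights, calibration all
        # come from the training trials only)
        trials = _toy_trials()
        res1 = leave_one_trial_out(trials, "scene_rms", "sq00")
        rng = np.random.default_rng(99)
        s0 = trials[0].vars.get("scene_rms", "sq00")
        s0.values = rng.permutation(s0.values)
        res2 = leave_one_trial_out(trials, "scene_rms", "sq00")
        assert np.array_equal(res1.predictions[0].dvs, res2.predictions[0].dvs)
        assert np.array_equal(res1.predictions[0].values, res2.predictions[0].values)

    def test_prediction_errors_follow_sign_errors(self):
        # time points the binary classifier misclassifies are exactly those
        # whose calibrated prediction lands on the wrong side of the
        # calibration midpoint (the sigmoid is monotone in the DV)
        trials = _toy_trials(snr=3.0, seed=7)
        res = leave_one_trial_out(trials, "scene_rms", "sq00")
        binz = Binarizer("scene_rms").fit(
            [t.vars.get("scene_rms", "sq00") for t in trials[1:]])
        lab = binz.transform(trials[0].vars.get("scene_rms", "sq00"))
        pred = res.predictions[0]
        sign_wrong = np.where(pred.dvs >= 0, 1, -1) != lab.labels
        assert 0 < sign_wrong.sum() < len(sign_wrong)  # imperfect but informative

    def test_mean_prediction_tracks_base_rate(self):
        trials = _toy_trials(snr=6.0)
        res = leave_one_trial_out(trials, "scene_rms", "sq00")
        mean_pred = np.mean([p.values.mean() for p in res.predictions])
        assert abs(mean_pred - 0.5) < 0.15  # median split: base rate 0.5

    def test_two_trials_minimum(self):
        with pytest.raises(ValueError):
            leave_one_trial_out(_toy_trials(n_trials=1), "scene_rms", "sq00")


class TestSerialization:
    def test_decoder_json_round_trip(self, tmp_path):
        from mazedecode.decode import decoder_from_json, decoder_to_json

        trials = _toy_trials()
        res = leave_one_trial_out(trials, "scene_rms", "sq00", roi="V1")
        # rebuild a calibrated decoder for trial-0's fold and round-trip it
        binz = Binarizer("scene_rms").fit(
            [t.vars.get("scene_rms", "sq00") for t in trials[1:]])
        labs = [binz.transform(t.vars.get("scene_rms", "sq00"), training=True)
                for t in trials[1:]]
        X = np.concatenate([t.X for t in trials[1:]])
        labeling = BinaryLabeling(np.concatenate([l.labels for l in labs]),
                                  np.concatenate([l.include for l in labs]), "r")
        dec_obj = train_decoder(X, labeling, "sq00", "V1")
        dvs = dec_obj.decision_values(X[labeling.include])
        dec_obj.calibration = calibrate(dvs, labeling.labels[labeling.include])
        path = tmp_path / "decoder.json"
        decoder_to_json(dec_obj, path)
        back = decoder_from_json(path)
        probe = trials[0].X
        assert np.allclose(back.decision_values(probe), dec_obj.decision_values(probe))
        assert np.allclose(back.calibration(dec_obj.decision_values(probe)),
                           dec_obj.calibration(dec_obj.decision_values(probe)))

    def test_predictions_tsv_export(self, tmp_path):
        from mazedecode.decode import predictions_to_tsv

        trials = _toy_trials(n_trials=3)
        res = leave_one_trial_out(trials, "scene_rms", "sq00")
        path = tmp_path / "preds.tsv"
        predictions_to_tsv({"sq00": res}, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "trial\tvariable\ttr\tdv\tpredicted"
        assert len(lines) == 1 + 3 * 24
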