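"""Metric correctness, LOSO integrity and the reporting convention."""

import numpy as np
import pytest
from scipy import stats

from gaitkinetics import (EvaluationReport, aggregate_report, compare_models,
                          loso_folds, nrmse, overall_from_component_means, pcc)
from gaitkinetics.evaluation import FoldSpec, evaluate_model, evaluate_windows
from gaitkinetics.exceptions import ConfigError, DegenerateInputError
from gaitkinetics.models import build_teacher
from gaitkinetics.synthetic import KINETIC_COMPONENTS


def _brute_nrmse(pred, truth):
    se = 0.0
    for p, t in zip(pred, truth):
        se += (p - t) ** 2
    rmse = (se / len(pred)) ** 0.5
    return 100.0 * rmse / (max(truth) - min(truth))


def _brute_pcc(pred, truth):
    n = len(pred)
    mp = sum(pred) / n
    mt = sum(truth) / n
    num = sum((p - mp) * (t - mt) for p, t in zip(pred, truth))
    dp = sum((p - mp) ** 2 for p in pred) ** 0.5
    dt = sum((t - mt) ** 2 for t in truth) ** 0.5
    return num / (dp * dt)


class TestNRMSE:
    def test_perfect_prediction_is_zero(self, rng):
        x = rng.normal(size=50)
        assert nrmse(x, x) == 0.0

    def test_hand_worked_example(self):
        truth = np.array([0.0, 1, 2, 3])
        np.testing.assert_allclose(nrmse(truth + 1, truth), 100.0 / 3,
                                   rtol=1e-12)

    def test_constant_truth_raises_not_inf(self):
        with pytest.raises(DegenerateInputError):
            nrmse(np.arange(4.0), np.ones(4))

    def test_matches_brute_force_loop(self, rng):
        for _ in range(20):
            t = rng.normal(size=30)
            p = t + rng.normal(size=30)
            np.testing.assert_allclose(nrmse(p, t),
                                       _brute_nrmse(list(p), list(t)),
                                       rtol=1e-12)


class TestPCC:
    def test_identity_and_negation(self, rng):
        x = rng.normal(size=40)
        np.testing.assert_allclose(pcc(x, x), 1.0, atol=1e-12)
        np.testing.assert_allclose(pcc(-x, x), -1.0, atol=1e-12)

    def test_hand_worked_example(self):
        r = pcc(np.array([1.0, 2, 4]), np.array([1.0, 2, 3]))
        assert round(r, 4) == 0.9820

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            pcc(np.ones(5), np.arange(5.0))

    def test_matches_brute_force_loop(self, rng):
        for _ in range(20):
            t = rng.normal(size=25)
            p = 0.3 * t + rng.normal(size=25)
            np.testing.assert_allclose(pcc(p, t),
                                       _brute_pcc(list(p), list(t)),
                                       rtol=1e-10)

    def test_shuffled_predictions_decorrelate(self, rng):
        t = rng.normal(size=3000)
        p = rng.permutation(t)
        assert abs(pcc(p, t)) < 0.1


class TestLosoFolds:
    def test_seventeen_subjects_give_seventeen_folds(self):
        labels = [f"S{i:02d}" for i in range(1, 18)]
        folds = loso_folds(labels, seed=0)
        assert len(folds) == 17
        assert sorted(f.test_subject for f in folds) == sorted(labels)

    def test_test_subject_never_in_training(self):
        folds = loso_folds(["a", "b", "c", "d"], seed=1)
        for f in folds:
            assert f.test_subject not in f.train_subjects
            assert f.validation_subject in f.train_subjects

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigError):
            loso_folds(["a", "b"])

    def test_window_level_leakage_canary(self, small_recordings):
        """Plant a unique constant per subject; it must never appear in
        another fold's training windows."""
        from gaitkinetics import window_dataset

        recs = small_recordings
        canary = {rec.subject_id: 1000.0 + i for i, rec in enumerate(recs)}
        for rec in recs:
            for trial in rec.trials:
                trial.imu_gyr = trial.imu_gyr.copy()
                trial.imu_gyr[:, 0, 0] = canary[rec.subject_id]
        ds = window_dataset(recs)
        folds = loso_folds([r.subject_id for r in recs], seed=0)
        for fold in folds:
            train = ds.subset(fold.train_subjects)
            assert canary[fold.test_subject] not in train.gyr
            test = ds.subset([fold.test_subject])
            assert np.all(test.gyr[:, :, 0] == canary[fold.test_subject])


class TestEvaluateModel:
    def test_perfect_oracle_scores(self, small_windows, tiny_model_cfg):
        """A model patched to return ground truth scores NRMSE 0, PCC 1."""
        model = build_teacher(tiny_model_cfg)
        model.is_trained = True
        truth_by_idx = small_windows.kinetics

        def perfect_forward(batch):
            from gaitkinetics.autodiff import Tensor
            key = batch["acc"]
            idx = [np.flatnonzero(
                (small_windows.acc == key[i]).all(axis=(1, 2)))[0]
                for i in range(key.shape[0])]
            return Tensor(truth_by_idx[idx])

        model.forward = perfect_forward
        fold = FoldSpec(test_subject=small_windows.subjects[0],
                        train_subjects=tuple(small_windows.subjects[1:]),
                        validation_subject=small_windows.subjects[1])
        metrics = evaluate_model(model, fold, small_windows)
        for c in KINETIC_COMPONENTS:
            assert metrics["nrmse"][c] < 1e-9
            assert metrics["pcc"][c] > 1 - 1e-9

    def test_untrained_model_rejected(self, small_windows, tiny_model_cfg):
        model = build_teacher(tiny_model_cfg)
        fold = FoldSpec(test_subject=small_windows.subjects[0],
                        train_subjects=tuple(small_windows.subjects[1:]),
                        validation_subject=small_windows.subjects[1])
        with pytest.raises(ConfigError):
            evaluate_model(model, fold, small_windows)

    def test_metrics_use_exactly_the_test_subject_frames(self, small_windows,
                                                         tiny_model_cfg):
        model = build_teacher(tiny_model_cfg)
        model.eval()
        model.is_trained = True
        test_subject = small_windows.subjects[0]
        sub = small_windows.subset([test_subject])
        from gaitkinetics.evaluation import predict_frames
        frames = predict_frames(model, sub)
        n_frames = sum(v.shape[0] for v in frames.values())
        n_expected = sum(1 for s in small_windows.subject_ids
                         if s == test_subject) * small_windows.window
        assert n_frames == n_expected


class TestOverlapAveraging:
    def test_overlapping_truth_reassembles_original_frames(
            self, small_recordings):
        """With stride < ΔT the per-frame reassembly must average
        agreeing copies back to the original trial values."""
        from gaitkinetics import window_dataset
        from gaitkinetics.evaluation import _frame_truth

        ds = window_dataset(small_recordings, window=50, stride=10)
        frames = _frame_truth(ds)
        for rec in small_recordings:
            for i, trial in enumerate(rec.trials):
                key = (rec.subject_id, i)
                T_covered = frames[key].shape[0]
                np.testing.assert_allclose(frames[key],
                                           trial.kinetics[:T_covered],
                                           atol=1e-12)

    def test_predictions_cover_every_windowed_frame(self, small_recordings,
                                                    tiny_model_cfg):
        from gaitkinetics import build_teacher, window_dataset
        from gaitkinetics.evaluation import predict_frames

        ds = window_dataset(small_recordings, window=50, stride=25)
        model = build_teacher(tiny_model_cfg)
        model.eval()
        frames = predict_frames(model, ds)
        for key, arr in frames.items():
            assert np.all(np.isfinite(arr))
            starts = [m[2] for m in ds.meta if (m[0], m[1]) == key]
            assert arr.shape[0] == max(starts) + ds.window


class TestAggregation:
    def _report(self, values):
        n = np.array(values, dtype=float)
        return EvaluationReport(
            subjects=[f"s{i}" for i in range(n.shape[0])],
            components=KINETIC_COMPONENTS,
            nrmse_values=n, pcc_values=np.clip(1 - n / 100, -1, 1))

    def test_overall_is_unweighted_component_mean(self):
        rep = self._report([[1, 2, 3, 4, 5], [3, 4, 5, 6, 7]])
        np.testing.assert_allclose(rep.overall_nrmse, 4.0)

    def test_equal_subjects_give_zero_sd(self):
        rep = self._report([[2, 2, 2, 2, 2], [2, 2, 2, 2, 2]])
        assert np.all(rep.component_sd_nrmse == 0)

    def test_single_subject_mean_is_value(self):
        rep = self._report([[1, 2, 3, 4, 5]])
        np.testing.assert_allclose(rep.component_mean_nrmse, [1, 2, 3, 4, 5])

    def test_missing_fold_rejected(self):
        with pytest.raises(ConfigError):
            aggregate_report({"s1": {"nrmse": {}, "pcc": {}}})

    def test_aggregate_report_round_trip(self):
        per_fold = {
            s: {"nrmse": {c: float(i + j) for j, c in
                          enumerate(KINETIC_COMPONENTS)},
                "pcc": {c: 0.9 for c in KINETIC_COMPONENTS}}
            for i, s in enumerate(["s1", "s2", "s3"])
        }
        rep = aggregate_report(per_fold)
        assert rep.subjects == ["s1", "s2", "s3"]
        np.testing.assert_allclose(rep.overall_pcc, 0.9)


class TestCompareModels:
    def _report(self, values):
        n = np.asarray(values, dtype=float)
        return EvaluationReport(subjects=[f"s{i}" for i in range(len(n))],
                                components=KINETIC_COMPONENTS,
                                nrmse_values=n,
                                pcc_values=np.clip(1 - n / 100, -1, 1))

    def test_identical_reports_not_significant(self):
        rep = self._report(np.full((5, 5), 3.0))
        out = compare_models(rep, rep)
        assert out["p_adjusted"] == 1.0
        assert not out["significant_0.05"]

    def test_constant_positive_difference_significant(self):
        a = self._report(np.full((4, 5), 5.0))
        b = self._report(np.full((4, 5), 4.0))
        out = compare_models(a, b)
        assert out["p_adjusted"] < 0.01
        assert out["mean_difference"] == 1.0

    def test_bonferroni_multiplies_and_caps(self, rng):
        base = rng.normal(5, 1, size=(6, 5))
        a = self._report(base)
        b = self._report(base + rng.normal(0.3, 0.4, size=(6, 5)))
        raw = compare_models(a, b, n_comparisons=1)
        adj = compare_models(a, b, n_comparisons=7)
        np.testing.assert_allclose(adj["p_adjusted"],
                                   min(1.0, raw["p_raw"] * 7))

    def test_subject_mismatch_rejected(self):
        a = self._report(np.full((4, 5), 5.0))
        b = self._report(np.full((5, 5), 5.0))
        with pytest.raises(ConfigError):
            compare_models(a, b)

    def test_agrees_with_scipy_on_random_data(self, rng):
        a_vals = rng.normal(5, 1, size=(8, 5))
        b_vals = a_vals + rng.normal(0.1, 0.5, size=(8, 5))
        a, b = self._report(a_vals), self._report(b_vals)
        out = compare_models(a, b)
        expected = stats.ttest_rel(a_vals.mean(axis=1),
                                   b_vals.mean(axis=1)).pvalue
        np.testing.assert_allclose(out["p_raw"], expected)


def test_overall_from_component_means_matches_numpy():
    vals = [5.03, 5.86, 4.41, 4.40, 3.69]
    np.testing.assert_allclose(overall_from_component_means(vals),
                               np.mean(vals))
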