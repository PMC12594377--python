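"""Training loop, KD loss arithmetic and knowledge-transfer freeze contracts."""

import numpy as np
import pytest

from gaitkinetics.autodiff import Tensor
from gaitkinetics.exceptions import ConfigError, DimensionError
from gaitkinetics.models import ModelConfig, build_student, build_teacher
from gaitkinetics.nn import Linear, parameter_hash, rmse_loss
from gaitkinetics.transfer import (KDConfig, TrainConfig,
                                   feature_alignment_loss, finetune_student,
                                   kd_loss, knowledge_transfer,
                                   pretrain_student_encoder,
                                   project_concat_features, split_validation,
                                   train_model)


class TestKDLoss:
    def test_alpha_zero_equals_plain_rmse(self, rng):
        truth = Tensor(rng.normal(size=(4, 10, 5)))
        pred_s = Tensor(rng.normal(size=(4, 10, 5)))
        pred_t = Tensor(rng.normal(size=(4, 10, 5)))
        cfg = KDConfig(alpha=0.0)
        assert float(kd_loss(pred_s, pred_t, truth, cfg).data) == \
            float(rmse_loss(pred_s, truth).data)

    def test_perfect_everything_gives_zero(self, rng):
        x = Tensor(rng.normal(size=(2, 5, 5)))
        p = Tensor(rng.normal(size=(2, 5, 3)))
        cfg = KDConfig(alpha=0.7, variant="vanilla_plus_layer_loss")
        loss = kd_loss(x, x, x, cfg, p, p)
        assert float(loss.data) < 1e-6

    def test_hand_worked_example(self):
        # truth=[0,0], pred_s=pred_t=[1,1], alpha=0.5 vanilla:
        # L_student = 1, L_KD = 0 -> total 1
        truth = Tensor(np.zeros((1, 2, 1)))
        pred = Tensor(np.ones((1, 2, 1)))
        loss = kd_loss(pred, pred, truth, KDConfig(alpha=0.5))
        np.testing.assert_allclose(float(loss.data), 1.0, atol=1e-6)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ConfigError):
            KDConfig(alpha=-0.1)


class TestFeatureAlignment:
    def test_zero_iff_equal(self, rng):
        s = Tensor(rng.normal(size=(3, 4, 8)))
        assert float(feature_alignment_loss(s, s).data) < 1e-9
        t = Tensor(s.data + 0.1)
        assert float(feature_alignment_loss(s, t).data) > 0

    def test_constant_offset_closed_form(self, rng):
        s = Tensor(rng.normal(size=(3, 4, 8)))
        delta = 0.37
        t = Tensor(s.data + delta)
        np.testing.assert_allclose(float(feature_alignment_loss(s, t).data),
                                   delta, atol=1e-6)

    def test_symmetry(self, rng):
        s = Tensor(rng.normal(size=(2, 3, 4)))
        t = Tensor(rng.normal(size=(2, 3, 4)))
        assert float(feature_alignment_loss(s, t).data) == \
            float(feature_alignment_loss(t, s).data)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(DimensionError):
            feature_alignment_loss(Tensor(np.zeros((2, 3, 4))),
                                   Tensor(np.zeros((2, 3, 5))))


class TestProjection:
    def test_width_and_linearity(self, rng):
        proj = Linear(12, 7, rng)
        x = Tensor(rng.normal(size=(2, 5, 12)))
        y = Tensor(rng.normal(size=(2, 5, 12)))
        out = project_concat_features(proj, x)
        assert out.shape == (2, 5, 7)
        left = project_concat_features(
            proj, Tensor(2 * x.data + 3 * y.data)).data
        right = (2 * project_concat_features(proj, x).data
                 + 3 * project_concat_features(proj, y).data
                 - 4 * proj.bias.data)   # affine correction
        np.testing.assert_allclose(left, right, atol=1e-9)

    def test_zero_input_gives_tiled_bias(self, rng):
        proj = Linear(6, 3, rng)
        out = project_concat_features(proj, Tensor(np.zeros((2, 4, 6)))).data
        np.testing.assert_allclose(out, np.broadcast_to(proj.bias.data,
                                                        (2, 4, 3)))

    def test_width_mismatch_rejected(self, rng):
        proj = Linear(6, 3, rng)
        with pytest.raises(DimensionError):
            project_concat_features(proj, Tensor(np.zeros((2, 4, 7))))


class TestTrainModel:
    def test_early_stop_after_patience_on_rigged_plateau(self, small_windows,
                                                         tiny_model_cfg):
        # learning rate 0 -> validation loss never improves after epoch 0,
        # so training stops after exactly `patience` non-improving epochs
        model = build_teacher(tiny_model_cfg)
        cfg = TrainConfig(learning_rate=0.0, epochs=40, patience=3,
                          batch_size=16, validation_policy="fraction", seed=0)
        history = train_model(model, small_windows, cfg)
        assert history.stopped_early
        assert history.n_epochs == 1 + cfg.patience
        assert history.best_epoch == 0

    def test_retained_weights_match_min_validation_epoch(self, small_windows,
                                                         tiny_model_cfg):
        model = build_teacher(tiny_model_cfg)
        cfg = TrainConfig(epochs=3, patience=3, batch_size=16,
                          validation_policy="fraction", seed=0)
        history = train_model(model, small_windows, cfg)
        assert history.best_epoch == int(np.argmin(history.val_loss))

    def test_same_seed_gives_identical_histories(self, small_windows,
                                                 tiny_model_cfg):
        histories = []
        for _ in range(2):
            model = build_teacher(tiny_model_cfg)
            cfg = TrainConfig(epochs=2, patience=2, batch_size=16,
                              validation_policy="fraction", seed=9)
            histories.append(train_model(model, small_windows, cfg))
        assert histories[0].train_loss == histories[1].train_loss
        assert histories[0].val_loss == histories[1].val_loss

    def test_empty_training_set_rejected(self, small_windows, tiny_model_cfg):
        model = build_teacher(tiny_model_cfg)
        empty = small_windows.subset([])
        cfg = TrainConfig(epochs=1, patience=1, seed=0)
        with pytest.raises(ConfigError):
            train_model(model, empty, cfg, small_windows)


class TestLearnability:
    def test_student_overfits_noiseless_linear_data(self):
        """On a tiny noiseless dataset the full student drives its training
        RMSE below 10% of the initial value within 40 epochs.

        Rate-scaled derivatives keep every modality's variance well above
        the batch-norm clamp in the noiseless setting."""
        from gaitkinetics import SimConfig, generate_dataset, window_dataset
        from gaitkinetics.models import ModelConfig, build_student

        sim = SimConfig(n_subjects=3, trials_per_subject=1, trial_length=250,
                        camera_noise_sd=0, imu_noise_sd=0,
                        kinetics_noise_sd=0, seed=31)
        ds = window_dataset(generate_dataset(sim), scale_by_rate=True)
        model = build_student(ModelConfig(hidden_dim=16, gcn_node_out=4,
                                          head_hidden=16, dropout=0.0,
                                          seed=31))
        cfg = TrainConfig(learning_rate=0.01, epochs=40, patience=40,
                          batch_size=4, validation_policy="fraction",
                          validation_fraction=0.2, seed=31)
        history = train_model(model, ds, cfg)
        assert history.train_loss[-1] < 0.1 * history.train_loss[0]


class TestSplitValidation:
    def test_subject_policy_holds_out_whole_subject(self, small_windows):
        cfg = TrainConfig(validation_policy="subject", seed=1)
        train, val = split_validation(small_windows, cfg)
        assert len(val.subjects) == 1
        assert val.subjects[0] not in train.subjects
        assert len(train) + len(val) == len(small_windows)

    def test_fraction_policy_sizes(self, small_windows):
        cfg = TrainConfig(validation_policy="fraction",
                          validation_fraction=0.25, seed=1)
        train, val = split_validation(small_windows, cfg)
        assert len(val) == round(0.25 * len(small_windows))


@pytest.fixture(scope="module")
def kt_setup(small_windows, tiny_model_cfg):
    cfg = TrainConfig(epochs=2, patience=2, batch_size=16,
                      validation_policy="fraction", seed=2)
    teacher = build_teacher(tiny_model_cfg)
    train_model(teacher, small_windows, cfg)
    return teacher, cfg


class TestKnowledgeTransferContracts:
    def test_untrained_teacher_rejected(self, small_windows, tiny_model_cfg):
        teacher = build_teacher(tiny_model_cfg)
        student = build_student(tiny_model_cfg)
        cfg = TrainConfig(epochs=1, patience=1, seed=0,
                          validation_policy="fraction")
        with pytest.raises(ConfigError):
            pretrain_student_encoder(student, teacher, small_windows, cfg)

    def test_finetune_requires_pretrained_encoder(self, small_windows,
                                                  tiny_model_cfg):
        student = build_student(tiny_model_cfg)
        cfg = TrainConfig(epochs=1, patience=1, seed=0,
                          validation_policy="fraction")
        with pytest.raises(ConfigError):
            finetune_student(student, small_windows, cfg)

    def test_teacher_frozen_through_step1_and_encoder_through_step2(
            self, kt_setup, small_windows, tiny_model_cfg):
        teacher, cfg = kt_setup
        student = build_student(tiny_model_cfg)
        teacher_hash = parameter_hash(teacher)
        pretrain_student_encoder(student, teacher, small_windows, cfg)
        assert parameter_hash(teacher) == teacher_hash

        from gaitkinetics.nn import Module

        class _Wrap(Module):
            def __init__(self, mods):
                super().__init__()
                self.mods = mods

        encoder_hash = parameter_hash(_Wrap(student.encoder_modules()))
        finetune_student(student, small_windows, cfg)
        assert parameter_hash(_Wrap(student.encoder_modules())) == encoder_hash
        assert parameter_hash(teacher) == teacher_hash

    def test_step2_trains_only_mfm_and_head(self, kt_setup, small_windows,
                                            tiny_model_cfg):
        teacher, cfg = kt_setup
        student = build_student(tiny_model_cfg)
        pretrain_student_encoder(student, teacher, small_windows, cfg)
        finetune_student(student, small_windows, cfg)
        trainable = sum(p.data.size for p in student.parameters()
                        if p.trainable)
        head_params = sum(p.data.size for m in student.head_modules()
                          for p in m.parameters())
        assert trainable == head_params

    def test_alpha_sweep_grid_schema(self, kt_setup, small_windows,
                                     tiny_model_cfg):
        import inspect

        from gaitkinetics.transfer import alpha_sweep

        # the default grid is 5 alphas x 2 loss variants = 10 runs
        sig = inspect.signature(alpha_sweep)
        assert (len(sig.parameters["alphas"].default)
                * len(sig.parameters["variants"].default)) == 10
        # run a reduced grid end to end and check the row schema
        teacher, cfg = kt_setup
        rows = alpha_sweep(teacher, small_windows, small_windows, cfg,
                           tiny_model_cfg, alphas=(0.5,),
                           variants=("vanilla",))
        assert len(rows) == 1
        assert {"alpha", "variant", "nrmse", "pcc"} <= set(rows[0])
        with pytest.raises(ConfigError):
            alpha_sweep(teacher, small_windows, small_windows, cfg,
                        tiny_model_cfg, alphas=())

    def test_fa_validation_not_worse_at_retained_checkpoint(
            self, kt_setup, small_windows, tiny_model_cfg):
        teacher, cfg = kt_setup
        student = build_student(tiny_model_cfg)
        _, _, history = pretrain_student_encoder(student, teacher,
                                                 small_windows, cfg)
        assert min(history.val_loss) <= history.val_loss[0]
        assert history.best_epoch == int(np.argmin(history.val_loss))
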