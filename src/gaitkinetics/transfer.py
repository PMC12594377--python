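"""Training loop, two-step multi-modal knowledge transfer and KD baseline.

Knowledge transfer (KT) runs in two steps against an already-trained,
frozen teacher:

1. **Feature alignment** — the student encoder and one linear projection
   per stream are trained to minimize the RMSE between the linearly
   projected student encoder features and the linearly projected teacher
   encoder features (the teacher stays in eval mode and its parameters are
   never touched).
2. **Head fine-tuning** — the pre-trained student encoder is frozen
   (weights and batch-norm statistics) and only the MFM and the output
   layers are trained on the RMSE against ground-truth kinetics.

The conventional knowledge-distillation baseline instead trains the whole
student jointly on ``L_student + α · L_KD`` where ``L_KD`` matches the
student's predictions (and optionally its projected features) to the
teacher's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor
from .exceptions import ConfigError, DimensionError
from .models import KineticsModel, ModelConfig
from .nn import Adam, Linear, Module, parameter_hash, rmse_loss
from .synthetic import WindowedDataset

logger = logging.getLogger("gaitkinetics")

__all__ = [
    "TrainConfig",
    "KDConfig",
    "TrainingHistory",
    "make_batches",
    "split_validation",
    "train_model",
    "project_concat_features",
    "feature_alignment_loss",
    "pretrain_student_encoder",
    "finetune_student",
    "kd_loss",
    "train_student_with_kd",
    "alpha_sweep",
]


@dataclass
class TrainConfig:
    """Optimization settings (Adam, RMSE loss, early stopping)."""

    learning_rate: float = 0.001
    epochs: int = 40
    patience: int = 10
    batch_size: int = 64
    validation_policy: str = "subject"   # subject | fraction
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.patience > self.epochs:
            raise ConfigError("patience must be <= epochs")
        if self.validation_policy not in ("subject", "fraction"):
            raise ConfigError("validation_policy must be 'subject' or 'fraction'")


@dataclass
class KDConfig:
    """Knowledge-distillation baseline settings."""

    alpha: float = 0.5
    variant: str = "vanilla"             # vanilla | vanilla_plus_layer_loss

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigError("alpha must be >= 0")
        if self.variant not in ("vanilla", "vanilla_plus_layer_loss"):
            raise ConfigError(f"unknown KD variant {self.variant!r}")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _model_batch(model: KineticsModel, ds: WindowedDataset, idx) -> dict:
    return {key: getattr(ds, key)[idx] for key, _ in model.spec.inputs}


def make_batches(n: int, batch_size: int, rng: np.random.Generator
                 ) -> list[np.ndarray]:
    """Shuffled index batches for one epoch."""
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def split_validation(ds: WindowedDataset, cfg: TrainConfig
                     ) -> tuple[WindowedDataset, WindowedDataset]:
    """Hold out a validation set: one whole subject (default, prevents
    window-level leakage) or a random fraction of windows."""
    if cfg.validation_policy == "subject":
        subjects = ds.subjects
        if len(subjects) < 2:
            raise ConfigError(
                "subject-level validation requires >= 2 training subjects"
            )
        rng = np.random.default_rng(cfg.seed)
        val_subject = subjects[int(rng.integers(len(subjects)))]
        train_subjects = [s for s in subjects if s != val_subject]
        return ds.subset(train_subjects), ds.subset([val_subject])
    rng = np.random.default_rng(cfg.seed)
    n = len(ds)
    n_val = max(1, int(round(cfg.validation_fraction * n)))
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    take = lambda idx: WindowedDataset(   # noqa: E731
        jcp=ds.jcp[idx], jcv=ds.jcv[idx], jca=ds.jca[idx],
        acc=ds.acc[idx], gyr=ds.gyr[idx], kinetics=ds.kinetics[idx],
        subject_ids=ds.subject_ids[idx],
        meta=[ds.meta[i] for i in idx], window=ds.window,
    )
    return take(train_idx), take(val_idx)


def _eval_loss(loss_fn, models: list[Module], ds: WindowedDataset,
               batch_size: int) -> float:
    """Dataset loss in eval mode (element-weighted across chunks)."""
    was_training = [m.training for m in models]
    for m in models:
        m.eval()
    total, count = 0.0, 0
    for start in range(0, len(ds), batch_size):
        idx = np.arange(start, min(start + batch_size, len(ds)))
        loss = loss_fn(idx, ds)
        total += float(loss.data) ** 2 * len(idx)
        count += len(idx)
    for m, mode in zip(models, was_training):
        m.training = mode
        if mode:
            m.train()
    return float(np.sqrt(total / max(count, 1)))


def _run_training(
    loss_fn,
    trainable_modules: list[Module],
    all_models: list[Module],
    train_ds: WindowedDataset,
    val_ds: WindowedDataset,
    cfg: TrainConfig,
) -> TrainingHistory:
    """Generic loop: Adam, early stopping, best-validation checkpointing.

    ``loss_fn(idx, ds)`` builds the scalar loss Tensor for the index batch.
    The retained weights are those with the smallest validation loss.
    """
    if len(train_ds) == 0:
        raise ConfigError("empty training set")
    params = [p for m in trainable_modules for p in m.parameters()]
    optimizer = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history = TrainingHistory()
    best_val = np.inf
    best_state = [m.copy_state() for m in trainable_modules]
    epochs_since_best = 0
    for epoch in range(cfg.epochs):
        for m in all_models:
            if m in trainable_modules:
                m.train()
        epoch_losses = []
        for idx in make_batches(len(train_ds), cfg.batch_size, rng):
            loss = loss_fn(idx, train_ds)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        train_loss = float(np.mean(epoch_losses))
        val_loss = _eval_loss(loss_fn, all_models, val_ds, cfg.batch_size)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        logger.info("epoch %d: train %.5f  val %.5f", epoch, train_loss, val_loss)
        if val_loss < best_val:
            best_val = val_loss
            history.best_epoch = epoch
            best_state = [m.copy_state() for m in trainable_modules]
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= cfg.patience:
                history.stopped_early = True
                break
    for m, state in zip(trainable_modules, best_state):
        m.load_state(state)
    for m in all_models:
        m.eval()
    return history


def train_model(model: KineticsModel, train_ds: WindowedDataset,
                cfg: TrainConfig, val_ds: WindowedDataset | None = None
                ) -> TrainingHistory:
    """Train a model on RMSE against ground-truth kinetics."""
    if val_ds is None:
        train_ds, val_ds = split_validation(train_ds, cfg)

    def loss_fn(idx, ds):
        pred = model.forward(_model_batch(model, ds, idx))
        return rmse_loss(pred, Tensor(ds.kinetics[idx]))

    history = _run_training(loss_fn, [model], [model], train_ds, val_ds, cfg)
    model.is_trained = True
    return history


# ---------------------------------------------------------------------------
# knowledge transfer
# ---------------------------------------------------------------------------

def project_concat_features(projection: Linear, features: Tensor) -> Tensor:
    """Single linear map of concatenated encoder features."""
    if features.shape[-1] != projection.in_features:
        raise DimensionError(
            f"projection expects width {projection.in_features}, got "
            f"{features.shape[-1]}"
        )
    return projection(features)


def feature_alignment_loss(student_proj: Tensor, teacher_proj: Tensor) -> Tensor:
    """RMSE between the two projected feature streams (symmetric, >= 0)."""
    if student_proj.shape != teacher_proj.shape:
        raise DimensionError("projected features must have equal shapes")
    return rmse_loss(student_proj, teacher_proj)


def _require_trained(teacher: KineticsModel) -> None:
    if not getattr(teacher, "is_trained", False):
        raise ConfigError("teacher must be trained before knowledge transfer")


def pretrain_student_encoder(
    student: KineticsModel,
    teacher: KineticsModel,
    train_ds: WindowedDataset,
    cfg: TrainConfig,
    val_ds: WindowedDataset | None = None,
    projection_dim: int | None = None,
) -> tuple[Linear, Linear, TrainingHistory]:
    """KT step 1: align projected student and teacher encoder features.

    Optimizes the student encoder together with the student-side projection
    on the feature-alignment loss only; the teacher stays frozen in eval
    mode and is bit-identical before and after.  The teacher-side
    projection is a *fixed* random linear map: if both projections were
    free, the alignment loss could be minimized by shrinking both toward
    zero without the encoder learning anything, whereas a frozen target
    projection makes the aligned signal information-bearing.  Returns the
    two projections and the training history; the student keeps its
    best-validation encoder.
    """
    _require_trained(teacher)
    if val_ds is None:
        train_ds, val_ds = split_validation(train_ds, cfg)
    projection_dim = projection_dim or student.cfg.projection_dim
    rng = np.random.default_rng(cfg.seed + 1)
    proj_s = Linear(student.enc_width, projection_dim, rng)
    proj_t = Linear(teacher.enc_width, projection_dim, rng)
    proj_t.set_trainable(False)
    teacher.eval()
    teacher.set_trainable(False)

    class _Wrap(Module):
        def __init__(self, mods):
            super().__init__()
            self.mods = mods

    enc = _Wrap(student.encoder_modules())
    projections = _Wrap([proj_s])

    def loss_fn(idx, ds):
        s_feat = student.encoder_forward(_model_batch(student, ds, idx))
        with_teacher = teacher.encoder_forward(_model_batch(teacher, ds, idx))
        t_feat = Tensor(with_teacher.data)   # constant: no grads into teacher
        return feature_alignment_loss(
            project_concat_features(proj_s, s_feat),
            project_concat_features(proj_t, t_feat),
        )

    history = _run_training(
        loss_fn, [enc, projections], [student, teacher, enc, projections],
        train_ds, val_ds, cfg,
    )
    student.is_pretrained = True
    return proj_s, proj_t, history


def finetune_student(
    student: KineticsModel,
    train_ds: WindowedDataset,
    cfg: TrainConfig,
    val_ds: WindowedDataset | None = None,
) -> TrainingHistory:
    """KT step 2: freeze the pre-trained encoder, train MFM + head on RMSE."""
    if not getattr(student, "is_pretrained", False):
        raise ConfigError(
            "student encoder must be pretrained (KT step 1) before fine-tuning"
        )
    if val_ds is None:
        train_ds, val_ds = split_validation(train_ds, cfg)
    student.freeze_encoder()

    class _Wrap(Module):
        def __init__(self, mods):
            super().__init__()
            self.mods = mods

    head = _Wrap(student.head_modules())

    def loss_fn(idx, ds):
        # the encoder is frozen (weights and statistics), so its output is
        # a constant of the optimization and can be detached
        enc = student.encoder_forward(_model_batch(student, ds, idx))
        pred = student.head(student.fuse(Tensor(enc.data)))
        return rmse_loss(pred, Tensor(ds.kinetics[idx]))

    history = _run_training(loss_fn, [head], [student, head],
                            train_ds, val_ds, cfg)
    student.is_trained = True
    return history


def knowledge_transfer(
    student: KineticsModel,
    teacher: KineticsModel,
    train_ds: WindowedDataset,
    cfg: TrainConfig,
    val_ds: WindowedDataset | None = None,
) -> tuple[TrainingHistory, TrainingHistory]:
    """Run both KT steps; returns (alignment history, fine-tune history)."""
    if val_ds is None:
        train_ds, val_ds = split_validation(train_ds, cfg)
    _, _, h1 = pretrain_student_encoder(student, teacher, train_ds, cfg, val_ds)
    h2 = finetune_student(student, train_ds, cfg, val_ds)
    return h1, h2


# ---------------------------------------------------------------------------
# knowledge-distillation baseline
# ---------------------------------------------------------------------------

def kd_loss(
    pred_student: Tensor,
    pred_teacher: Tensor,
    truth: Tensor,
    cfg: KDConfig,
    proj_student: Tensor | None = None,
    proj_teacher: Tensor | None = None,
) -> Tensor:
    """``L = L_student + α · L_KD``.

    ``L_student`` is the RMSE to ground truth; the first KD term is the
    RMSE between student and teacher predictions, and the
    ``vanilla_plus_layer_loss`` variant adds the RMSE between the projected
    encoder features.  With ``α = 0`` this is exactly the plain loss.
    """
    l_student = rmse_loss(pred_student, truth)
    if cfg.alpha == 0.0:
        return l_student
    l_kd = rmse_loss(pred_student, pred_teacher)
    if cfg.variant == "vanilla_plus_layer_loss":
        if proj_student is None or proj_teacher is None:
            raise ConfigError("layer loss requires projected features")
        l_kd = l_kd + feature_alignment_loss(proj_student, proj_teacher)
    return l_student + cfg.alpha * l_kd


def train_student_with_kd(
    student: KineticsModel,
    teacher: KineticsModel,
    train_ds: WindowedDataset,
    cfg: TrainConfig,
    kd: KDConfig,
    val_ds: WindowedDataset | None = None,
) -> TrainingHistory:
    """KD baseline: train the whole student jointly on the KD loss."""
    _require_trained(teacher)
    if val_ds is None:
        train_ds, val_ds = split_validation(train_ds, cfg)
    teacher.eval()
    teacher.set_trainable(False)
    rng = np.random.default_rng(cfg.seed + 1)
    need_proj = kd.variant == "vanilla_plus_layer_loss"
    proj_s = Linear(student.enc_width, student.cfg.projection_dim, rng)
    proj_t = Linear(teacher.enc_width, student.cfg.projection_dim, rng)

    class _Wrap(Module):
        def __init__(self, mods):
            super().__init__()
            self.mods = mods

    trainables: list[Module] = [student]
    if need_proj:
        trainables.append(_Wrap([proj_s, proj_t]))

    def loss_fn(idx, ds):
        s_batch = _model_batch(student, ds, idx)
        t_batch = _model_batch(teacher, ds, idx)
        pred_s = student.forward(s_batch)
        pred_t = Tensor(teacher.forward(t_batch).data)
        ps = pt = None
        if need_proj:
            s_feat = student.encoder_forward(s_batch)
            t_feat = Tensor(teacher.encoder_forward(t_batch).data)
            ps = project_concat_features(proj_s, s_feat)
            pt = project_concat_features(proj_t, t_feat)
        return kd_loss(pred_s, pred_t, Tensor(ds.kinetics[idx]), kd, ps, pt)

    history = _run_training(loss_fn, trainables,
                            trainables + [teacher], train_ds, val_ds, cfg)
    student.is_trained = True
    return history


def alpha_sweep(
    teacher: KineticsModel,
    train_ds: WindowedDataset,
    test_ds: WindowedDataset,
    cfg: TrainConfig,
    model_cfg: ModelConfig,
    alphas: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
    variants: tuple[str, ...] = ("vanilla", "vanilla_plus_layer_loss"),
) -> list[dict]:
    """Train one KD student per (α, variant) and tabulate test metrics."""
    from .evaluation import evaluate_windows
    from .models import build_student

    if not alphas:
        raise ConfigError("alpha sweep requires at least one alpha")
    rows: list[dict] = []
    for variant in variants:
        for alpha in alphas:
            student = build_student(model_cfg)
            kd = KDConfig(alpha=alpha, variant=variant)
            history = train_student_with_kd(student, teacher, train_ds,
                                            cfg, kd)
            metrics = evaluate_windows(student, test_ds)
            rows.append({
                "alpha": alpha,
                "variant": variant,
                "nrmse": float(np.mean(list(metrics["nrmse"].values()))),
                "pcc": float(np.mean(list(metrics["pcc"].values()))),
                "best_epoch": history.best_epoch,
            })
    return rows
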