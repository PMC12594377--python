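"""Experiment orchestration: simulate -> LOSO -> train -> transfer -> report.

``run_experiment`` executes the three-stage workflow per leave-one-subject-
out fold: train the teacher on the fold's training subjects, run the
two-step knowledge transfer into the student, evaluate on the held-out
subject, and aggregate across folds.  Additional no-transfer variants can
be trained per fold to reproduce the ablation grid.  Folds are resumable:
with an output directory, finished folds are skipped on re-run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from .data_io import ExperimentConfig, config_hash
from .evaluation import (EvaluationReport, aggregate_report, evaluate_model,
                         loso_folds)
from .models import ModelConfig, build_student, build_teacher, build_variant
from .synthetic import generate_dataset, window_dataset
from .transfer import TrainConfig, knowledge_transfer, train_model

logger = logging.getLogger("gaitkinetics")

__all__ = ["run_experiment", "run_fold", "kt_benefit_trial",
           "noiseless_teacher_sanity"]


# ---------------------------------------------------------------------------
# desk-scale benchmark profiles
# ---------------------------------------------------------------------------
#
# Both profiles run end to end on one CPU core.  The smoke-scale datasets
# provide only a handful of Adam update steps per epoch, so the profiles use
# a higher learning rate (and, for the transfer benchmark, a smaller batch)
# than the full-scale training defaults.

def _mean_metrics(model, test_ds) -> dict[str, float]:
    from .evaluation import evaluate_windows
    m = evaluate_windows(model, test_ds)
    return {"nrmse": float(np.mean(list(m["nrmse"].values()))),
            "pcc": float(np.mean(list(m["pcc"].values())))}


def kt_benefit_trial(seed: int) -> dict[str, dict[str, float]]:
    """One seed of the knowledge-transfer benefit benchmark.

    Default-noise synthetic cohort of 10 subjects (2 × 3 s trials each);
    the last subject is the test subject, the second-to-last the validation
    subject.  Teacher, student-without-transfer and the two-step transfer
    student are trained under identical conditions (C = 32, 15 epochs per
    stage, batch 16, lr 0.005) and scored on the held-out subject.
    """
    from .models import build_student, build_teacher
    from .synthetic import SimConfig, generate_dataset, window_dataset
    from .transfer import knowledge_transfer, train_model

    sim = SimConfig(n_subjects=10, trials_per_subject=2, trial_length=300,
                    seed=seed)
    ds = window_dataset(generate_dataset(sim))
    subs = ds.subjects
    train_ds = ds.subset(subs[:-2])
    val_ds = ds.subset([subs[-2]])
    test_ds = ds.subset([subs[-1]])
    mc = ModelConfig(hidden_dim=32, seed=seed)
    tc = TrainConfig(learning_rate=0.005, epochs=15, patience=15,
                     batch_size=16, seed=seed)

    teacher = build_teacher(mc)
    train_model(teacher, train_ds, tc, val_ds)
    student_plain = build_student(mc)
    train_model(student_plain, train_ds, tc, val_ds)
    student_kt = build_student(mc)
    knowledge_transfer(student_kt, teacher, train_ds, tc, val_ds)
    return {"teacher": _mean_metrics(teacher, test_ds),
            "student_no_kt": _mean_metrics(student_plain, test_ds),
            "student_kt": _mean_metrics(student_kt, test_ds)}


def noiseless_teacher_sanity(seed: int) -> dict[str, float]:
    """Noiseless-simulator sanity benchmark.

    Every stochastic perturbation of the simulator — measurement noise,
    subject-level coefficient jitter and per-channel frequency detuning —
    is zero, so the kinetics are an exact shared linear function of the
    kinematics; a teacher trained on 3 subjects (C = 32, no dropout,
    lr 0.003, 150 epochs) should fit a held-out subject almost perfectly.
    ``seed`` selects the simulated cohort; initialization and batching use
    fixed benchmark seeds.  Returns the held-out mean NRMSE (percent) and
    PCC.
    """
    from .models import build_teacher
    from .synthetic import SimConfig, generate_dataset, window_dataset
    from .transfer import train_model

    sim = SimConfig(n_subjects=5, trials_per_subject=4, trial_length=600,
                    camera_noise_sd=0.0, imu_noise_sd=0.0,
                    kinetics_noise_sd=0.0, subject_effect_sd=0.0,
                    freq_detune_sd=0.0, seed=seed)
    ds = window_dataset(generate_dataset(sim))
    subs = ds.subjects
    train_ds = ds.subset(subs[:3])
    val_ds = ds.subset([subs[3]])
    test_ds = ds.subset([subs[4]])
    mc = ModelConfig(hidden_dim=32, dropout=0.0, seed=0)
    tc = TrainConfig(learning_rate=0.003, epochs=150, patience=30, seed=0)
    teacher = build_teacher(mc)
    train_model(teacher, train_ds, tc, val_ds)
    return _mean_metrics(teacher, test_ds)


def _fold_seed(base_seed: int, fold_index: int) -> int:
    # one derived sub-seed per fold, kept below 2**31
    return int((base_seed * 1_000_003 + fold_index * 7919 + 1) % (2 ** 31))


def run_fold(cfg: ExperimentConfig, fold, ds, fold_index: int) -> dict:
    """Train teacher + KT student (and requested variants) on one fold."""
    seed = _fold_seed(cfg.seed, fold_index)
    train_ds = ds.subset([s for s in fold.train_subjects
                          if s != fold.validation_subject])
    val_ds = ds.subset([fold.validation_subject])
    tcfg = dataclasses.replace(cfg.train, seed=seed)

    results: dict = {"fold": fold.test_subject, "seed": seed}
    teacher = build_teacher(dataclasses.replace(cfg.model, seed=seed))
    train_model(teacher, train_ds, tcfg, val_ds)
    results["teacher"] = evaluate_model(teacher, fold, ds)

    student = build_student(dataclasses.replace(cfg.model, seed=seed + 1))
    knowledge_transfer(student, teacher, train_ds, tcfg, val_ds)
    results["student_kt"] = evaluate_model(student, fold, ds)

    for name in cfg.variants:
        model = build_variant(name, dataclasses.replace(cfg.model,
                                                        seed=seed + 2))
        train_model(model, train_ds, tcfg, val_ds)
        results[name] = evaluate_model(model, fold, ds)
    return results


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None
                   ) -> dict[str, EvaluationReport]:
    """Run the full workflow; returns one report per trained model kind."""
    recordings = generate_dataset(dataclasses.replace(cfg.sim, seed=cfg.seed))
    ds = window_dataset(recordings, window=cfg.sim.window, stride=cfg.stride)
    folds = loso_folds([r.subject_id for r in recordings], seed=cfg.seed)
    if cfg.max_folds is not None:
        folds = folds[:cfg.max_folds]

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "config.json").write_text(json.dumps(
            {"config": cfg.to_dict(), "config_hash": config_hash(cfg.to_dict()),
             "seed": cfg.seed}, indent=1))

    per_fold: list[dict] = []
    for i, fold in enumerate(folds):
        fold_file = (out_path / f"fold_{fold.test_subject}.json"
                     if out_path is not None else None)
        if fold_file is not None and fold_file.exists():
            logger.info("fold %s already done; skipping", fold.test_subject)
            per_fold.append(json.loads(fold_file.read_text()))
            continue
        logger.info("running fold %d/%d (test=%s)", i + 1, len(folds),
                    fold.test_subject)
        result = run_fold(cfg, fold, ds, i)
        per_fold.append(result)
        if fold_file is not None:
            fold_file.write_text(json.dumps(result, indent=1))

    model_kinds = [k for k in per_fold[0]
                   if k not in ("fold", "seed")]
    reports = {}
    for kind in model_kinds:
        reports[kind] = aggregate_report(
            {r["fold"]: r[kind] for r in per_fold})
    if out_path is not None:
        (out_path / "report.json").write_text(json.dumps(
            {k: v.to_dict() for k, v in reports.items()}, indent=1))
    return reports
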