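"""Metrics, leave-one-subject-out protocol and report aggregation.

Metrics follow the field's reporting convention for gait-kinetics
estimation:

* **NRMSE** — RMSE between prediction and ground truth, divided by the
  range (max − min) of the ground-truth series of the evaluated subject and
  component, in percent;
* **PCC** — the Pearson correlation between the concatenated predicted and
  ground-truth frames of a subject.

Per-component values are averaged across subjects, and the *overall* value
of a model is the unweighted mean of the five component means.  Model
comparison uses a paired t-test on per-subject overall metrics with
Bonferroni correction — a surrogate for the repeated-measures ANOVA +
post-hoc procedure used with commercial statistics software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigError, DegenerateInputError, DimensionError
from .models import KineticsModel
from .synthetic import KINETIC_COMPONENTS, WindowedDataset

__all__ = [
    "FoldSpec",
    "EvaluationReport",
    "nrmse",
    "pcc",
    "loso_folds",
    "predict_frames",
    "evaluate_windows",
    "evaluate_model",
    "aggregate_report",
    "overall_from_component_means",
    "compare_models",
]


@dataclass(frozen=True)
class FoldSpec:
    """One leave-one-subject-out fold."""

    test_subject: str
    train_subjects: tuple[str, ...]
    validation_subject: str

    def __post_init__(self) -> None:
        if self.test_subject in self.train_subjects:
            raise ConfigError("test subject must not appear in training set")
        if self.validation_subject not in self.train_subjects:
            raise ConfigError("validation subject must come from the training set")


@dataclass
class EvaluationReport:
    """Per-subject, per-component metrics plus the summary convention."""

    subjects: list[str]
    components: tuple[str, ...]
    nrmse_values: np.ndarray   # [n_subjects, n_components], percent
    pcc_values: np.ndarray     # [n_subjects, n_components]

    @property
    def component_mean_nrmse(self) -> np.ndarray:
        return self.nrmse_values.mean(axis=0)

    @property
    def component_sd_nrmse(self) -> np.ndarray:
        return self.nrmse_values.std(axis=0, ddof=1) \
            if len(self.subjects) > 1 else np.zeros(len(self.components))

    @property
    def component_mean_pcc(self) -> np.ndarray:
        return self.pcc_values.mean(axis=0)

    @property
    def component_sd_pcc(self) -> np.ndarray:
        return self.pcc_values.std(axis=0, ddof=1) \
            if len(self.subjects) > 1 else np.zeros(len(self.components))

    @property
    def overall_nrmse(self) -> float:
        """Unweighted mean over the five components of subject-averaged NRMSE."""
        return float(self.component_mean_nrmse.mean())

    @property
    def overall_pcc(self) -> float:
        return float(self.component_mean_pcc.mean())

    def per_subject_overall(self, metric: str = "nrmse") -> np.ndarray:
        values = self.nrmse_values if metric == "nrmse" else self.pcc_values
        return values.mean(axis=1)

    def to_dict(self) -> dict:
        return {
            "subjects": self.subjects,
            "components": list(self.components),
            "nrmse": {
                c: {"mean": float(m), "sd": float(s)}
                for c, m, s in zip(self.components, self.component_mean_nrmse,
                                   self.component_sd_nrmse)
            },
            "pcc": {
                c: {"mean": float(m), "sd": float(s)}
                for c, m, s in zip(self.components, self.component_mean_pcc,
                                   self.component_sd_pcc)
            },
            "overall_nrmse": self.overall_nrmse,
            "overall_pcc": self.overall_pcc,
        }


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def nrmse(pred: np.ndarray, truth: np.ndarray, label: str = "") -> float:
    """``100 · RMSE / (max(truth) − min(truth))``, in percent."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise DimensionError("prediction and truth lengths differ")
    if truth.size < 2:
        raise DegenerateInputError("need at least 2 frames")
    rng = truth.max() - truth.min()
    if rng == 0:
        raise DegenerateInputError(
            f"ground-truth range is zero{f' for {label}' if label else ''}"
        )
    rmse = np.sqrt(np.mean((pred - truth) ** 2))
    return float(100.0 * rmse / rng)


def pcc(pred: np.ndarray, truth: np.ndarray, label: str = "") -> float:
    """Pearson correlation coefficient between the two series."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.shape != truth.shape:
        raise DimensionError("prediction and truth lengths differ")
    if truth.size < 2:
        raise DegenerateInputError("need at least 2 frames")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        raise DegenerateInputError(
            f"constant series has no correlation"
            f"{f' ({label})' if label else ''}"
        )
    return float(stats.pearsonr(pred, truth).statistic)


# ---------------------------------------------------------------------------
# leave-one-subject-out protocol
# ---------------------------------------------------------------------------

def loso_folds(subject_labels, seed: int = 0) -> list[FoldSpec]:
    """One fold per subject; a validation subject is drawn from each fold's
    training subjects with the given seed."""
    labels = list(subject_labels)
    if len(labels) < 3:
        raise ConfigError("leave-one-subject-out requires at least 3 subjects")
    if len(set(labels)) != len(labels):
        raise ConfigError("subject labels must be unique")
    rng = np.random.default_rng(seed)
    folds = []
    for test in labels:
        train = tuple(s for s in labels if s != test)
        val = train[int(rng.integers(len(train)))]
        folds.append(FoldSpec(test_subject=test, train_subjects=train,
                              validation_subject=val))
    return folds


def predict_frames(model: KineticsModel, ds: WindowedDataset,
                   batch_size: int = 256) -> dict[tuple[str, int], np.ndarray]:
    """Frame-level predictions per (subject, trial), overlap-averaged.

    Window predictions are scattered back onto trial frames; where windows
    overlap (stride < ΔT) the predictions for a frame are averaged.
    Returns truth-aligned arrays only for frames covered by some window.
    """
    model.eval()
    preds = np.empty((len(ds), ds.window, len(KINETIC_COMPONENTS)))
    for start in range(0, len(ds), batch_size):
        idx = np.arange(start, min(start + batch_size, len(ds)))
        batch = {key: getattr(ds, key)[idx] for key, _ in model.spec.inputs}
        preds[idx] = model.forward(batch).data
    # scatter to frames
    sums: dict[tuple[str, int], np.ndarray] = {}
    counts: dict[tuple[str, int], np.ndarray] = {}
    for w, (subject, trial, start) in enumerate(ds.meta):
        key = (subject, trial)
        end = start + ds.window
        if key not in sums:
            sums[key] = np.zeros((end, len(KINETIC_COMPONENTS)))
            counts[key] = np.zeros(end)
        elif sums[key].shape[0] < end:
            grow = end - sums[key].shape[0]
            sums[key] = np.vstack([sums[key],
                                   np.zeros((grow, len(KINETIC_COMPONENTS)))])
            counts[key] = np.concatenate([counts[key], np.zeros(grow)])
        sums[key][start:end] += preds[w]
        counts[key][start:end] += 1.0
    out = {}
    for key in sums:
        covered = counts[key] > 0
        frames = sums[key].copy()
        frames[covered] /= counts[key][covered, None]
        out[key] = frames[covered]
    return out


def _frame_truth(ds: WindowedDataset) -> dict[tuple[str, int], np.ndarray]:
    """Ground-truth frames assembled the same way as the predictions."""
    sums: dict[tuple[str, int], np.ndarray] = {}
    counts: dict[tuple[str, int], np.ndarray] = {}
    for w, (subject, trial, start) in enumerate(ds.meta):
        key = (subject, trial)
        end = start + ds.window
        if key not in sums:
            sums[key] = np.zeros((end, len(KINETIC_COMPONENTS)))
            counts[key] = np.zeros(end)
        elif sums[key].shape[0] < end:
            grow = end - sums[key].shape[0]
            sums[key] = np.vstack([sums[key],
                                   np.zeros((grow, len(KINETIC_COMPONENTS)))])
            counts[key] = np.concatenate([counts[key], np.zeros(grow)])
        sums[key][start:end] += ds.kinetics[w]
        counts[key][start:end] += 1.0
    out = {}
    for key in sums:
        covered = counts[key] > 0
        frames = sums[key].copy()
        frames[covered] /= counts[key][covered, None]
        out[key] = frames[covered]
    return out


def evaluate_windows(model: KineticsModel, ds: WindowedDataset
                     ) -> dict[str, dict[str, float]]:
    """Per-component NRMSE/PCC over all frames of a windowed dataset."""
    preds = predict_frames(model, ds)
    truths = _frame_truth(ds)
    pred_cat = np.vstack([preds[k] for k in sorted(preds)])
    truth_cat = np.vstack([truths[k] for k in sorted(truths)])
    return {
        "nrmse": {c: nrmse(pred_cat[:, i], truth_cat[:, i], label=c)
                  for i, c in enumerate(KINETIC_COMPONENTS)},
        "pcc": {c: pcc(pred_cat[:, i], truth_cat[:, i], label=c)
                for i, c in enumerate(KINETIC_COMPONENTS)},
    }


def evaluate_model(model: KineticsModel, fold: FoldSpec,
                   ds: WindowedDataset) -> dict[str, dict[str, float]]:
    """Evaluate a fold's trained model on its held-out test subject."""
    if not getattr(model, "is_trained", False):
        raise ConfigError("model must be trained before evaluation")
    test_ds = ds.subset([fold.test_subject])
    if len(test_ds) == 0:
        raise ConfigError(f"no windows for test subject {fold.test_subject}")
    return evaluate_windows(model, test_ds)


def aggregate_report(per_fold_metrics: dict[str, dict[str, dict[str, float]]]
                     ) -> EvaluationReport:
    """Aggregate per-subject metrics to the summary convention.

    ``per_fold_metrics`` maps test-subject label to the metric dict returned
    by :func:`evaluate_model`.
    """
    if not per_fold_metrics:
        raise ConfigError("no folds to aggregate")
    subjects = sorted(per_fold_metrics)
    for s in subjects:
        m = per_fold_metrics[s]
        missing = [c for c in KINETIC_COMPONENTS
                   if c not in m.get("nrmse", {}) or c not in m.get("pcc", {})]
        if missing:
            raise ConfigError(f"subject {s} is missing components {missing}")
    nr = np.array([[per_fold_metrics[s]["nrmse"][c] for c in KINETIC_COMPONENTS]
                   for s in subjects])
    pc = np.array([[per_fold_metrics[s]["pcc"][c] for c in KINETIC_COMPONENTS]
                   for s in subjects])
    return EvaluationReport(subjects=subjects, components=KINETIC_COMPONENTS,
                            nrmse_values=nr, pcc_values=pc)


def overall_from_component_means(component_means) -> float:
    """The summary convention: unweighted mean of the component means."""
    values = np.asarray(list(component_means), dtype=float)
    if values.size == 0:
        raise ConfigError("no component means given")
    return float(values.mean())


def compare_models(report_a: EvaluationReport, report_b: EvaluationReport,
                   metric: str = "nrmse", n_comparisons: int = 1) -> dict:
    """Paired test on per-subject overall metrics with Bonferroni correction.

    Returns the raw and adjusted p-values with significance flags at the
    0.05 and 0.01 thresholds.  Exactly tied samples give p = 1; a constant
    nonzero difference (zero variance) is treated as maximally significant.
    """
    if report_a.subjects != report_b.subjects:
        raise ConfigError("reports cover different subjects")
    if n_comparisons < 1:
        raise ConfigError("n_comparisons must be >= 1")
    a = report_a.per_subject_overall(metric)
    b = report_b.per_subject_overall(metric)
    diff = a - b
    if np.allclose(diff, 0.0):
        p_raw = 1.0
    elif np.std(diff) == 0.0:
        p_raw = 0.0   # constant nonzero difference: exact-tie rule
    else:
        p_raw = float(stats.ttest_rel(a, b).pvalue)
    p_adj = min(1.0, p_raw * n_comparisons)
    return {
        "metric": metric,
        "mean_difference": float(diff.mean()),
        "p_raw": p_raw,
        "p_adjusted": p_adj,
        "significant_0.05": p_adj < 0.05,
        "significant_0.01": p_adj < 0.01,
        "n_comparisons": n_comparisons,
    }
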