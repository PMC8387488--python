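"""Evaluation protocol: 80/20 split, 5-fold cross-validation, metrics, ROC/AUC,
and the extractor/classifier benchmark grid.

Splits are stratified by label and grouped by recording: every segment of a
recording lands on the same side of every split, so overlapping segments can
never leak between training and evaluation. The held-out 20% test set is
scored by the ensemble mean of the five fold models' probabilities.

Per-class precision/recall/F1 follow the usual confusion-matrix definitions
(zero denominators return 0 with a flag); multiclass ROC is one-vs-rest with
trapezoidal AUC and a Hanley-McNeil 95% confidence interval, and "mean AUC"
is the unweighted mean over classes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .classify import (
    TASK_CLASSES,
    TrainConfig,
    predict,
    to_binary_labels,
    train_head,
)
from .extract import extract_features, get_extractor

__all__ = [
    "FoldPlan",
    "EvaluationReport",
    "StratificationError",
    "UndefinedAUCError",
    "make_fold_plan",
    "compute_metrics",
    "roc_auc",
    "run_cv",
    "benchmark",
]


class StratificationError(ValueError):
    """Too few recordings per class to stratify the requested splits."""


class UndefinedAUCError(ValueError):
    """ROC/AUC undefined: truth contains only one class."""


@dataclass(frozen=True)
class FoldPlan:
    """Recording-level split plan: held-out test ids plus five
    (train, validation) partitions of the remaining 80%."""

    test_ids: tuple
    folds: tuple  # of (train_ids, validation_ids) tuples
    seed: int

    @property
    def training_ids(self) -> tuple:
        out = []
        for _, val in self.folds:
            out.extend(val)
        return tuple(sorted(out))


def make_fold_plan(
    ids, labels, seed: int, n_folds: int = 5, test_frac: float = 0.2
) -> FoldPlan:
    """Stratified 80/20 split plus stratified k-fold partition of the 80%.

    Each training recording appears in exactly one validation block and in
    the training side of the other k-1 folds. Deterministic given the seed.
    """
    ids = list(ids)
    labels = list(labels)
    if len(ids) != len(labels):
        raise ValueError("ids and labels must have equal length")
    if len(ids) < 10:
        raise StratificationError("need at least 10 recordings for a fold plan")
    if len(set(labels)) < 2:
        raise StratificationError("need at least 2 classes for stratification")
    counts = pd.Series(labels).value_counts()
    if (counts < max(2, n_folds)).any():
        small = counts[counts < max(2, n_folds)].to_dict()
        raise StratificationError(
            f"classes too small to stratify into {n_folds} folds: {small}"
        )
    idx = np.arange(len(ids))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, stratify=labels, random_state=seed
    )
    y_train = [labels[i] for i in train_idx]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = []
    for tr, va in skf.split(train_idx, y_train):
        folds.append(
            (
                tuple(sorted(ids[i] for i in train_idx[tr])),
                tuple(sorted(ids[i] for i in train_idx[va])),
            )
        )
    return FoldPlan(
        test_ids=tuple(sorted(ids[i] for i in test_idx)),
        folds=tuple(folds),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_metrics(y_true, y_pred, class_set) -> dict:
    """Accuracy, per-class precision/recall/F1, macro averages, confusion matrix."""
    class_set = tuple(class_set)
    y_true, y_pred = list(y_true), list(y_pred)
    bad = (set(y_true) | set(y_pred)) - set(class_set)
    if bad:
        raise ValueError(f"labels {sorted(bad)} outside class set {class_set}")
    cm = confusion_matrix(y_true, y_pred, labels=list(class_set))
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=list(class_set), zero_division=0
    )
    per_class = {}
    for i, cls in enumerate(class_set):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        per_class[cls] = {
            "precision": float(prec[i]),
            "recall": float(rec[i]),
            "f1": float(f1[i]),
            "support": int(support[i]),
            "zero_division": bool((tp + fp == 0) or (tp + fn == 0)),
        }
    return {
        "accuracy": float(np.trace(cm) / max(cm.sum(), 1)),
        "per_class": per_class,
        "macro_precision": float(np.mean(prec)),
        "macro_recall": float(np.mean(rec)),
        "macro_f1": float(np.mean(f1)),
        "confusion_matrix": cm.tolist(),
        "classes": list(class_set),
    }


def _hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int) -> tuple[float, float]:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = np.sqrt(max(var, 0.0))
    return (max(auc - 1.96 * se, 0.0), min(auc + 1.96 * se, 1.0))


def roc_auc(y_true, scores, class_names) -> dict:
    """One-vs-rest ROC points, trapezoidal AUC and 95% CI per class; mean AUC.

    ``scores``: (N, C) probability matrix aligned with ``class_names``, or a
    1-D positive-class score vector for the binary case (positive class =
    ``class_names[1]``).
    """
    class_names = tuple(class_names)
    y_true = list(y_true)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = np.column_stack([1.0 - scores, scores])
    if scores.shape != (len(y_true), len(class_names)):
        raise ValueError("scores must be (n_samples, n_classes)")
    if len(set(y_true)) < 2:
        raise UndefinedAUCError("AUC undefined: truth contains a single class")
    out = {"per_class": {}, "mean_auc": None}
    aucs = []
    for j, cls in enumerate(class_names):
        truth = np.array([1 if t == cls else 0 for t in y_true])
        n_pos, n_neg = int(truth.sum()), int(len(truth) - truth.sum())
        if n_pos == 0 or n_neg == 0:
            raise UndefinedAUCError(
                f"AUC undefined for class {cls!r}: one-sided truth"
            )
        fpr, tpr, _ = roc_curve(truth, scores[:, j])
        auc = float(np.trapezoid(tpr, fpr))
        out["per_class"][cls] = {
            "auc": auc,
            "ci95": _hanley_mcneil_ci(auc, n_pos, n_neg),
            "fpr": fpr.tolist(),
            "tpr": tpr.tolist(),
        }
        aucs.append(auc)
    out["mean_auc"] = float(np.mean(aucs))
    return out


# ---------------------------------------------------------------------------
# cross-validated runs
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-fold validation metrics, their means, and held-out test results."""

    task: str
    folds: list = field(default_factory=list)
    fold_mean: dict = field(default_factory=dict)
    test: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "folds": self.folds,
            "fold_mean": self.fold_mean,
            "test": self.test,
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def _task_view(labels, task):
    """(keep_mask, mapped_labels) restricting/collapsing 4-class labels."""
    labels = list(labels)
    if task == "binary_normal_abnormal":
        return np.ones(len(labels), bool), to_binary_labels(labels)
    if task == "three_class_abnormal":
        mask = np.array([lab != "normal" for lab in labels])
        return mask, [lab for lab in labels if lab != "normal"]
    return np.ones(len(labels), bool), labels


def run_cv(
    features,
    labels,
    recording_ids,
    plan: FoldPlan,
    head_kind: str = "cnn_one_layer",
    task: str = "four_class_flat",
    config: TrainConfig | None = None,
) -> EvaluationReport:
    """Train one head per fold under the plan; report fold means and the
    ensemble-scored held-out test metrics.

    ``features`` is a batch aligned with ``labels`` and ``recording_ids``
    (one entry per segment); all selection happens at recording level.
    """
    cfg = config or TrainConfig()
    from .classify import _as_tensor_batch  # single canonical coercion

    t, _ = _as_tensor_batch(features)
    labels = list(labels)
    rec = np.asarray(recording_ids)
    keep, view_labels = _task_view(labels, task)
    t = t[keep]
    rec = rec[keep]
    y = np.asarray(view_labels)
    classes = TASK_CLASSES[task]

    def _sel(idset):
        return np.isin(rec, list(idset))

    report = EvaluationReport(task=task, seed=cfg.seed, config=asdict(cfg))
    test_mask = _sel(plan.test_ids)
    test_probs = np.zeros((int(test_mask.sum()), len(classes)))
    for k, (train_ids, val_ids) in enumerate(plan.folds):
        tr, va = _sel(train_ids), _sel(val_ids)
        head = train_head(
            head_kind,
            task,
            t[tr],
            y[tr].tolist(),
            config=cfg,
            validation=(t[va], y[va].tolist()),
        )
        val_pred = predict(head, t[va])
        fold_metrics = compute_metrics(y[va].tolist(), val_pred.labels, classes)
        fold_metrics["fold"] = k
        report.folds.append(fold_metrics)
        if test_mask.any():
            test_probs += predict(head, t[test_mask]).probs
    for key in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
        report.fold_mean[key] = float(np.mean([f[key] for f in report.folds]))
    if test_mask.any():
        test_probs /= len(plan.folds)
        pred_labels = [classes[i] for i in test_probs.argmax(axis=1)]
        y_test = y[test_mask].tolist()
        report.test = compute_metrics(y_test, pred_labels, classes)
        try:
            roc = roc_auc(y_test, test_probs, classes)
            report.test["mean_auc"] = roc["mean_auc"]
            report.test["auc_per_class"] = {
                c: v["auc"] for c, v in roc["per_class"].items()
            }
        except UndefinedAUCError:
            report.test["mean_auc"] = None
    return report


def benchmark(
    stacks,
    labels,
    recording_ids,
    plan: FoldPlan,
    extractor_names=("inceptionv3", "densenet201", "resnet50", "resnet101",
                     "vgg16", "vgg19"),
    head_kinds=("cnn_one_layer", "svm"),
    task: str = "four_class_flat",
    config: TrainConfig | None = None,
    extractor_seed: int = 0,
) -> pd.DataFrame:
    """One row per (extractor, head) under the identical fold plan.

    Returns a tidy frame with test accuracy and macro precision/recall/F1,
    machine-readable for CSV export.
    """
    cfg = config or TrainConfig()
    rows = []
    for name in extractor_names:
        extractor = get_extractor(name, pretrained=False, seed=extractor_seed)
        feats = extract_features(extractor, stacks)
        for kind in head_kinds:
            rep = run_cv(feats, labels, recording_ids, plan, kind, task, cfg)
            src = rep.test if rep.test else rep.fold_mean
            rows.append(
                {
                    "extractor": name,
                    "head": kind,
                    "accuracy": src["accuracy"],
                    "precision": src["macro_precision"],
                    "recall": src["macro_recall"],
                    "f1": src["macro_f1"],
                    "plan_seed": plan.seed,
                }
            )
    return pd.DataFrame(rows)
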