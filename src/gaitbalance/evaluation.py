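"""Leave-one-subject-out evaluation, pooled metrics, ablation and sweeps.

Each fold holds out one subject for testing and one for validation-based
early stopping; the remaining subjects train the network.  Test predictions
from all folds are pooled into one complete set before metrics are computed
(rather than averaging per-fold metrics), so every sample is tested exactly
once and contributes equally.

Metrics follow the one-vs-rest convention: per-class TP/FP/TN/FN, with
precision and F1 computed per class and macro-averaged (unweighted
arithmetic mean across the three balance levels).  Accuracy is the pooled
fraction of correct predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifier import (
    ModelConfig, build_classifier, predict, train_classifier,
)
from .dataset import Dataset
from .preprocessing import preprocess_dataset
from .skeleton import JointGroup, joint_group

logger = logging.getLogger(__name__)

N_CLASSES = 3


@dataclass(frozen=True)
class FoldSpec:
    """One cross-validation fold: disjoint test/validation/train subjects."""

    fold_id: int
    test_subject: int
    val_subject: int
    train_subjects: tuple[int, ...]

    def __post_init__(self) -> None:
        roles = {self.test_subject, self.val_subject, *self.train_subjects}
        if len(roles) != 2 + len(self.train_subjects):
            raise ValueError("test/validation/train subjects must be disjoint")


@dataclass
class ConfusionCounts:
    """3x3 confusion matrix (rows = true, cols = predicted) and its
    one-vs-rest per-class counts."""

    matrix: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def total(self) -> int:
        return int(self.matrix.sum())


@dataclass
class Metrics:
    accuracy: float
    precision: np.ndarray       # per class
    recall: np.ndarray          # per class
    f1: np.ndarray              # per class
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: ConfusionCounts


@dataclass
class EvaluationReport:
    """Outcome of a full LOSO run."""

    folds: list[FoldSpec]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    metrics: Metrics
    per_fold_accuracy: list[float]
    config: ModelConfig
    group: str


@dataclass
class AblationReport:
    """Per-joint-group LOSO metrics with improvement over the A0 control."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows)


@dataclass
class SweepReport:
    """Per-hyperparameter-combination validation loss and accuracy."""

    parameter: str
    rows: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows)

    def best(self) -> dict:
        return min(self.rows, key=lambda r: r["val_loss"])


def make_loso_folds(dataset: Dataset, val_policy: str = "cyclic",
                    seed: int = 0) -> list[FoldSpec]:
    """One fold per subject; the validation subject is the cyclic successor
    of the test subject (or a random other subject with ``val_policy='random'``).
    """
    subjects = dataset.subjects
    if len(subjects) < 3:
        raise ValueError(
            f"LOSO needs >= 3 subjects (train/val/test all non-empty), "
            f"got {len(subjects)}"
        )
    rng = np.random.default_rng(seed)
    folds = []
    for i, test_subj in enumerate(subjects):
        if val_policy == "cyclic":
            val_subj = subjects[(i + 1) % len(subjects)]
        elif val_policy == "random":
            others = [s for s in subjects if s != test_subj]
            val_subj = int(rng.choice(others))
        else:
            raise ValueError(f"unknown val_policy {val_policy!r}")
        train = tuple(s for s in subjects if s not in (test_subj, val_subj))
        folds.append(FoldSpec(i, test_subj, val_subj, train))
    return folds


def compute_metrics(true_labels, predicted_labels, n_classes: int = N_CLASSES) -> Metrics:
    """Pooled multiclass metrics from label vectors.

    A class that is never predicted gets precision 0 (with a warning), and a
    class never present gets recall 0; F1 is 0 whenever its denominator is.
    """
    yt = np.asarray(true_labels, dtype=np.int64)
    yp = np.asarray(predicted_labels, dtype=np.int64)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if yt.size == 0:
        raise ValueError("label vectors must be non-empty")
    for arr, name in ((yt, "true"), (yp, "predicted")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} labels outside 0..{n_classes - 1}")

    matrix = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(matrix, (yt, yp), 1)
    total = matrix.sum()
    tp = np.diag(matrix).astype(np.int64)
    fp = matrix.sum(axis=0) - tp
    fn = matrix.sum(axis=1) - tp
    tn = total - tp - fp - fn
    confusion = ConfusionCounts(matrix=matrix, tp=tp, fp=fp, tn=tn, fn=fn)

    accuracy = float(tp.sum() / total)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        recall = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / np.maximum(denom, 1e-300), 0.0)
    never = [c for c in range(n_classes) if tp[c] + fp[c] == 0]
    if never:
        warnings.warn(
            f"classes never predicted: {never}; their precision is set to 0",
            stacklevel=2,
        )
    return Metrics(
        accuracy=accuracy,
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        confusion=confusion,
    )


def run_loso(
    dataset: Dataset,
    group: JointGroup | str = "A0",
    config: ModelConfig | None = None,
    val_policy: str = "cyclic",
) -> EvaluationReport:
    """Full leave-one-subject-out evaluation of the classifier.

    For each fold the dataset is preprocessed with ``group``, the network is
    trained on the training subjects with early stopping on the validation
    subject, and the held-out subject is predicted.  All test predictions
    are pooled before metrics are computed.
    """
    config = config or ModelConfig()
    if isinstance(group, str):
        group = joint_group(group)
    samples = preprocess_dataset(dataset, group)
    folds = make_loso_folds(dataset, val_policy=val_policy, seed=config.seed)

    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    per_fold_acc: list[float] = []
    for fold in folds:
        tr = [s for s in samples if s.subject_id in fold.train_subjects]
        va = [s for s in samples if s.subject_id == fold.val_subject]
        te = [s for s in samples if s.subject_id == fold.test_subject]
        model = build_classifier(config, len(group))
        model, hist = train_classifier(model, tr, va, config)
        _, pred = predict(model, te)
        yt = np.array([s.label for s in te])
        pooled_true.append(yt)
        pooled_pred.append(pred)
        acc = float((pred == yt).mean())
        per_fold_acc.append(acc)
        logger.info(
            "fold %d (test subject %d): acc=%.3f, epochs=%d",
            fold.fold_id, fold.test_subject, acc, hist.stopped_epoch + 1,
        )

    yt = np.concatenate(pooled_true)
    yp = np.concatenate(pooled_pred)
    return EvaluationReport(
        folds=folds,
        true_labels=yt,
        predicted_labels=yp,
        metrics=compute_metrics(yt, yp),
        per_fold_accuracy=per_fold_acc,
        config=config,
        group=group.name,
    )


def joint_ablation(
    dataset: Dataset,
    groups: list[str] | None = None,
    config: ModelConfig | None = None,
) -> AblationReport:
    """LOSO per joint group, reporting accuracy improvement over A0.

    ``groups`` must contain the control group A0; all groups run with
    identical seeds so differences are attributable to joint selection.
    """
    if groups is None:
        groups = ["A0", "T1", "T2", "H1", "H2", "H3", "H4",
                  "L1", "L2", "L3", "L4", "G1", "G2"]
    names = [g.upper() for g in groups]
    if "A0" not in names:
        raise ValueError("the control group A0 must be among the groups")
    config = config or ModelConfig()

    reports = {name: run_loso(dataset, name, config) for name in names}
    base_acc = reports["A0"].metrics.accuracy
    out = AblationReport()
    for name in names:
        rep = reports[name]
        g = joint_group(name)
        out.rows.append({
            "group": name,
            "description": g.description,
            "n_joints": len(g),
            "accuracy": rep.metrics.accuracy,
            "macro_precision": rep.metrics.macro_precision,
            "macro_f1": rep.metrics.macro_f1,
            "improvement": rep.metrics.accuracy - base_acc,
        })
    return out


def hyperparameter_sweep(
    dataset: Dataset,
    parameter: str,
    values: list,
    config: ModelConfig | None = None,
    group: str = "A0",
    full_loso: bool = False,
) -> SweepReport:
    """Sweep one hyperparameter axis, recording validation loss and accuracy.

    ``parameter`` is one of ``kernel_sizes``, ``channels``, ``n_blocks``,
    ``optimizer``.  By default each combination trains on a single fixed fold
    (fold 0) and reports that fold's best validation loss/accuracy, which
    keeps e.g. a 64-point kernel grid tractable; ``full_loso=True`` runs the
    complete protocol per combination instead.
    """
    if parameter not in ("kernel_sizes", "channels", "n_blocks", "optimizer"):
        raise ValueError(f"unknown sweep parameter {parameter!r}")
    if not values:
        raise ValueError("sweep grid must be non-empty")
    base = config or ModelConfig()
    gobj = joint_group(group)
    report = SweepReport(parameter=parameter)
    for value in values:
        cfg_kwargs = {**base.__dict__, parameter: value}
        cfg = ModelConfig(**cfg_kwargs)
        if full_loso:
            rep = run_loso(dataset, gobj, cfg)
            row = {
                parameter: value,
                "val_loss": float("nan"),
                "val_accuracy": rep.metrics.accuracy,
            }
        else:
            samples = preprocess_dataset(dataset, gobj)
            fold = make_loso_folds(dataset, seed=cfg.seed)[0]
            tr = [s for s in samples if s.subject_id in fold.train_subjects]
            va = [s for s in samples if s.subject_id == fold.val_subject]
            model = build_classifier(cfg, len(gobj))
            model, hist = train_classifier(model, tr, va, cfg)
            row = {
                parameter: value,
                "val_loss": hist.val_loss[hist.best_epoch],
                "val_accuracy": hist.val_accuracy[hist.best_epoch],
                "epochs": hist.stopped_epoch + 1,
            }
        report.rows.append(row)
        logger.info("sweep %s=%r: %s", parameter, value, row)
    return report


#: Grid axes matching the published parametric study.
DEFAULT_SWEEP_GRIDS = {
    "kernel_sizes": [(k1, k2, k3) for k1 in (1, 3, 5, 7)
                     for k2 in (1, 3, 5, 7) for k3 in (1, 3, 5, 7)],
    "channels": [4, 8, 16, 32, 64],
    "n_blocks": [1, 2, 3, 4],
    "optimizer": ["sgd", "rmsprop", "adam"],
}
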