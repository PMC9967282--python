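"""Metrics, balanced splitting, retrain-from-scratch subset evaluation and
the hyperparameter grid.

All classification metrics are macro-averaged: computed per class from the
confusion matrix and averaged with equal class weight.  Pseudo-overfitting
is the signed difference between train and validation precision; positive
values indicate the classifier performs worse on unseen data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix
from .network import BaseNetConfig, FPLNetwork, TrainConfig, train_epochs

__all__ = [
    "SplitSpec",
    "MetricsReport",
    "GridResult",
    "Standardizer",
    "macro_precision",
    "macro_recall",
    "macro_f1",
    "accuracy",
    "pseudo_overfitting",
    "balanced_split",
    "evaluate_subset",
    "enumerate_grid",
    "hyperparameter_grid",
    "DEFAULT_F_RANGE",
    "DEFAULT_PREC_RANGE",
]

#: Hyperparameter grid defaults: 4 pruning-fraction values x 8 precision
#: thresholds = 32 cells.
DEFAULT_F_RANGE: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
DEFAULT_PREC_RANGE: tuple[float, ...] = tuple(
    np.round(np.arange(0.60, 0.951, 0.05), 2))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray,
               classes: np.ndarray) -> np.ndarray:
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def _check_inputs(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    return y_true, y_pred, classes


def macro_precision(y_true, y_pred) -> float:
    """Per-class precision TP/(TP+FP), averaged with equal class weight.

    A class with no predicted positives contributes 0 (with a warning).
    """
    y_true, y_pred, classes = _check_inputs(y_true, y_pred)
    cm = _confusion(y_true, y_pred, classes)
    pred_pos = cm.sum(axis=0)
    if (pred_pos == 0).any():
        warnings.warn("class with zero predicted positives contributes 0 "
                      "to macro precision", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_pos > 0, np.diag(cm) / np.maximum(pred_pos, 1),
                        0.0)
    return float(prec.mean())


def macro_recall(y_true, y_pred) -> float:
    y_true, y_pred, classes = _check_inputs(y_true, y_pred)
    cm = _confusion(y_true, y_pred, classes)
    actual = cm.sum(axis=1)
    rec = np.where(actual > 0, np.diag(cm) / np.maximum(actual, 1), 0.0)
    return float(rec.mean())


def macro_f1(y_true, y_pred) -> float:
    y_true, y_pred, classes = _check_inputs(y_true, y_pred)
    cm = _confusion(y_true, y_pred, classes)
    pred_pos = cm.sum(axis=0)
    actual = cm.sum(axis=1)
    tp = np.diag(cm)
    prec = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1), 0.0)
    rec = np.where(actual > 0, tp / np.maximum(actual, 1), 0.0)
    denom = prec + rec
    f1 = np.where(denom > 0, 2 * prec * rec / np.maximum(denom, 1e-300), 0.0)
    return float(f1.mean())


def accuracy(y_true, y_pred) -> float:
    y_true, y_pred, _ = _check_inputs(y_true, y_pred)
    return float(np.mean(y_true == y_pred))


def pseudo_overfitting(train_prec: float, val_prec: float) -> float:
    """Signed train-minus-validation precision gap (may be negative)."""
    return float(train_prec) - float(val_prec)


@dataclass
class SplitSpec:
    """Class-balanced 70/30 train/test split with a validation carve-out.

    10% of the training pool is nominated as validation set.  The class-count
    difference within each split must stay within ``balance_tolerance``.
    """

    test_fraction: float = 0.30
    validation_fraction_of_train: float = 0.10
    balance_tolerance: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.test_fraction, self.validation_fraction_of_train):
            if not 0.0 < f < 1.0:
                raise ValueError("split fractions must be in (0, 1)")


def balanced_split(features: FeatureMatrix,
                   spec: SplitSpec) -> tuple[FeatureMatrix, FeatureMatrix,
                                             FeatureMatrix]:
    """Stratified (train, validation, test) split of a feature table."""
    labels = features.labels
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError(
            f"need both classes present; got counts "
            f"{dict(zip(*np.unique(labels, return_counts=True)))}")
    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx, test_idx = [], [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_test = int(round(len(idx) * spec.test_fraction))
        test_idx.append(idx[:n_test])
        pool = idx[n_test:]
        n_val = int(round(len(pool) * spec.validation_fraction_of_train))
        val_idx.append(pool[:n_val])
        train_idx.append(pool[n_val:])
    splits = tuple(np.sort(np.concatenate(part))
                   for part in (train_idx, val_idx, test_idx))
    for name, part in zip(("train", "validation", "test"), splits):
        counts = np.array([(labels[part] == c).sum() for c in classes])
        gap = int(counts.max() - counts.min())
        if gap > spec.balance_tolerance:
            raise ValueError(
                f"{name} split class gap {gap} exceeds tolerance "
                f"{spec.balance_tolerance} (counts {counts.tolist()})")
    return tuple(features.take_rows(part) for part in splits)


class Standardizer:
    """Column z-scoring fitted on the training split."""

    def fit(self, X: np.ndarray) -> "Standardizer":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    psovft: float
    std: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "precision": self.precision,
             "recall": self.recall, "f1": self.f1, "psovft": self.psovft}
        if self.std:
            d["std"] = dict(self.std)
        return d


def _train_base_and_report(train_fm: FeatureMatrix, val_fm: FeatureMatrix,
                           test_fm: FeatureMatrix, net_cfg: BaseNetConfig,
                           train_cfg: TrainConfig) -> MetricsReport:
    scaler = Standardizer().fit(train_fm.values)
    Xtr, Xva, Xte = (scaler.transform(f.values)
                     for f in (train_fm, val_fm, test_fm))
    model = FPLNetwork(train_fm.n_features, net_cfg, with_fpl=False,
                       seed=train_cfg.seed)
    trace = train_epochs(model, Xtr, train_fm.labels, Xva, val_fm.labels,
                         train_cfg)
    y_pred = model.predict(Xte)
    y_true = test_fm.labels
    return MetricsReport(
        accuracy=accuracy(y_true, y_pred),
        precision=macro_precision(y_true, y_pred),
        recall=macro_recall(y_true, y_pred),
        f1=macro_f1(y_true, y_pred),
        psovft=pseudo_overfitting(trace.train_precision[-1],
                                  trace.val_precision[-1]),
    )


def evaluate_subset(features: FeatureMatrix, selected: list[str],
                    repeats: int = 4,
                    net_config: BaseNetConfig | None = None,
                    train_config: TrainConfig | None = None,
                    split_spec: SplitSpec | None = None,
                    ) -> tuple[MetricsReport, list[MetricsReport]]:
    """Retrain the base network (no FPL) from scratch on a feature subset.

    Each repeat uses a fresh initialisation with a seed derived from the
    master seed (master + run index); the split itself is fixed.  Returns the
    averaged report (with per-metric standard deviations) plus per-run
    reports.
    """
    net_config = net_config if net_config is not None else BaseNetConfig()
    train_config = train_config if train_config is not None else TrainConfig()
    split_spec = split_spec if split_spec is not None else SplitSpec(
        seed=train_config.seed)
    subset = features.select(list(selected))
    train_fm, val_fm, test_fm = balanced_split(subset, split_spec)
    runs = []
    for r in range(repeats):
        cfg = TrainConfig(optimizer=train_config.optimizer,
                          learning_rate=train_config.learning_rate,
                          batch_size=train_config.batch_size,
                          seed=train_config.seed + r,
                          epochs=train_config.epochs)
        runs.append(_train_base_and_report(train_fm, val_fm, test_fm,
                                           net_config, cfg))
    keys = ("accuracy", "precision", "recall", "f1", "psovft")
    means = {k: float(np.mean([getattr(r, k) for r in runs])) for k in keys}
    stds = {k: float(np.std([getattr(r, k) for r in runs])) for k in keys}
    mean_report = MetricsReport(**means, std=stds)
    return mean_report, runs


def enumerate_grid(f_range: tuple[float, ...] = DEFAULT_F_RANGE,
                   prec_range: tuple[float, ...] = DEFAULT_PREC_RANGE,
                   ) -> list[tuple[float, float]]:
    """All (f, final_prec) hyperparameter cells; 4 x 8 = 32 by default."""
    return [(float(f), float(p)) for f in f_range for p in prec_range]


@dataclass
class GridResult:
    cells: list[dict]
    best: dict

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def hyperparameter_grid(features: FeatureMatrix, fraction: float,
                        f_range: tuple[float, ...] = DEFAULT_F_RANGE,
                        prec_range: tuple[float, ...] = DEFAULT_PREC_RANGE,
                        repeats: int = 4,
                        net_config: BaseNetConfig | None = None,
                        train_config: TrainConfig | None = None,
                        split_spec: SplitSpec | None = None,
                        selection_kwargs: dict | None = None) -> GridResult:
    """Run selection + subset evaluation for every hyperparameter cell.

    Cells are ranked by the averaged macro precision achieved by the base
    network retrained on the selected subset (``newset_prec``).
    """
    from .selection import (PruneCriteria, ScheduleParams, StopCriteria,
                            run_selection, target_count)

    if not f_range or not prec_range:
        raise ValueError("hyperparameter ranges must be non-empty")
    selection_kwargs = dict(selection_kwargs or {})
    stop_kwargs = selection_kwargs.pop("stop", {})
    train_config = train_config if train_config is not None else TrainConfig()
    des = target_count(fraction, features.n_features)
    cells = []
    for f, fp in enumerate_grid(f_range, prec_range):
        result = run_selection(
            features,
            sched=ScheduleParams(f=f),
            crit=PruneCriteria(final_prec=fp),
            stop=StopCriteria(des_feat_num=des, **stop_kwargs),
            train_config=train_config,
            net_config=net_config,
            split_spec=split_spec,
            **selection_kwargs,
        )
        report, _ = evaluate_subset(features, result.selected_names,
                                    repeats=repeats, net_config=net_config,
                                    train_config=train_config,
                                    split_spec=split_spec)
        cells.append({"f": f, "final_prec": fp,
                      "selected": result.selected_names,
                      "report": report})
    best = max(cells, key=lambda c: c["report"].precision)
    return GridResult(cells=cells, best=best)
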