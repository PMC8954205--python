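"""Classification metrics and resampling protocols.

AD is the positive class throughout.  Metrics are computed from the binary
confusion matrix: sensitivity (true positive rate), specificity (true
negative rate), accuracy, F1, and the Matthews correlation coefficient

.. math:: \\mathrm{MCC} = \\frac{tp\\,tn - fp\\,fn}
          {\\sqrt{(tp+fp)(tp+fn)(tn+fp)(tn+fn)}}.

Any 0/0 is defined as 0 (degenerate predictors only).  Two protocols are
provided: a stratified 70/30 train/test split and stratified k-fold
cross-validation (default k=3) with per-fold metrics aggregated as
mean +/- across-fold standard deviation (ddof=1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "ConfusionCounts", "MetricSet", "METRIC_NAMES",
    "confusion", "metrics", "split_train_test", "make_folds",
    "cross_validate", "aggregate_metrics",
]

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "f1", "mcc")

LABEL_CODES = {"control": 0, "ad": 1}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def _codes(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return np.array([LABEL_CODES[str(v)] for v in arr], dtype=np.int64)
    out = arr.astype(np.int64)
    if not set(np.unique(out)) <= {0, 1}:
        raise ValueError("labels must be binary (0=control, 1=ad)")
    return out


def confusion(pred_labels: Sequence, true_labels: Sequence) -> ConfusionCounts:
    """Binary confusion counts with AD (=1) as the positive class."""
    pred = _codes(pred_labels)
    true = _codes(true_labels)
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs "
                         f"{len(true)} truths")
    tp = int(np.sum((pred == 1) & (true == 1)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics(c: ConfusionCounts) -> MetricSet:
    """All five metrics from confusion counts; 0/0 is defined as 0."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    f1 = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    mcc = _ratio(c.tp * c.tn - c.fp * c.fn, float(np.sqrt(denom)))
    return MetricSet(sensitivity=sens, specificity=spec, accuracy=acc,
                     f1=f1, mcc=mcc)


def split_train_test(manifest: pd.DataFrame, frac_train: float = 0.7,
                     seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified subject-level train/test split on a cohort manifest."""
    if not 0 < frac_train < 1:
        raise ValueError("frac_train must lie in (0, 1)")
    counts = manifest["label"].value_counts()
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 subjects to split")
    train_ids, test_ids = train_test_split(
        manifest["id"].tolist(), train_size=frac_train,
        stratify=manifest["label"].tolist(),
        random_state=seed & 0x7FFFFFFF, shuffle=True)
    return list(train_ids), list(test_ids)


def make_folds(manifest: pd.DataFrame, k: int = 3, seed: int = 0,
               stratified: bool = True) -> dict[str, int]:
    """Assign each subject id to one of ``k`` folds (stratified by class)."""
    ids = manifest["id"].to_numpy()
    y = _codes(manifest["label"].tolist())
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed & 0x7FFFFFFF)
        splits = splitter.split(ids, y)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(ids))
        chunks = np.array_split(perm, k)
        splits = [(np.setdiff1d(perm, c), c) for c in chunks]
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splits):
        for i in test_idx:
            assignment[str(ids[i])] = fold
    return assignment


def aggregate_metrics(fold_metrics: Sequence[MetricSet]) -> dict[str, tuple[float, float]]:
    """Across-fold mean and sd (ddof=1) per metric."""
    out: dict[str, tuple[float, float]] = {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(fm, m) for fm in fold_metrics], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[m] = (float(vals.mean()), sd)
    return out


def cross_validate(manifest: pd.DataFrame,
                   fit_predict: Callable[[list[str], list[str], int],
                                         tuple[Sequence, Sequence]],
                   k: int = 3, seed: int = 0, stratified: bool = True,
                   ) -> tuple[list[MetricSet], dict[str, tuple[float, float]]]:
    """Stratified k-fold cross-validation over a cohort manifest.

    ``fit_predict(train_ids, test_ids, fold) -> (pred_labels, true_labels)``
    trains on the k-1 remaining folds and returns predictions for the
    held-out fold.  Returns per-fold metric sets and the mean/sd aggregate.
    Training failures propagate annotated with the fold index.
    """
    counts = manifest["label"].value_counts()
    if (counts < k).any():
        raise ValueError(f"need at least {k} subjects per class for {k}-fold CV")
    assignment = make_folds(manifest, k=k, seed=seed, stratified=stratified)
    ids = manifest["id"].tolist()
    fold_metrics: list[MetricSet] = []
    for fold in range(k):
        test_ids = [i for i in ids if assignment[i] == fold]
        train_ids = [i for i in ids if assignment[i] != fold]
        try:
            pred, true = fit_predict(train_ids, test_ids, fold)
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {fold}: {exc}") from exc
        fold_metrics.append(metrics(confusion(pred, true)))
    return fold_metrics, aggregate_metrics(fold_metrics)
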