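"""Evaluation protocol: confusion counts, TPR/PPV/F-measure, stratified
10-fold cross-validation with symmetric 95% t-intervals, and an adapter
hook so external classifiers can be run through the identical protocol.

Only the minority (positive) class is scored: TPR = TP/(TP+FN) is its
recall, PPV = TP/(TP+FP) its precision, and the F-measure their
beta-weighted harmonic mean (beta = 1 by default).  When no positive
prediction is made PPV (and hence F) is undefined; the undefined flag is
NaN, and fold means substitute 0 for it with a logged warning rather than
silently dropping the fold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .booster import RankCostModel, TrainConfig, fit
from .data import LabeledDataset

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "CVResult",
    "ClassifierAdapter",
    "RankCostAdapter",
    "confusion",
    "tpr",
    "ppv",
    "f_measure",
    "metrics_from_confusion",
    "cross_validate",
    "evaluate_adapter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts with +1 the positive (minority) class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricSet:
    """TPR, PPV and F-measure; NaN marks an undefined value."""

    tpr: float
    ppv: float
    f_measure: float
    beta: float = 1.0


@dataclass
class CVResult:
    """Per-fold metrics with means, F-of-means, and symmetric 95% CIs.

    ``mean_of_folds.f_measure`` averages the per-fold F values;
    ``f_of_means`` instead recomputes F from the mean TPR and mean PPV.
    Both aggregations are reported because they genuinely differ.
    """

    per_fold: list[MetricSet]
    mean_of_folds: MetricSet
    f_of_means: float
    ci95: dict[str, tuple[float, float]]
    k: int
    seed: int
    undefined_folds: int = 0


def _check_pm1(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    bad = set(np.unique(v)) - {-1, 1}
    if bad:
        raise ValueError(f"{name} must contain only +1/-1, found {sorted(bad)}")
    return v


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    """Tally the four confusion counts for ±1 label vectors."""
    y_true = _check_pm1(y_true, "y_true")
    y_pred = _check_pm1(y_pred, "y_pred")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
    )


def tpr(cm: ConfusionMatrix) -> float:
    """Recall of the positive class; NaN when there are no positives."""
    denom = cm.tp + cm.fn
    return cm.tp / denom if denom else float("nan")


def ppv(cm: ConfusionMatrix) -> float:
    """Precision of the positive class; NaN when nothing is predicted positive."""
    denom = cm.tp + cm.fp
    return cm.tp / denom if denom else float("nan")


def f_measure(tpr_value: float, ppv_value: float, beta: float = 1.0) -> float:
    """Beta-weighted harmonic mean of TPR and PPV (beta = 1: plain harmonic)."""
    if np.isnan(tpr_value) or np.isnan(ppv_value):
        return float("nan")
    denom = beta * beta * tpr_value + ppv_value
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * tpr_value * ppv_value / denom


def metrics_from_confusion(cm: ConfusionMatrix, beta: float = 1.0) -> MetricSet:
    t, p = tpr(cm), ppv(cm)
    return MetricSet(t, p, f_measure(t, p, beta), beta)


# ---------------------------------------------------------------------------
# cross-validation


class ClassifierAdapter(Protocol):
    """Train/predict contract any external classifier must honor."""

    def train(self, features: np.ndarray, labels: np.ndarray) -> None: ...

    def predict(self, features: np.ndarray) -> np.ndarray: ...


class RankCostAdapter:
    """Adapter exposing the boosting classifier through the generic contract."""

    def __init__(self, config: TrainConfig = TrainConfig()):
        self.config = config
        self.model: RankCostModel | None = None

    def train(self, features: np.ndarray, labels: np.ndarray) -> None:
        self.model = fit(LabeledDataset(features, labels), self.config)

    def predict(self, features: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("train must be called before predict")
        return self.model.predict(features)


def _mean_with_undefined(values: np.ndarray) -> tuple[float, int]:
    undefined = int(np.sum(np.isnan(values)))
    return float(np.nan_to_num(values, nan=0.0).mean()), undefined


def evaluate_adapter(
    classifier: ClassifierAdapter,
    data: LabeledDataset,
    k: int = 10,
    seed: int = 0,
    beta: float = 1.0,
) -> CVResult:
    """Stratified k-fold CV of any adapter honoring the train/predict contract.

    Folds preserve class proportions and are formed once from the seed, so
    every fold retains minority members and results are reproducible.  The
    95% interval per metric is mean ± t_{0.975,k-1}·sd/√k (symmetric, and
    allowed to leave [0, 1]).  Undefined fold metrics (no positive
    prediction) enter the means as 0 and are counted in undefined_folds.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    for name, count in (("positive", data.n_pos), ("negative", data.n_neg)):
        if count < k:
            raise ValueError(
                f"{name} class has only {count} members, fewer than k={k} folds"
            )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold: list[MetricSet] = []
    for fold, (train_idx, test_idx) in enumerate(
        splitter.split(data.features, data.labels)
    ):
        try:
            classifier.train(data.features[train_idx], data.labels[train_idx])
            y_pred = np.asarray(classifier.predict(data.features[test_idx]))
        except Exception as exc:
            raise RuntimeError(f"classifier adapter failed on fold {fold}: {exc}") from exc
        per_fold.append(metrics_from_confusion(confusion(data.labels[test_idx], y_pred), beta))

    arr = {
        "tpr": np.array([m.tpr for m in per_fold]),
        "ppv": np.array([m.ppv for m in per_fold]),
        "f_measure": np.array([m.f_measure for m in per_fold]),
    }
    means, undefined_total = {}, 0
    for name, values in arr.items():
        means[name], n_undef = _mean_with_undefined(values)
        undefined_total = max(undefined_total, n_undef)
        if n_undef:
            logger.warning(
                "%d of %d folds had undefined %s (no positive predictions); "
                "treated as 0 in the fold mean", n_undef, k, name,
            )
    tcrit = float(stats.t.ppf(0.975, df=k - 1))
    ci95 = {}
    for name, values in arr.items():
        filled = np.nan_to_num(values, nan=0.0)
        half = tcrit * filled.std(ddof=1) / np.sqrt(k)
        ci95[name] = (means[name] - half, means[name] + half)
    return CVResult(
        per_fold=per_fold,
        mean_of_folds=MetricSet(means["tpr"], means["ppv"], means["f_measure"], beta),
        f_of_means=f_measure(means["tpr"], means["ppv"], beta),
        ci95=ci95,
        k=k,
        seed=seed,
        undefined_folds=undefined_total,
    )


def cross_validate(
    data: LabeledDataset,
    config: TrainConfig = TrainConfig(),
    k: int = 10,
    seed: int = 0,
    beta: float = 1.0,
) -> CVResult:
    """Stratified k-fold CV of the boosting classifier itself."""
    return evaluate_adapter(RankCostAdapter(config), data, k=k, seed=seed, beta=beta)
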