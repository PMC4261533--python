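"""Functional gradient boosting of the ranking scorer F(x) = Σ_m ρ_m f_m(x).

Starting from F ≡ 0, each round fits a shallow regression tree to the
per-sample negative gradient of the squared-hinge ranking loss, chooses
its multiplier ρ by exact one-dimensional line search (the loss restricted
to the step size is convex piecewise quadratic, so bisection on its
derivative finds the global minimizer), and adds the scaled tree to the
ensemble.  The classification cut-off C is the midpoint of the two class
mean scores on the training data; a new sample is called minority when
F(x) >= C.

Fitted models are self-contained: trees are exported to plain arrays at
fit time, so scoring and the JSON model file need neither the training
data nor scikit-learn.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .data import FeatureMeta, LabeledDataset
from .ranking_loss import LossParams, PairSet, build_pairs, relaxed_loss, sample_gradients

__all__ = [
    "TrainConfig",
    "RegressionTree",
    "RankCostModel",
    "fit",
    "line_search_rho",
    "compute_threshold",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1
_LINE_SEARCH_TOL = 1e-8


@dataclass(frozen=True)
class TrainConfig:
    """Boosting hyper-parameters.

    max_iter caps the number of boosting rounds (training typically
    plateaus within about a hundred).  tau sets the ranking margin and
    thereby the score scale.  tree_max_depth / tree_min_leaf shape the
    regression-tree base learner.  shrinkage in (0, 1] damps each step;
    rel_tol stops early once the relative per-round loss decrease falls
    below it; rho_max brackets the line search.
    """

    max_iter: int = 100
    tau: float = 1.0
    tree_max_depth: int = 3
    tree_min_leaf: int = 5
    shrinkage: float = 1.0
    rel_tol: float = 1e-6
    rho_max: float = 1e3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.tree_max_depth < 1 or self.tree_min_leaf < 1:
            raise ValueError("tree parameters must be positive")
        if not 0 < self.shrinkage <= 1:
            raise ValueError("shrinkage must lie in (0, 1]")
        if self.rel_tol < 0:
            raise ValueError("rel_tol must be nonnegative")
        if not self.rho_max > 0:
            raise ValueError("rho_max must be positive")


@dataclass
class RegressionTree:
    """Flat-array export of a fitted regression tree.

    ``children_left``/``children_right`` hold child node ids (-1 for a
    leaf), ``feature`` the split column, ``threshold`` the split value
    (go left when x[feature] <= threshold), ``value`` the leaf prediction.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray

    @classmethod
    def from_sklearn(cls, tree: DecisionTreeRegressor) -> "RegressionTree":
        t = tree.tree_
        return cls(
            children_left=t.children_left.astype(np.int64).copy(),
            children_right=t.children_right.astype(np.int64).copy(),
            feature=t.feature.astype(np.int64).copy(),
            threshold=t.threshold.astype(np.float64).copy(),
            value=t.value.reshape(-1).astype(np.float64).copy(),
        )

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        node = np.zeros(features.shape[0], dtype=np.int64)
        while True:
            internal = self.children_left[node] >= 0
            if not internal.any():
                break
            idx = np.flatnonzero(internal)
            cur = node[idx]
            go_left = features[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.children_left[cur], self.children_right[cur])
        return self.value[node]

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=np.int64),
            children_right=np.asarray(d["children_right"], dtype=np.int64),
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=np.float64),
            value=np.asarray(d["value"], dtype=np.float64),
        )


@dataclass
class RankCostModel:
    """Fitted additive ranking scorer with its classification threshold."""

    base_learners: list[RegressionTree]
    multipliers: list[float]
    tau: float
    threshold: float
    shrinkage: float = 1.0
    loss_trace: list[float] = field(default_factory=list)
    indicator_trace: list[int] = field(default_factory=list)
    n_features: int = 0
    feature_meta: list[FeatureMeta] = field(default_factory=list)
    columns: list[str] = field(default_factory=list)
    config: TrainConfig | None = None

    def score(self, features: np.ndarray) -> np.ndarray:
        """F(x) = Σ_m ν·ρ_m·f_m(x) per row."""
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[1] != self.n_features:
            raise ValueError(
                f"feature matrix must have {self.n_features} columns, got shape {features.shape}"
            )
        out = np.zeros(features.shape[0])
        for tree, rho in zip(self.base_learners, self.multipliers):
            out += self.shrinkage * rho * tree.predict(features)
        return out

    def predict(self, features: np.ndarray) -> np.ndarray:
        """+1 (minority) when F(x) >= C, else -1; ties go to the minority."""
        return np.where(self.score(features) >= self.threshold, 1, -1).astype(np.int64)


def compute_threshold(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Cut-off C: midpoint of the two class mean scores."""
    scores_pos = np.asarray(scores_pos, dtype=np.float64)
    scores_neg = np.asarray(scores_neg, dtype=np.float64)
    if scores_pos.size == 0 or scores_neg.size == 0:
        raise ValueError("both classes need at least one score to place the cut-off")
    return float((scores_pos.mean() + scores_neg.mean()) / 2.0)


def line_search_rho(
    scores: np.ndarray,
    direction: np.ndarray,
    pairs: PairSet,
    params: LossParams,
    rho_max: float = 1e3,
) -> float:
    """Exact minimizer of g(ρ) = L̃(scores + ρ·direction) on [0, rho_max].

    g is convex piecewise quadratic, so its derivative is nondecreasing;
    bisection on g' locates the (smallest, when g has a flat stretch)
    minimizer to within 1e-8.  A direction that cannot reduce the loss
    (g'(0) >= 0) returns ρ = 0.
    """
    scores = np.asarray(scores, dtype=np.float64)
    direction = np.asarray(direction, dtype=np.float64)
    # per-pair margin at step rho is a + rho * b
    a = scores[pairs.neg_index] - scores[pairs.pos_index] + params.tau
    b = direction[pairs.neg_index] - direction[pairs.pos_index]

    def dg(rho: float) -> float:
        m = a + rho * b
        return float(np.sum(np.where(m > 0, m * b, 0.0)))

    lo, hi = 0.0, float(rho_max)
    if dg(lo) >= 0.0:
        return 0.0
    # when g is flat beyond the kink (all hinges released), g' is 0 there and
    # bisection converges to the smallest minimizer rather than the cap
    if dg(hi) < 0.0:
        return hi
    while hi - lo > _LINE_SEARCH_TOL:
        mid = 0.5 * (lo + hi)
        if dg(mid) < 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit(data: LabeledDataset, config: TrainConfig = TrainConfig()) -> RankCostModel:
    """Learn the additive scorer by gradient boosting and set the cut-off.

    Each round: aggregate the pairwise negative gradients per sample, fit
    a regression tree to them, pick the step ρ_m by exact line search, add
    ν·ρ_m·h_m to the running scores, and append the relaxed loss to the
    trace.  Stops at max_iter, when the relative loss decrease drops below
    rel_tol, or once the loss hits zero.  Deterministic given config.
    """
    if data.n_pos == 0 or data.n_neg == 0:
        raise ValueError("training data must contain both classes")
    X = data.features
    pairs = build_pairs(data.labels)
    params = LossParams(config.tau)

    scores = np.zeros(data.n)
    trees: list[RegressionTree] = []
    rhos: list[float] = []
    loss = relaxed_loss(scores, pairs, params)
    trace = [loss]
    from .ranking_loss import indicator_loss as _ind
    ind_trace = [_ind(scores, pairs)]

    for m in range(config.max_iter):
        grad = sample_gradients(scores, pairs, params)
        if not np.any(grad):
            break
        learner = DecisionTreeRegressor(
            max_depth=config.tree_max_depth,
            min_samples_leaf=config.tree_min_leaf,
            random_state=config.seed,
        )
        learner.fit(X, grad)
        tree = RegressionTree.from_sklearn(learner)
        h = tree.predict(X)
        rho = line_search_rho(scores, h, pairs, params, config.rho_max)
        if rho == 0.0:
            break
        scores = scores + config.shrinkage * rho * h
        new_loss = relaxed_loss(scores, pairs, params)
        trees.append(tree)
        rhos.append(rho)
        trace.append(new_loss)
        ind_trace.append(_ind(scores, pairs))
        if new_loss == 0.0:
            break
        if loss > 0 and (loss - new_loss) / loss < config.rel_tol:
            loss = new_loss
            break
        loss = new_loss

    threshold = compute_threshold(scores[data.labels == 1], scores[data.labels == -1])
    return RankCostModel(
        base_learners=trees,
        multipliers=rhos,
        tau=config.tau,
        threshold=threshold,
        shrinkage=config.shrinkage,
        loss_trace=trace,
        indicator_trace=ind_trace,
        n_features=X.shape[1],
        feature_meta=list(data.feature_meta),
        columns=list(data.columns),
        config=config,
    )


# ---------------------------------------------------------------------------
# serialization


def save_model(model: RankCostModel, path: str | Path) -> None:
    """Write the model as versioned JSON; round-trips bit-exactly."""
    payload = {
        "format": "rankcost-model",
        "version": MODEL_FORMAT_VERSION,
        "tau": model.tau,
        "threshold": model.threshold,
        "shrinkage": model.shrinkage,
        "n_features": model.n_features,
        "columns": model.columns,
        "multipliers": model.multipliers,
        "trees": [t.to_dict() for t in model.base_learners],
        "loss_trace": model.loss_trace,
        "indicator_trace": model.indicator_trace,
        "feature_meta": [
            {"name": fm.name, "kind": fm.kind, "levels": list(fm.levels),
             "fill_value": fm.fill_value}
            for fm in model.feature_meta
        ],
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_model(path: str | Path) -> RankCostModel:
    """Read a model file written by :func:`save_model`."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"malformed model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("format") != "rankcost-model":
        raise ValueError(f"{path} is not a rankcost model file")
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model version {payload.get('version')!r}; "
            f"this build reads version {MODEL_FORMAT_VERSION}"
        )
    try:
        return RankCostModel(
            base_learners=[RegressionTree.from_dict(d) for d in payload["trees"]],
            multipliers=[float(r) for r in payload["multipliers"]],
            tau=float(payload["tau"]),
            threshold=float(payload["threshold"]),
            shrinkage=float(payload["shrinkage"]),
            loss_trace=[float(v) for v in payload["loss_trace"]],
            indicator_trace=[int(v) for v in payload.get("indicator_trace", [])],
            n_features=int(payload["n_features"]),
            columns=list(payload.get("columns", [])),
            feature_meta=[
                FeatureMeta(d["name"], d["kind"], tuple(d["levels"]), d["fill_value"])
                for d in payload.get("feature_meta", [])
            ],
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed model file {path}: missing field {exc}") from exc
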