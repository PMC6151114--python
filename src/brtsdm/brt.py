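"""Boosted regression trees for presence/absence responses, from scratch.

The model is an additive ensemble on the logit scale:

    F(x) = intercept + sum_t  T_t(x)

where each T_t is a shallow regression tree fitted by stagewise gradient
boosting of the Bernoulli deviance. At each stage a bag of the training
rows (fraction ``bf``, drawn without replacement) is scored with the
current gradient residuals ``y − p``; a tree with at most ``tc`` splits is
grown greedily on squared-error reduction of those residuals; terminal
node values take a single guarded Newton step ``Σ(y−p) / Σ p(1−p)`` and
are shrunk by the learning rate ``lr`` before being added to the ensemble.

The number of trees ``nt`` is selected by the stagewise cross-validation
procedure: ``n_folds`` fold models (each trained on the other folds) grow
in parallel with the full model, and every ``ss`` trees the pooled
held-out deviance is evaluated; boosting stops once that profile has not
improved for a configured patience, and the full model is truncated to
the ``nt`` minimizing held-out deviance. Smaller learning rates shrink
each tree's contribution and therefore need more trees to reach the same
deviance — the profile makes that trade explicit.

Relative influence (per-variable share of total split-improvement) and
partial dependence (marginal logit-scale effect of one predictor,
averaging over the others) are the ensemble's standard interpretation
tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "BRTParams",
    "RegressionTree",
    "BRTModel",
    "bernoulli_deviance",
    "fit_regression_tree",
    "fit_brt",
    "predict_brt",
    "relative_influence",
    "partial_dependence",
]

PROB_EPS = 1e-12  # probability clipping for deviance
NEWTON_GUARD = 1e-8  # denominator floor in terminal Newton steps
LEAF_CAP = 4.0  # cap on raw (pre-shrinkage) terminal values


@dataclass(frozen=True)
class BRTParams:
    """Boosting hyper-parameters.

    bf: bag fraction, the share of training rows drawn (without
        replacement) to fit each tree, in (0, 1].
    lr: learning rate (shrinkage) applied to every tree, > 0.
    tc: tree complexity — the number of splits per tree (so a tree has at
        most tc + 1 terminal nodes), >= 1.
    ss: step size — trees added between successive evaluations of the
        cross-validated deviance profile, >= 1.
    max_trees: hard cap on the ensemble size.
    n_folds: folds for the stagewise CV selection of nt, >= 2.
    min_obs_per_node: smallest admissible terminal-node size.
    patience: CV evaluations without improvement before boosting stops.
    """

    bf: float = 0.5
    lr: float = 0.01
    tc: int = 2
    ss: int = 25
    max_trees: int = 1000
    n_folds: int = 10
    min_obs_per_node: int = 10
    patience: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.bf <= 1.0:
            raise ValueError("bag fraction must lie in (0, 1]")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.tc < 1:
            raise ValueError("tree complexity must be >= 1")
        if self.ss < 1:
            raise ValueError("step size must be >= 1")
        if self.max_trees < 0:
            raise ValueError("max_trees must be >= 0")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.min_obs_per_node < 1:
            raise ValueError("min_obs_per_node must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


# -- trees -----------------------------------------------------------------


@dataclass
class _Node:
    # internal: feature/threshold set; leaf: value set
    feature: int | None = None
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0
    improvement: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class RegressionTree:
    """A shallow regression tree; terminal values are logit increments."""

    root: _Node
    n_splits: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        stack = [(self.root, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if node.is_leaf:
                out[idx] = node.value
                continue
            go_left = X[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return out

    def iter_splits(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                yield node
                stack.append(node.left)
                stack.append(node.right)

    def to_dict(self) -> dict:
        def rec(node: _Node) -> dict:
            if node.is_leaf:
                return {"value": node.value}
            return {
                "feature": node.feature,
                "threshold": node.threshold,
                "improvement": node.improvement,
                "left": rec(node.left),
                "right": rec(node.right),
            }

        return {"n_splits": self.n_splits, "root": rec(self.root)}

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        def rec(nd: dict) -> _Node:
            if "value" in nd:
                return _Node(value=nd["value"])
            return _Node(
                feature=nd["feature"],
                threshold=nd["threshold"],
                improvement=nd.get("improvement", 0.0),
                left=rec(nd["left"]),
                right=rec(nd["right"]),
            )

        return cls(root=rec(d["root"]), n_splits=d["n_splits"])


def bernoulli_deviance(labels: np.ndarray, probs: np.ndarray) -> float:
    """Mean Bernoulli deviance (−2/n) Σ [y ln p + (1−y) ln(1−p)]."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probs must have equal length")
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _newton_value(num: float, den: float) -> float:
    v = num / max(den, NEWTON_GUARD)
    return float(np.clip(v, -LEAF_CAP, LEAF_CAP))


def _best_split(X, z, idx, min_obs):
    """Best (feature, threshold, gain) on rows idx by SSE reduction of z."""
    n = len(idx)
    if n < 2 * min_obs:
        return None
    zi = z[idx]
    total = zi.sum()
    base = total * total / n
    best = None  # (gain, feature, threshold)
    for j in range(X.shape[1]):
        xj = X[idx, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        zs = zi[order]
        csum = np.cumsum(zs)
        nl = np.arange(1, n)  # size of left side at cut positions
        valid = (xs[1:] != xs[:-1]) & (nl >= min_obs) & (n - nl >= min_obs)
        if not valid.any():
            continue
        sl = csum[:-1]
        gain = sl * sl / nl + (total - sl) ** 2 / (n - nl) - base
        gain = np.where(valid, gain, -np.inf)
        k = int(np.argmax(gain))
        if gain[k] > 0 and (best is None or gain[k] > best[0]):
            best = (float(gain[k]), j, float((xs[k] + xs[k + 1]) / 2.0))
    return best


def fit_regression_tree(
    X: np.ndarray,
    residuals: np.ndarray,
    grad_num: np.ndarray,
    grad_den: np.ndarray,
    tc: int,
    min_obs_per_node: int = 10,
) -> RegressionTree:
    """Grow one tree on gradient residuals, best-first, at most tc splits.

    Splits maximize squared-error reduction of the working response
    (``residuals``); terminal values take the single Newton step
    ``Σ grad_num / Σ grad_den`` over the node's rows (denominator
    guarded, value capped at ±4). If no admissible split exists the tree
    is a single leaf.
    """
    X = np.asarray(X, dtype=float)
    z = np.asarray(residuals, dtype=float)
    n = X.shape[0]
    root = _Node()
    leaves = {id(root): (root, np.arange(n))}
    candidates = {id(root): _best_split(X, z, np.arange(n), min_obs_per_node)}
    n_splits = 0
    while n_splits < tc:
        live = [k for k, c in candidates.items() if c is not None]
        if not live:
            break
        k = max(live, key=lambda kk: candidates[kk][0])
        gain, j, thr = candidates.pop(k)
        node, idx = leaves.pop(k)
        node.feature, node.threshold, node.improvement = j, thr, gain
        go_left = X[idx, j] <= thr
        node.left, node.right = _Node(), _Node()
        for child, cidx in ((node.left, idx[go_left]), (node.right, idx[~go_left])):
            leaves[id(child)] = (child, cidx)
            candidates[id(child)] = _best_split(X, z, cidx, min_obs_per_node)
        n_splits += 1
    for node, idx in leaves.values():
        node.value = _newton_value(grad_num[idx].sum(), grad_den[idx].sum())
    return RegressionTree(root=root, n_splits=n_splits)


# -- the boosted ensemble --------------------------------------------------


@dataclass
class BRTModel:
    intercept: float
    trees: list[RegressionTree]
    nt: int
    params: BRTParams
    variables: list[str]
    cv_deviance_profile: list[tuple[int, float]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    cv_predictions: np.ndarray | None = None  # held-out probs at the selected nt
    cv_labels: np.ndarray | None = None

    def predict(self, features, scale: str = "probability") -> np.ndarray:
        return predict_brt(self, features, scale)

    # serialization: JSON round-trips are prediction-exact because Python's
    # float repr round-trips through json
    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "nt": self.nt,
            "params": asdict(self.params),
            "variables": self.variables,
            "trees": [t.to_dict() for t in self.trees],
            "cv_deviance_profile": [[int(a), float(b)] for a, b in
                                    self.cv_deviance_profile],
            "metadata": self.metadata,
        }

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "BRTModel":
        return cls(
            intercept=d["intercept"],
            trees=[RegressionTree.from_dict(t) for t in d["trees"]],
            nt=d["nt"],
            params=BRTParams(**d["params"]),
            variables=list(d["variables"]),
            cv_deviance_profile=[(int(a), float(b)) for a, b in
                                 d.get("cv_deviance_profile", [])],
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, s: str) -> "BRTModel":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_json_file(cls, path: str) -> "BRTModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _feature_matrix(features, variables: list[str]) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [v for v in variables if v not in features.columns]
        if missing:
            raise KeyError(f"features missing model variables: {missing}")
        return features.loc[:, variables].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.shape[1] != len(variables):
        raise ValueError("feature matrix width does not match model variables")
    return X


def _stratified_folds(y: np.ndarray, k: int, rng) -> np.ndarray:
    """Fold labels 0..k-1; per class, sizes differ by at most one."""
    fold = np.empty(len(y), dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < k:
            raise ValueError(f"class {c} has fewer records ({len(idx)}) than folds ({k})")
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


class _BoostState:
    """One growing ensemble (the full model or one CV fold model)."""

    def __init__(self, X, y, train_idx, intercept):
        self.X, self.y = X, y
        self.train_idx = train_idx
        self.F = np.full(X.shape[0], intercept)
        self.trees: list[RegressionTree] = []

    def add_tree(self, params: BRTParams, rng) -> None:
        idx = self.train_idx
        n_bag = max(2 * params.min_obs_per_node,
                    int(round(params.bf * len(idx))))
        n_bag = min(n_bag, len(idx))
        bag = rng.choice(idx, size=n_bag, replace=False) if n_bag < len(idx) else idx
        p = _logistic(self.F[bag])
        resid = self.y[bag] - p
        tree = fit_regression_tree(
            self.X[bag], resid, resid, p * (1.0 - p),
            params.tc, params.min_obs_per_node,
        )
        # fold shrinkage into the stored terminal values
        stack = [tree.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                node.value *= params.lr
            else:
                stack.append(node.left)
                stack.append(node.right)
        self.F += tree.predict(self.X)
        self.trees.append(tree)


def fit_brt(train, params: BRTParams, label_col: str = "label") -> BRTModel:
    """Fit a boosted-regression-tree ensemble with stagewise CV tree selection.

    ``train`` is a feature table (DataFrame with predictor columns and a
    binary label column; a ``record_id`` column is ignored). The returned
    model is truncated to the tree count minimizing the cross-validated
    deviance profile; its ``cv_predictions`` hold the pooled held-out
    probabilities at that tree count (each training row is held out in
    exactly one fold), from which cross-validated AUC and deviance are
    computed downstream.
    """
    if not isinstance(train, pd.DataFrame):
        raise TypeError("train must be a DataFrame feature table")
    variables = [c for c in train.columns if c not in (label_col, "record_id")]
    if not variables:
        raise ValueError("no predictor columns")
    X = train.loc[:, variables].to_numpy(dtype=float)
    y = train[label_col].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("response is single-class; cannot fit")
    prevalence = y.mean()
    intercept = float(np.log(prevalence / (1.0 - prevalence)))

    if params.max_trees == 0:
        return BRTModel(intercept=intercept, trees=[], nt=0, params=params,
                        variables=variables,
                        metadata={"n_train": len(y), "prevalence": float(prevalence)})

    rng = np.random.default_rng(params.seed)
    fold_of = _stratified_folds(y, params.n_folds, rng)
    all_idx = np.arange(len(y))
    full = _BoostState(X, y, all_idx, intercept)
    folds = [
        _BoostState(X, y, all_idx[fold_of != f], intercept)
        for f in range(params.n_folds)
    ]
    hold_idx = [all_idx[fold_of == f] for f in range(params.n_folds)]

    profile: list[tuple[int, float]] = []
    snapshots: dict[int, np.ndarray] = {}
    best_dev = np.inf
    stale = 0
    capped_improving = False
    nt_grown = 0
    while nt_grown < params.max_trees:
        block = min(params.ss, params.max_trees - nt_grown)
        for _ in range(block):
            full.add_tree(params, rng)
            for st in folds:
                st.add_tree(params, rng)
            nt_grown += 1
        heldout = np.empty(len(y))
        for st, hidx in zip(folds, hold_idx):
            heldout[hidx] = _logistic(st.F[hidx])
        dev = bernoulli_deviance(y, heldout)
        profile.append((nt_grown, dev))
        snapshots[nt_grown] = heldout
        if dev < best_dev:
            best_dev = dev
            stale = 0
            if nt_grown >= params.max_trees:
                capped_improving = True
        else:
            stale += 1
            if stale >= params.patience:
                break

    # argmin over evaluated points; ties go to the smaller nt
    nt = min(profile, key=lambda t: (t[1], t[0]))[0]
    model = BRTModel(
        intercept=intercept,
        trees=full.trees[:nt],
        nt=nt,
        params=params,
        variables=variables,
        cv_deviance_profile=profile,
        metadata={
            "n_train": len(y),
            "prevalence": float(prevalence),
            "nt_grown": nt_grown,
            "cv_deviance_at_nt": float(dict(profile)[nt]),
            "nt_at_cap_still_improving": bool(capped_improving),
        },
        cv_predictions=snapshots[nt],
        cv_labels=y.copy(),
    )
    return model


def predict_brt(model: BRTModel, features, scale: str = "probability") -> np.ndarray:
    """Ensemble prediction: intercept plus the summed tree outputs."""
    if scale not in ("logit", "probability"):
        raise ValueError("scale must be 'logit' or 'probability'")
    X = _feature_matrix(features, model.variables)
    F = np.full(X.shape[0], model.intercept)
    for tree in model.trees:
        F += tree.predict(X)
    return F if scale == "logit" else _logistic(F)


def relative_influence(model: BRTModel) -> pd.Series:
    """Per-variable share of total split improvement, in percent.

    Sums each split's squared-error improvement by split variable over
    all trees of the fitted ensemble and normalizes to 100.
    """
    if model.nt < 1:
        raise ValueError("model has no trees")
    raw = np.zeros(len(model.variables))
    for tree in model.trees:
        for node in tree.iter_splits():
            raw[node.feature] += node.improvement
    total = raw.sum()
    if total <= 0:
        raise ValueError("ensemble contains no splits; influence undefined")
    return pd.Series(100.0 * raw / total, index=model.variables,
                     name="relative_influence").sort_values(ascending=False)


def partial_dependence(
    model: BRTModel, variable: str, grid: np.ndarray, background
) -> pd.DataFrame:
    """Marginal logit-scale effect of one predictor.

    For each grid value v, the variable's column in the background table
    is overwritten with v and the model logit is averaged over rows.
    """
    if variable not in model.variables:
        raise KeyError(f"{variable!r} is not a model variable")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    X = _feature_matrix(background, model.variables)
    j = model.variables.index(variable)
    means = np.empty(grid.size)
    for i, v in enumerate(grid):
        Xi = X.copy()
        Xi[:, j] = v
        means[i] = predict_brt(model, Xi, scale="logit").mean()
    return pd.DataFrame({"value": grid, "mean_logit": means})
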