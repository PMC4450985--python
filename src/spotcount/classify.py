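"""Bagged decision-tree ensemble with leaf-proportion probabilities.

Each tree is grown on a bootstrap resample of the curated training set,
trying a random subset of features at every split. A candidate's
preliminary probability of being a real emitter is the fraction of signal
examples in the leaf it reaches, averaged without weighting across all
trees — leaf-proportion averaging rather than majority vote, because the
averaged proportions are what gets calibrated downstream.

Trees are built with scikit-learn; after training every tree is exported to
plain arrays (children, split feature, threshold, per-node signal
proportion) so that prediction, serialization and reload depend only on
this module. Models round-trip through versioned JSON, never pickles.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES, SCHEMA_VERSION
from .stacks import ValidationError

__all__ = [
    "TreeArrays",
    "ForestModel",
    "train_forest",
    "preliminary_probability",
    "oob_probabilities",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class TreeArrays:
    """One decision tree flattened to parallel node arrays.

    ``children_left[i] == -1`` marks a leaf. ``signal_prop`` is the fraction
    of bootstrap training examples in the node labeled signal; ``n_node`` the
    number of bootstrap examples that reached it (>= 1 at every leaf).
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    signal_prop: np.ndarray
    n_node: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Route each row of X to its leaf index (vectorized tree walk)."""
        node = np.zeros(len(X), dtype=np.intp)
        active = self.children_left[node] != -1
        while np.any(active):
            idx = np.nonzero(active)[0]
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(
                go_left, self.children_left[nd], self.children_right[nd]
            )
            active = self.children_left[node] != -1
        return node

    def leaf_proportions(self, X: np.ndarray) -> np.ndarray:
        return self.signal_prop[self.apply(X)]


@dataclass
class ForestModel:
    """Trained ensemble plus the bookkeeping needed for OOB probabilities."""

    trees: list[TreeArrays]
    n_features: int
    feature_names: list[str]
    schema_version: int
    seed: int
    mtry: int
    min_leaf: int
    in_bag: np.ndarray | None = None  # (n_trees, n_train) bootstrap multiplicities
    n_train: int = 0
    class_counts: tuple[int, int] = (0, 0)  # (noise, signal) in training data
    extra: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _extract_tree(clf: DecisionTreeClassifier) -> TreeArrays:
    t = clf.tree_
    value = np.asarray(t.value)  # (n_nodes, 1, n_classes)
    counts = value[:, 0, :]
    totals = counts.sum(axis=1)
    # sklearn >= 1.3 stores per-node class fractions; older versions counts.
    # Either way normalizing gives the signal proportion.
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / totals[:, None]
    classes = list(clf.classes_)
    if 1 in classes:
        sig_col = classes.index(1)
        signal_prop = frac[:, sig_col]
    else:  # single-class tree cannot occur (guarded at training), but be safe
        signal_prop = np.zeros(len(totals))
    n_node = np.asarray(t.weighted_n_node_samples, dtype=np.float64)
    return TreeArrays(
        children_left=t.children_left.copy(),
        children_right=t.children_right.copy(),
        feature=t.feature.copy(),
        threshold=t.threshold.copy(),
        signal_prop=np.nan_to_num(signal_prop),
        n_node=n_node,
    )


def _training_matrix(training: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_NAMES + ["label"] if c not in training.columns]
    if missing:
        raise ValidationError(f"training table missing columns {missing}")
    X = training[FEATURE_NAMES].to_numpy(dtype=np.float64)
    y = training["label"].to_numpy(dtype=np.intp)
    if not np.all(np.isfinite(X)):
        raise ValidationError("training features contain non-finite values")
    return X, y


def train_forest(
    training: pd.DataFrame,
    n_trees: int = 500,
    mtry: int | None = None,
    min_leaf: int = 5,
    seed: int = 0,
) -> ForestModel:
    """Grow ``n_trees`` trees, each on its own bootstrap resample.

    ``mtry`` features are tried at every split (default ceil(sqrt(p)));
    splits minimize Gini impurity and growth stops at ``min_leaf`` examples
    per leaf or purity. min_leaf > 1 keeps leaf proportions informative as
    probability estimates instead of collapsing them to 0/1.
    """
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    X, y = _training_matrix(training)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("training set must contain both signal and noise examples")
    n = len(y)
    p = X.shape[1]
    if mtry is None:
        mtry = math.ceil(math.sqrt(p))
    if not (1 <= mtry <= p):
        raise ValidationError(f"mtry must be in [1, {p}]")

    ss = np.random.SeedSequence([int(seed), 0xF0E5])
    child_seeds = ss.spawn(n_trees)
    trees: list[TreeArrays] = []
    in_bag = np.zeros((n_trees, n), dtype=np.int32)
    for t, cs in enumerate(child_seeds):
        rng = np.random.default_rng(cs)
        idx = rng.integers(0, n, size=n)
        np.add.at(in_bag[t], idx, 1)
        clf = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=min_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[idx], y[idx])
        trees.append(_extract_tree(clf))

    count_map = dict(zip(classes.tolist(), counts.tolist()))
    return ForestModel(
        trees=trees,
        n_features=p,
        feature_names=list(FEATURE_NAMES),
        schema_version=SCHEMA_VERSION,
        seed=int(seed),
        mtry=int(mtry),
        min_leaf=int(min_leaf),
        in_bag=in_bag,
        n_train=n,
        class_counts=(int(count_map.get(0, 0)), int(count_map.get(1, 0))),
    )


def _check_schema(model: ForestModel, X: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValidationError(
            f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"model expects {model.n_features}"
        )
    if model.schema_version != SCHEMA_VERSION:
        raise ValidationError(
            f"model schema v{model.schema_version} != extractor schema v{SCHEMA_VERSION}"
        )


def preliminary_probability(model: ForestModel, fv: np.ndarray) -> np.ndarray:
    """Unweighted mean across trees of the reached leaf's signal proportion.

    Accepts one vector or an (n, p) matrix; returns a scalar array of
    probabilities in [0, 1].
    """
    X = np.atleast_2d(np.asarray(fv, dtype=np.float64))
    _check_schema(model, X)
    acc = np.zeros(len(X))
    for tree in model.trees:
        acc += tree.leaf_proportions(X)
    return acc / model.n_trees


def oob_probabilities(
    model: ForestModel, training: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Out-of-bag preliminary probabilities for the training examples.

    Each example is scored only by trees whose bootstrap excluded it, which
    is what makes these probabilities usable as an unbiased calibration
    corpus. Returns ``(p_oob, labels, kept_mask)``; examples that landed in
    every bootstrap get no OOB value and are dropped with a warning (an
    error if more than 20% drop, which only happens with far too few trees).
    """
    if model.in_bag is None:
        raise ValidationError("model was trained without bootstrap bookkeeping")
    X, y = _training_matrix(training)
    if len(y) != model.n_train:
        raise ValidationError(
            f"training table has {len(y)} rows, model was trained on {model.n_train}"
        )
    _check_schema(model, X)
    votes = np.zeros(len(y))
    n_votes = np.zeros(len(y))
    for t, tree in enumerate(model.trees):
        oob = model.in_bag[t] == 0
        if not np.any(oob):
            continue
        votes[oob] += tree.leaf_proportions(X[oob])
        n_votes[oob] += 1
    kept = n_votes > 0
    dropped = int((~kept).sum())
    if dropped:
        frac = dropped / len(y)
        msg = f"{dropped}/{len(y)} training examples were in every bootstrap"
        if frac > 0.2:
            msg += " (>20%: too few trees for a trustworthy calibration corpus)"
        warnings.warn(msg, stacklevel=2)
    p = votes[kept] / n_votes[kept]
    return p, y[kept], kept


def save_model(model: ForestModel, path) -> None:
    """Serialize a forest to versioned JSON (portable, diffable)."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "schema_version": model.schema_version,
        "feature_names": model.feature_names,
        "n_features": model.n_features,
        "seed": model.seed,
        "mtry": model.mtry,
        "min_leaf": model.min_leaf,
        "n_train": model.n_train,
        "class_counts": list(model.class_counts),
        "in_bag": model.in_bag.tolist() if model.in_bag is not None else None,
        "trees": [
            {
                "children_left": t.children_left.tolist(),
                "children_right": t.children_right.tolist(),
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "signal_prop": t.signal_prop.tolist(),
                "n_node": t.n_node.tolist(),
            }
            for t in model.trees
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ForestModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model format version {doc.get('format_version')}"
        )
    trees = [
        TreeArrays(
            children_left=np.asarray(t["children_left"], dtype=np.intp),
            children_right=np.asarray(t["children_right"], dtype=np.intp),
            feature=np.asarray(t["feature"], dtype=np.intp),
            threshold=np.asarray(t["threshold"], dtype=np.float64),
            signal_prop=np.asarray(t["signal_prop"], dtype=np.float64),
            n_node=np.asarray(t["n_node"], dtype=np.float64),
        )
        for t in doc["trees"]
    ]
    in_bag = doc.get("in_bag")
    return ForestModel(
        trees=trees,
        n_features=int(doc["n_features"]),
        feature_names=list(doc["feature_names"]),
        schema_version=int(doc["schema_version"]),
        seed=int(doc["seed"]),
        mtry=int(doc["mtry"]),
        min_leaf=int(doc["min_leaf"]),
        in_bag=np.asarray(in_bag, dtype=np.int32) if in_bag is not None else None,
        n_train=int(doc.get("n_train", 0)),
        class_counts=tuple(doc.get("class_counts", (0, 0))),
    )
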