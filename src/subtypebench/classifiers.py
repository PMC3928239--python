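"""The six response classifiers as interchangeable fit/score components.

Every classifier exposes a continuous pCR-propensity score (higher = more
pCR-like) so its ROC/AUC is well defined:

* ``NB``   -- naive Bayes on mixed features (Gaussian likelihood for
              continuous, Laplace-smoothed categorical otherwise); score =
              posterior P(pCR | x).
* ``NM``   -- nearest mean in Euclidean space; score = d(x, mean_noPCR) -
              d(x, mean_pCR).
* ``3NN``  -- 3-nearest-neighbour; score = fraction of pCR among the 3
              nearest Euclidean neighbours.
* ``LREG`` -- logistic regression; score = fitted probability.
* ``SVM``  -- linear-kernel SVM (C = 1) on standardized features; score =
              signed decision value.
* ``TREE`` -- CART decision tree with entropy impurity and minimum leaf size
              2 (embedded feature selection: it receives all features); score
              = Laplace-smoothed leaf pCR proportion.

Fits are deterministic: no randomized initialization survives (the tree's
tie-breaking is seeded to a constant).
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

CLASSIFIER_NAMES = ("NB", "NM", "3NN", "LREG", "SVM", "TREE")

_FORMAT_VERSION = 1


class _MixedNB:
    """Naive Bayes over mixed continuous/categorical features.

    Continuous features get per-class Gaussian likelihoods (variance floored
    at 1e-9 times the largest feature variance, as is conventional, to keep
    degenerate features finite).  Categorical features get Laplace-smoothed
    (alpha = 1) level frequencies; a level unseen at fit time contributes the
    smoothed minimum likelihood alpha / (n_k + alpha * (L + 1)).
    """

    alpha = 1.0

    def fit(self, X: np.ndarray, y: np.ndarray, categorical: np.ndarray) -> "_MixedNB":
        self.categorical_ = categorical
        self.classes_ = np.array([0, 1])
        n = len(y)
        self.log_prior_ = np.log(np.array([(y == c).sum() / n for c in (0, 1)]))
        var_floor = 1e-9 * max(X.var(axis=0).max(), 1e-12)
        self.gauss_ = {}   # (class, j) -> (mean, var)
        self.catlik_ = {}  # (class, j) -> {level: log prob}, plus "__unseen__"
        for c in (0, 1):
            Xc = X[y == c]
            for j in range(X.shape[1]):
                v = Xc[:, j]
                if categorical[j]:
                    levels, counts = np.unique(v, return_counts=True)
                    L = len(np.unique(X[:, j]))
                    denom = len(v) + self.alpha * (L + 1)
                    lik = {
                        float(lv): np.log((ct + self.alpha) / denom)
                        for lv, ct in zip(levels, counts)
                    }
                    lik["__unseen__"] = np.log(self.alpha / denom)
                    self.catlik_[(c, j)] = lik
                else:
                    self.gauss_[(c, j)] = (v.mean(), max(v.var(), var_floor))
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        logp = np.tile(self.log_prior_, (n, 1))
        for c in (0, 1):
            for j in range(X.shape[1]):
                if self.categorical_[j]:
                    lik = self.catlik_[(c, j)]
                    logp[:, c] += np.array(
                        [lik.get(float(v), lik["__unseen__"]) for v in X[:, j]]
                    )
                else:
                    mu, var = self.gauss_[(c, j)]
                    logp[:, c] += -0.5 * (np.log(2 * np.pi * var) + (X[:, j] - mu) ** 2 / var)
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        return p


class _NearestMean:
    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NearestMean":
        self.mean_pos_ = X[y == 1].mean(axis=0)
        self.mean_neg_ = X[y == 0].mean(axis=0)
        return self

    def decision(self, X: np.ndarray) -> np.ndarray:
        d_pos = np.linalg.norm(X - self.mean_pos_, axis=1)
        d_neg = np.linalg.norm(X - self.mean_neg_, axis=1)
        return d_neg - d_pos


@dataclass
class TrainedPredictor:
    """A fitted classifier bound to the features and encoding it was fit with."""

    name: str
    feature_ids: list
    kinds: dict
    state: object
    format_version: int = _FORMAT_VERSION

    def score(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_ids if f not in X.columns]
        if missing:
            raise KeyError(f"features missing at score time: {missing}")
        sub = X[self.feature_ids]
        if sub.isna().to_numpy().any():
            bad = sub.index[sub.isna().any(axis=1)].tolist()
            raise ValueError(f"missing feature values at score time: samples {bad}")
        M = sub.to_numpy(dtype=float)
        name, model = self.name, self.state
        if name == "NB":
            return model.predict_proba(M)[:, 1]
        if name == "NM":
            return model.decision(M)
        if name == "3NN":
            proba = model.predict_proba(M)
            return proba[:, list(model.classes_).index(1)]
        if name == "LREG":
            proba = model.predict_proba(M)
            return proba[:, list(model.classes_).index(1)]
        if name == "SVM":
            d = model.decision_function(M)
            return d if list(model.classes_)[1] == 1 else -d
        if name == "TREE":
            leaves = model.apply(M)
            tree = model.tree_
            value = tree.value[leaves, 0, :]  # class fractions since sklearn 1.4
            counts = value * tree.weighted_n_node_samples[leaves, None]
            idx = list(model.classes_).index(1)
            return (counts[:, idx] + 1.0) / (counts.sum(axis=1) + 2.0)
        raise ValueError(f"unknown classifier {name!r}")

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)


def load_predictor(path) -> TrainedPredictor:
    with open(path, "rb") as fh:
        obj = pickle.load(fh)
    if not isinstance(obj, TrainedPredictor):
        raise TypeError("file does not contain a TrainedPredictor")
    if obj.format_version != _FORMAT_VERSION:
        raise ValueError(f"unsupported predictor format {obj.format_version}")
    return obj


def fit(
    name: str,
    X_train: pd.DataFrame,
    y_train,
    kinds: Optional[Mapping[str, str]] = None,
) -> TrainedPredictor:
    """Fit one of the six classifiers on an already-feature-selected matrix.

    ``kinds`` maps feature id -> {continuous, binary, ordinal, categorical};
    unlisted features count as continuous.  Binary features are expected as
    0/1 columns and ordinal ones as integers (the clinical encoding); only
    naive Bayes distinguishes categorical likelihoods, the geometric models
    consume the numeric encoding directly.
    """
    if name not in CLASSIFIER_NAMES:
        raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")
    y = np.asarray(y_train).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class; re-stratify the split")
    if X_train.shape[1] == 0:
        raise ValueError("no features supplied")
    kinds = dict(kinds or {})
    feature_ids = [str(c) for c in X_train.columns]
    M = X_train.to_numpy(dtype=float)
    if not np.isfinite(M).all():
        raise ValueError("non-finite feature values in training matrix")

    if name == "NB":
        categorical = np.array(
            [kinds.get(f, "continuous") in ("binary", "ordinal", "categorical")
             for f in feature_ids]
        )
        state: object = _MixedNB().fit(M, y, categorical)
    elif name == "NM":
        state = _NearestMean().fit(M, y)
    elif name == "3NN":
        k = min(3, len(y) - 1)
        state = KNeighborsClassifier(n_neighbors=k, algorithm="brute").fit(M, y)
    elif name == "LREG":
        state = LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000).fit(M, y)
    elif name == "SVM":
        state = Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="linear", C=1.0))]
        ).fit(M, y)
    elif name == "TREE":
        state = DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=2, random_state=0
        ).fit(M, y)
    return TrainedPredictor(name=name, feature_ids=feature_ids, kinds=kinds, state=state)
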