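"""Random-forest activity classification and evaluation.

Seven activities are recognised from the fused feature vectors: watching
TV, playing with toys, eating, playing electronic games, doing online
exercises, reading/writing, and drawing.  Training uses 30% of the data,
the rest is held out for testing (no cross-validation); the forest grows
100 trees, each on a bootstrap resample with 5 candidate features per
split, and predicts by majority vote over trees.

The forest is assembled here from scikit-learn decision trees rather than
taken whole from :class:`sklearn.ensemble.RandomForestClassifier`, so the
bootstrap resampling and the hard-vote / lowest-class-index tie-break are
explicit and testable (a single-tree forest is exactly one bagged tree).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, check_random_state, validate_data

__all__ = [
    "ACTIVITIES",
    "EvalResult",
    "split_dataset",
    "ActivityRandomForest",
    "evaluate",
    "train_forest",
    "predict",
]

#: Canonical 7-class activity label set, in fixed order.
ACTIVITIES: tuple[str, ...] = (
    "watching_tv",
    "playing_with_toys",
    "eating",
    "electronic_games",
    "online_exercises",
    "reading_writing",
    "drawing",
)

_CRITERIA = {"gini": "gini", "information_gain": "entropy", "entropy": "entropy"}


@dataclass(frozen=True)
class EvalResult:
    """Classification metrics on a held-out test set."""

    accuracy: float
    macro_f1: float
    confusion: np.ndarray
    labels: tuple[str, ...]
    per_class: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
        }


def split_dataset(
    X: np.ndarray,
    y: np.ndarray,
    train_frac: float = 0.30,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Single random train/test split: floor(train_frac * N) training rows.

    Sampling is uniform without replacement given the seed; there is no
    stratification and no cross-validation.  Returns
    ``(X_train, y_train, X_test, y_test)``.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    X = np.asarray(X)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the sample count")
    n = X.shape[0]
    n_train = int(np.floor(train_frac * n))
    if n_train == 0:
        raise ValueError(f"train_frac={train_frac} gives an empty training set")
    perm = np.random.default_rng(seed).permutation(n)
    tr, te = perm[:n_train], perm[n_train:]
    return X[tr], y[tr], X[te], y[te]


class ActivityRandomForest(ClassifierMixin, BaseEstimator):
    """Bagged decision-tree ensemble with hard majority voting.

    Parameters
    ----------
    n_trees : int, default 100
        Number of trees in the forest.
    m_features : int, default 5
        Candidate features drawn at random at every split (m << M).
    criterion : {"gini", "information_gain", "entropy"}, default "gini"
        Split-quality measure.
    min_impurity_decrease : float, default 0.0
        Optional early-stopping knob; by default nodes split to purity and
        tree depth is determined automatically.
    random_state : int or RandomState, optional
        Drives both the bootstrap resampling and per-tree feature
        subsampling; fixed seeds give bit-identical models.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels; vote ties resolve to the smallest class index.
    estimators_ : list of DecisionTreeClassifier
    bootstrap_indices_ : list of ndarray
        The resampled row indices each tree was grown on.
    """

    def __init__(
        self,
        n_trees: int = 100,
        m_features: int = 5,
        criterion: str = "gini",
        min_impurity_decrease: float = 0.0,
        random_state=None,
    ):
        self.n_trees = n_trees
        self.m_features = m_features
        self.criterion = criterion
        self.min_impurity_decrease = min_impurity_decrease
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if self.criterion not in _CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.m_features <= X.shape[1]:
            raise ValueError(
                f"m_features={self.m_features} outside [1, {X.shape[1]}]"
            )
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        rng = check_random_state(self.random_state)
        n = X.shape[0]
        self.estimators_ = []
        self.bootstrap_indices_ = []
        for _ in range(self.n_trees):
            idx = rng.randint(0, n, n)
            tree = DecisionTreeClassifier(
                criterion=_CRITERIA[self.criterion],
                max_features=self.m_features,
                min_impurity_decrease=self.min_impurity_decrease,
                random_state=rng.randint(np.iinfo(np.int32).max),
            )
            tree.fit(X[idx], y_enc[idx])
            self.estimators_.append(tree)
            self.bootstrap_indices_.append(idx)
        return self

    def _vote_counts(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        counts = np.zeros((X.shape[0], self.classes_.size), dtype=int)
        rows = np.arange(X.shape[0])
        for tree in self.estimators_:
            # trees were trained on encoded labels, so predictions are
            # indices into self.classes_
            pred = tree.predict(X).astype(int)
            np.add.at(counts, (rows, pred), 1)
        return counts

    def predict(self, X):
        counts = self._vote_counts(X)
        # np.argmax takes the first maximum: ties go to the lowest class index
        return self.classes_[np.argmax(counts, axis=1)]

    def predict_proba(self, X):
        counts = self._vote_counts(X)
        return counts / self.n_trees


def train_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    m_features: int = 5,
    criterion: str = "gini",
    seed: int | None = None,
    min_impurity_decrease: float = 0.0,
) -> ActivityRandomForest:
    """Convenience wrapper: fit an :class:`ActivityRandomForest`."""
    m = min(m_features, np.asarray(X).shape[1])
    return ActivityRandomForest(
        n_trees=n_trees,
        m_features=m,
        criterion=criterion,
        min_impurity_decrease=min_impurity_decrease,
        random_state=seed,
    ).fit(X, y)


def predict(model: ActivityRandomForest, X: np.ndarray) -> np.ndarray:
    """Majority-vote predictions of a fitted forest."""
    return model.predict(X)


def evaluate(
    model: ActivityRandomForest,
    X: np.ndarray,
    y: np.ndarray,
    labels: tuple[str, ...] | None = None,
) -> EvalResult:
    """Accuracy, macro F1 and the confusion matrix on a test set.

    Macro F1 averages the per-class F1 over *all* listed classes
    (default: the 7 activities), counting classes with no predictions and
    no truth as 0 so the metric stays bounded.
    """
    y = np.asarray(y)
    if labels is None:
        labels = ACTIVITIES if set(np.unique(y)) <= set(ACTIVITIES) else tuple(
            np.unique(y)
        )
    y_pred = model.predict(X)
    label_list = list(labels)
    cm = confusion_matrix(y, y_pred, labels=label_list)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y, y_pred, labels=label_list, zero_division=0
    )
    accuracy = float(np.trace(cm)) / float(len(y))
    per_class = {
        lab: {
            "precision": float(p),
            "recall": float(r),
            "f1": float(f),
        }
        for lab, p, r, f in zip(label_list, precision, recall, f1)
    }
    return EvalResult(
        accuracy=accuracy,
        macro_f1=float(np.mean(f1)),
        confusion=cm,
        labels=tuple(label_list),
        per_class=per_class,
    )
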