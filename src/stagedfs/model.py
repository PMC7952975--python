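"""Stage 3: gradient-boosted decision trees tuned by Bayesian optimization.

The embedded model is a scikit-learn ``GradientBoostingClassifier`` whose six
hyperparameters (learning_rate, max_depth, min_samples_leaf,
min_samples_split, n_estimators, subsample) are tuned by TPE (or random
search) against a stratified fivefold cross-validation loss, 1 - mean
validation accuracy.  Fold assignment is frozen once per optimization run so
that trials are comparable.

Fixed-setting baseline classifiers (linear SVM with C=1, KNN with 7
neighbours and the Manhattan metric, and a random forest) share the same
prediction contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import PipelineError
from .optimize import HyperparamSpace, random_search, tpe_optimize

logger = logging.getLogger(__name__)

BASELINE_NAMES = ("SVM", "KNN", "RF")


def make_gbdt(params: dict | None = None, seed: int = 0) -> GradientBoostingClassifier:
    """A GBDT at the given hyperparameter point (defaults when params is None)."""
    return GradientBoostingClassifier(random_state=seed, **(params or {}))


def cv_objective(
    params: dict, X, y, k: int = 5, seed: int = 0, metric: str = "accuracy"
) -> float:
    """Stratified k-fold CV loss (1 - mean validation accuracy) of a GBDT.

    The fold assignment is a pure function of ``seed`` so every trial of an
    optimization run sees the same folds.  ``metric="balanced_accuracy"``
    swaps in macro-average recall as the score.
    """
    X, y = np.asarray(X), np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(np.unique(y)) < 2:
        raise PipelineError("cross-validation requires both classes")
    if np.bincount(y).min() < k:
        raise PipelineError(
            f"minority class too small for {k}-fold stratification"
        )
    if metric not in ("accuracy", "balanced_accuracy"):
        raise ValueError(f"unknown objective metric {metric!r}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    accs = []
    for train_idx, val_idx in skf.split(X, y):
        clf = make_gbdt(params, seed=seed % 2**31)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[val_idx])
        if metric == "accuracy":
            accs.append(float((pred == y[val_idx]).mean()))
        else:
            accs.append(
                float(np.mean([(pred[y[val_idx] == c] == c).mean()
                               for c in np.unique(y[val_idx])]))
            )
    return 1.0 - float(np.mean(accs))


@dataclass
class FittedModel:
    """A trained classifier bound to the exact feature (gene) list it saw."""

    estimator: object
    genes: tuple[str, ...]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def _check(self, genes) -> None:
        if tuple(genes) != self.genes:
            raise ValueError(
                "feature gene list mismatch: the model was trained on a "
                "different gene list/order"
            )

    def predict(self, X, genes) -> np.ndarray:
        self._check(genes)
        return self.estimator.predict(np.asarray(X))

    def predict_proba_tumor(self, X, genes) -> np.ndarray:
        self._check(genes)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(np.asarray(X))
            return proba[:, list(est.classes_).index(1)]
        scores = est.decision_function(np.asarray(X))
        return 1.0 / (1.0 + np.exp(-scores))


def train_final(params: dict, X, y, genes, seed: int = 0) -> FittedModel:
    """Train the GBDT at ``params`` on the full learning split."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise PipelineError("training data contains a single class")
    clf = make_gbdt(params, seed=seed % 2**31)
    clf.fit(np.asarray(X), y)
    return FittedModel(estimator=clf, genes=tuple(genes), params=dict(params), seed=seed)


def baseline_classifier(name: str, seed: int = 0):
    """The fixed-setting comparison classifiers.

    SVM: C=1, linear kernel.  KNN: 7 neighbours, Manhattan metric.
    RF: max_depth=46, min_samples_leaf=2, min_samples_split=94,
    n_estimators=75.
    """
    if name == "SVM":
        return SVC(C=1.0, kernel="linear", random_state=seed % 2**31)
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=7, metric="manhattan")
    if name == "RF":
        return RandomForestClassifier(
            max_depth=46,
            min_samples_leaf=2,
            min_samples_split=94,
            n_estimators=75,
            random_state=seed % 2**31,
        )
    raise ValueError(f"unknown baseline {name!r}; choose from {BASELINE_NAMES}")


class TunedGradientBoostingClassifier(ClassifierMixin, BaseEstimator):
    """GBDT with TPE (or random-search) hyperparameter tuning inside ``fit``.

    ``fit`` runs ``n_iter`` trials of the chosen optimizer against the
    stratified k-fold CV loss on the training data, then refits a GBDT at the
    best point.  Composes with sklearn pipelines and model selection.

    Parameters
    ----------
    n_iter : optimization budget (trials).
    k : CV folds of the objective.
    method : "tpe" or "random".
    space : HyperparamSpace or None for the default box.
    random_state : seed for folds, sampler and the final model.

    Attributes
    ----------
    best_params_ : dict        best hyperparameter point found
    best_loss_ : float         its CV loss
    history_ : list of Trial   every trial, in order
    estimator_ : the refitted GradientBoostingClassifier
    """

    def __init__(
        self,
        n_iter: int = 300,
        k: int = 5,
        method: str = "tpe",
        space: HyperparamSpace | None = None,
        objective_metric: str = "accuracy",
        random_state: int = 0,
    ):
        self.n_iter = n_iter
        self.k = k
        self.method = method
        self.space = space
        self.objective_metric = objective_metric
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        y = np.asarray(y).astype(int)
        space = self.space if self.space is not None else HyperparamSpace()
        if self.method not in ("tpe", "random"):
            raise ValueError(f"unknown method {self.method!r}")
        objective = lambda params: cv_objective(
            params, X, y, k=self.k, seed=self.random_state,
            metric=self.objective_metric,
        )
        optimizer = tpe_optimize if self.method == "tpe" else random_search
        best, history = optimizer(
            space, objective, n_iter=self.n_iter, seed=self.random_state
        )
        self.best_params_ = dict(best.params)
        self.best_loss_ = best.cv_loss
        self.history_ = history
        self.estimator_ = make_gbdt(self.best_params_, seed=self.random_state % 2**31)
        self.estimator_.fit(X, y)
        self.classes_ = self.estimator_.classes_
        logger.info(
            "%s tuning over %d trials: best cv_loss=%.4f %s",
            self.method, self.n_iter, self.best_loss_, self.best_params_,
        )
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.estimator_.predict_proba(X)
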