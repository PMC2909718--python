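"""The five classification methods behind one fit/predict contract.

* ``svml`` — soft-margin linear-kernel SVM, cost fixed at 1.
* ``svmr`` — radial-basis-kernel SVM; gamma selected by stratified
  inner 10-fold cross-validation on a logarithmic grid around the
  1/n_features heuristic, cost fixed at 1.
* ``rf`` — random forest, 1000 trees, 20 candidate variables per split.
* ``pplsda`` — powered-PLS discriminant analysis (see :mod:`poolsim.ppls`);
  the number of components is chosen by inner 10-fold CV.
* ``ttest_lda`` — per-feature two-sample t-test (pooled variance); the
  ten smallest p-values select the features for a linear discriminant
  analysis.

All methods are scikit-learn estimators; the ``train_*`` functions wrap
them into a :class:`TrainedModel` carrying the method tag and a record
of the tuned hyperparameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils import check_random_state
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .config import METHODS, PPLSDA, RF, SVML, SVMR, TTEST_LDA, ClassifierConfig
from .ppls import PPLSDAClassifier


def _check_two_class(y) -> None:
    if len(np.unique(y)) != 2:
        raise ValueError("training labels must contain exactly two classes")


class TunedRBFSVM(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with gamma chosen by inner stratified CV.

    The grid is ``2**e / n_features`` for the exponents in
    ``gamma_grid_log2``; the gamma with the smallest CV
    misclassification count wins, ties going to the smallest gamma.
    """

    def __init__(self, C=1.0, gamma_grid_log2=tuple(range(-10, 3)), cv=10,
                 random_state=None):
        self.C = C
        self.gamma_grid_log2 = gamma_grid_log2
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        _check_two_class(y)
        rs = check_random_state(self.random_state)
        _, y01 = np.unique(y, return_inverse=True)
        grid = np.array(
            [2.0**e / X.shape[1] for e in self.gamma_grid_log2], dtype=float
        )
        n_splits = max(2, int(min(self.cv, np.bincount(y01).min())))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rs)
        errors = np.zeros(len(grid))
        folds = list(skf.split(X, y01))
        for gi, gamma in enumerate(grid):
            for train, val in folds:
                clf = SVC(kernel="rbf", C=self.C, gamma=gamma)
                clf.fit(X[train], y[train])
                errors[gi] += np.sum(clf.predict(X[val]) != y[val])
        best = int(np.argmin(errors))  # first minimum = smallest gamma
        self.gamma_grid_ = grid
        self.cv_errors_ = errors
        self.gamma_ = float(grid[best])
        self.svc_ = SVC(kernel="rbf", C=self.C, gamma=self.gamma_)
        self.svc_.fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self.svc_.predict(X)


class TTestLDAClassifier(ClassifierMixin, BaseEstimator):
    """Univariate t-test feature selection followed by LDA.

    Per feature, a two-sample t-test (pooled variance by default, Welch
    with ``equal_var=False``) compares the classes; the ``n_select``
    features with the smallest p-values (ties broken by column index)
    feed a linear discriminant analysis.  With few training samples the
    pooled covariance of the selected features can be (near-)singular;
    the SVD-based discriminant then effectively uses a pseudo-inverse,
    and a warning is emitted.
    """

    def __init__(self, n_select=10, equal_var=True):
        self.n_select = n_select
        self.equal_var = equal_var

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        _check_two_class(y)
        if X.shape[1] < self.n_select:
            raise ValueError(
                f"need at least n_select={self.n_select} features, got {X.shape[1]}"
            )
        classes = np.unique(y)
        a, b = X[y == classes[0]], X[y == classes[1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, axis=0, equal_var=self.equal_var)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        order = np.argsort(pvals, kind="stable")  # stable = ties by column index
        self.selected_features_ = np.sort(order[: self.n_select])
        self.pvalues_ = pvals
        if len(y) - 2 <= self.n_select:
            warnings.warn(
                "fewer training samples than selected features; LDA uses a "
                "pseudo-inverse of the pooled covariance",
                stacklevel=2,
            )
        self.lda_ = LinearDiscriminantAnalysis(solver="svd")
        self.lda_.fit(X[:, self.selected_features_], y)
        self.classes_ = self.lda_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "lda_")
        X = check_array(X, dtype=float, ensure_min_samples=0)
        if X.shape[0] == 0:
            return np.empty(0, dtype=self.classes_.dtype)
        return self.lda_.predict(X[:, self.selected_features_])


@dataclass
class TrainedModel:
    """A fitted classifier with its method tag and tuning record."""

    method: str
    estimator: object
    tuning: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        return predict(self, X)


def predict(model: TrainedModel, X) -> np.ndarray:
    """One label per test row; empty input yields an empty label array."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("test matrix must be two-dimensional")
    if X.shape[0] == 0:
        return np.empty(0, dtype=model.estimator.classes_.dtype)
    return model.estimator.predict(X)


def _seed(rng) -> int | None:
    if rng is None:
        return None
    if isinstance(rng, (int, np.integer)):
        return int(rng)
    return int(np.random.default_rng(rng).integers(2**31 - 1))


def train_svm_linear(Y, labels, cfg: ClassifierConfig | None = None) -> TrainedModel:
    cfg = cfg or ClassifierConfig()
    _check_two_class(labels)
    est = SVC(kernel="linear", C=cfg.svm_cost)
    est.fit(np.asarray(Y, dtype=float), labels)
    return TrainedModel(SVML, est, {"cost": cfg.svm_cost})


def train_svm_radial(Y, labels, cfg: ClassifierConfig | None = None, rng=None) -> TrainedModel:
    cfg = cfg or ClassifierConfig()
    est = TunedRBFSVM(
        C=cfg.svm_cost,
        gamma_grid_log2=cfg.gamma_grid_log2,
        cv=cfg.inner_cv,
        random_state=_seed(rng),
    )
    est.fit(np.asarray(Y, dtype=float), labels)
    return TrainedModel(
        SVMR, est,
        {"cost": cfg.svm_cost, "gamma": est.gamma_, "gamma_grid": list(est.gamma_grid_)},
    )


def train_random_forest(Y, labels, cfg: ClassifierConfig | None = None, rng=None) -> TrainedModel:
    cfg = cfg or ClassifierConfig()
    _check_two_class(labels)
    Y = np.asarray(Y, dtype=float)
    est = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=min(cfg.mtry, Y.shape[1]),
        random_state=_seed(rng),
    )
    est.fit(Y, labels)
    return TrainedModel(RF, est, {"n_trees": cfg.n_trees, "mtry": min(cfg.mtry, Y.shape[1])})


def train_pplsda(Y, labels, cfg: ClassifierConfig | None = None, rng=None) -> TrainedModel:
    cfg = cfg or ClassifierConfig()
    est = PPLSDAClassifier(
        max_components=cfg.max_components,
        power_bounds=cfg.power_bounds,
        n_power=cfg.n_power,
        cv=cfg.inner_cv,
        random_state=_seed(rng),
    )
    est.fit(np.asarray(Y, dtype=float), labels)
    return TrainedModel(
        PPLSDA, est,
        {"n_components": est.n_components_, "powers": list(est.powers_)},
    )


def train_ttest_lda(Y, labels, cfg: ClassifierConfig | None = None) -> TrainedModel:
    cfg = cfg or ClassifierConfig()
    est = TTestLDAClassifier(n_select=cfg.n_select, equal_var=cfg.equal_var)
    est.fit(np.asarray(Y, dtype=float), labels)
    return TrainedModel(
        TTEST_LDA, est,
        {
            "selected_features": list(map(int, est.selected_features_)),
            "pvalues": [float(est.pvalues_[i]) for i in est.selected_features_],
        },
    )


_TRAINERS = {
    SVML: lambda Y, lab, cfg, rng: train_svm_linear(Y, lab, cfg),
    SVMR: train_svm_radial,
    RF: train_random_forest,
    PPLSDA: train_pplsda,
    TTEST_LDA: lambda Y, lab, cfg, rng: train_ttest_lda(Y, lab, cfg),
}


def train_classifier(method: str, Y, labels, cfg: ClassifierConfig | None = None,
                     rng=None) -> TrainedModel:
    """Train one of the five methods on a measured training matrix."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return _TRAINERS[method](Y, labels, cfg, rng)


def make_classifier(method: str, cfg: ClassifierConfig | None = None,
                    n_features: int | None = None, random_state=None):
    """Unfitted scikit-learn estimator for a method tag."""
    cfg = cfg or ClassifierConfig()
    if method == SVML:
        return SVC(kernel="linear", C=cfg.svm_cost)
    if method == SVMR:
        return TunedRBFSVM(C=cfg.svm_cost, gamma_grid_log2=cfg.gamma_grid_log2,
                           cv=cfg.inner_cv, random_state=_seed(random_state))
    if method == RF:
        mtry = cfg.mtry if n_features is None else min(cfg.mtry, n_features)
        return RandomForestClassifier(n_estimators=cfg.n_trees, max_features=mtry,
                                      random_state=_seed(random_state))
    if method == PPLSDA:
        return PPLSDAClassifier(max_components=cfg.max_components,
                                power_bounds=cfg.power_bounds, n_power=cfg.n_power,
                                cv=cfg.inner_cv, random_state=_seed(random_state))
    if method == TTEST_LDA:
        return TTestLDAClassifier(n_select=cfg.n_select, equal_var=cfg.equal_var)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
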