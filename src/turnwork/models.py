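"""Regression and classification suite for the per-turn targets.

Four regression families predict the continuous responses (positive and
negative external work, approach and exit speed) from the 18 IMU features,
and four classifier families predict the pivot side.  The estimators are
scikit-learn compatible (``fit``/``predict``/``get_params``) so they compose
with sklearn model selection; :func:`crossval_regress` and
:func:`crossval_classify` wrap them with the evaluation protocol: a seeded
10-fold cross-validation with metrics pooled over held-out predictions for
the deterministic families, and a seeded 70/15/15 train/validation/test
split with validation-based early stopping for the neural network.

Unstated hyperparameters follow fixed conventions: the support-vector
epsilon tube is 0.1 times the response SD, the Gaussian kernel width comes
from the median pairwise-distance heuristic on standardized inputs, and
boosted trees use 40 learners (least-squares gradient boosting for
regression, adaptive boosting for classification) at learning rate 0.1.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingRegressor
from sklearn.linear_model import LinearRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR
from sklearn.utils.validation import check_is_fitted, validate_data

REGRESSION_FAMILIES = ("multilinear", "svr_gaussian", "boosted_trees", "ann")
CLASSIFIER_FAMILIES = ("lda", "svm_gaussian", "boosted_trees", "ann")

POSITIVE_CLASS = "left"  # sensitivity/specificity convention


def _median_gamma(X_scaled: np.ndarray, random_state: int | None) -> float:
    """RBF gamma = 1 / (2 m^2), m the median pairwise distance (subsampled)."""
    rng = np.random.default_rng(random_state)
    n = X_scaled.shape[0]
    sub = X_scaled[rng.choice(n, size=min(n, 400), replace=False)]
    d = pdist(sub)
    d = d[d > 0]
    if d.size == 0:
        return 1.0 / X_scaled.shape[1]
    m = float(np.median(d))
    return 1.0 / (2.0 * m * m)


class TurnRegressor(RegressorMixin, BaseEstimator):
    """Per-turn response regressor over the 18 IMU features.

    Parameters
    ----------
    family : str
        One of ``multilinear``, ``svr_gaussian``, ``boosted_trees``, ``ann``.
    n_trees : int
        Number of boosting stages for the boosted-trees family.
    hidden_neurons : int
        Hidden-layer width of the neural network (tanh activation, single
        hidden layer, one linear output).
    learning_rate : float
        Boosting shrinkage.
    epsilon_factor : float
        Support-vector epsilon tube as a fraction of SD(y).
    random_state : int or None
        Seed for the stochastic families.
    """

    def __init__(self, family: str = "svr_gaussian", n_trees: int = 40,
                 hidden_neurons: int = 40, learning_rate: float = 0.1,
                 epsilon_factor: float = 0.1, max_iter: int = 2000,
                 early_stopping: bool = True,
                 random_state: int | None = None):
        self.family = family
        self.n_trees = n_trees
        self.hidden_neurons = hidden_neurons
        self.learning_rate = learning_rate
        self.epsilon_factor = epsilon_factor
        self.max_iter = max_iter
        self.early_stopping = early_stopping
        self.random_state = random_state

    def _build(self, X, y):
        if self.family == "multilinear":
            return LinearRegression()
        if self.family == "boosted_trees":
            return GradientBoostingRegressor(
                n_estimators=self.n_trees, learning_rate=self.learning_rate,
                random_state=self.random_state)
        if self.family == "svr_gaussian":
            scaler = StandardScaler().fit(X)
            gamma = _median_gamma(scaler.transform(X), self.random_state)
            eps = self.epsilon_factor * float(np.std(y))
            return make_pipeline(
                StandardScaler(),
                SVR(kernel="rbf", gamma=gamma, epsilon=eps, C=10.0))
        if self.family == "ann":
            return make_pipeline(
                StandardScaler(),
                MLPRegressor(hidden_layer_sizes=(self.hidden_neurons,),
                             activation="tanh", max_iter=self.max_iter,
                             learning_rate_init=0.01, tol=1e-5,
                             early_stopping=self.early_stopping,
                             validation_fraction=0.15, n_iter_no_change=50,
                             random_state=self.random_state))
        raise ValueError(f"unknown regression family: {self.family}")

    def fit(self, X, y):
        X, y = validate_data(self, X, y, y_numeric=True)
        if self.family in ("ann", "boosted_trees") and self.random_state is None:
            raise ValueError(f"family {self.family!r} requires random_state")
        self.model_ = self._build(X, y).fit(X, y)
        if self.family == "boosted_trees":
            self.feature_importances_ = self.model_.feature_importances_
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.model_.predict(X)


class TurnSideClassifier(ClassifierMixin, BaseEstimator):
    """Pivot-side (left/right) classifier over the 18 IMU features."""

    def __init__(self, family: str = "lda", n_trees: int = 40,
                 hidden_neurons: int = 40, learning_rate: float = 0.1,
                 max_iter: int = 2000, early_stopping: bool = True,
                 random_state: int | None = None):
        self.family = family
        self.n_trees = n_trees
        self.hidden_neurons = hidden_neurons
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.early_stopping = early_stopping
        self.random_state = random_state

    def _build(self, X):
        if self.family == "lda":
            return LinearDiscriminantAnalysis()
        if self.family == "boosted_trees":
            return AdaBoostClassifier(
                n_estimators=self.n_trees,
                learning_rate=self.learning_rate,
                random_state=self.random_state)
        if self.family == "svm_gaussian":
            scaler = StandardScaler().fit(X)
            gamma = _median_gamma(scaler.transform(X), self.random_state)
            return make_pipeline(
                StandardScaler(), SVC(kernel="rbf", gamma=gamma, C=10.0))
        if self.family == "ann":
            return make_pipeline(
                StandardScaler(),
                MLPClassifier(hidden_layer_sizes=(self.hidden_neurons,),
                              activation="tanh", max_iter=self.max_iter,
                              learning_rate_init=0.01, tol=1e-5,
                              early_stopping=self.early_stopping,
                              validation_fraction=0.15, n_iter_no_change=50,
                              random_state=self.random_state))
        raise ValueError(f"unknown classifier family: {self.family}")

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype="numeric")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("both classes must be present")
        self.model_ = self._build(X).fit(X, y)
        if self.family == "boosted_trees":
            self.feature_importances_ = self.model_.feature_importances_
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.model_.predict(X)

    def decision_scores(self, X):
        """Continuous score for the positive (left) class, for ROC/AUC."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        inner = self.model_
        if hasattr(inner, "predict_proba"):
            proba = inner.predict_proba(X)
            pos = list(inner.classes_).index(
                POSITIVE_CLASS if POSITIVE_CLASS in inner.classes_
                else inner.classes_[-1])
            return proba[:, pos]
        score = inner.decision_function(X)
        if inner.classes_[-1] != POSITIVE_CLASS and POSITIVE_CLASS in inner.classes_:
            score = -score
        return score


def regression_metrics(y_true, y_pred):
    """(R^2, RMSE, MAE) with R^2 = 1 - SSE/SST."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must be equal length, n >= 2")
    sst = float(np.sum((y_true - np.mean(y_true)) ** 2))
    if sst == 0.0:
        raise ValueError("zero-variance y_true: R^2 undefined")
    err = y_true - y_pred
    r2 = 1.0 - float(np.sum(err**2)) / sst
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    return r2, rmse, mae


def bt_feature_importance(model) -> np.ndarray:
    """Split-gain feature importances of a fitted boosted-trees model,
    normalized to sum to one."""
    imp = getattr(model, "feature_importances_", None)
    if imp is None:
        raise ValueError("model is not a fitted boosted-trees model")
    imp = np.asarray(imp, dtype=float)
    total = imp.sum()
    return imp / total if total > 0 else np.full_like(imp, 1.0 / imp.size)


def _ann_split_eval(est, X, y, seed, classifier: bool):
    """Seeded 70/15/15 split: fit on 85% (with internal validation-based
    early stopping) and report on the held-out 15% test portion."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(0.15 * n))
    test, fit_idx = perm[:n_test], perm[n_test:]
    est = clone(est)
    est.set_params(random_state=seed)
    est.fit(X[fit_idx], y[fit_idx])
    return est, test


def crossval_regress(X, y, family: str, k: int = 10, seed: int = 0,
                     ann_mode: str = "split", **hyper) -> dict:
    """Evaluate one regression family on one response.

    Deterministic families use a seeded random ``k``-fold partition with
    metrics pooled over the held-out predictions; the neural network uses
    the 70/15/15 split protocol by default (``ann_mode="cv"`` forces k-fold).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} rows is fewer than k={k} folds")
    if family == "ann":
        hyper.setdefault("early_stopping", ann_mode == "split")
    est = TurnRegressor(family=family, random_state=seed, **hyper)
    if family == "ann" and ann_mode == "split":
        fitted, test = _ann_split_eval(est, X, y, seed, classifier=False)
        y_true, y_pred = y[test], fitted.predict(X[test])
        scheme = "70/15/15 split"
    else:
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        y_pred = np.empty_like(y)
        for tr, te in kf.split(X):
            y_pred[te] = clone(est).fit(X[tr], y[tr]).predict(X[te])
        y_true = y
        scheme = f"{k}-fold CV"
    r2, rmse, mae = regression_metrics(y_true, y_pred)
    return {"family": family, "scheme": scheme, "seed": seed, "n": int(X.shape[0]),
            "r2": r2, "rmse": rmse, "mae": mae}


def crossval_classify(X, y, family: str, k: int = 10, seed: int = 0,
                      ann_mode: str = "split", **hyper) -> dict:
    """Evaluate one classifier family on the side labels.

    Reports pooled held-out accuracy, sensitivity and specificity (positive
    class = left) in percent, and the AUC of the held-out scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} rows is fewer than k={k} folds")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if family == "ann":
        hyper.setdefault("early_stopping", ann_mode == "split")
    est = TurnSideClassifier(family=family, random_state=seed, **hyper)
    if family == "ann" and ann_mode == "split":
        fitted, test = _ann_split_eval(est, X, y, seed, classifier=True)
        y_true = y[test]
        y_pred = fitted.predict(X[test])
        scores = fitted.decision_scores(X[test])
        scheme = "70/15/15 split"
    else:
        kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        y_pred = np.empty_like(y)
        scores = np.empty(X.shape[0])
        for tr, te in kf.split(X, y):
            m = clone(est).fit(X[tr], y[tr])
            y_pred[te] = m.predict(X[te])
            scores[te] = m.decision_scores(X[te])
        y_true = y
        scheme = f"{k}-fold CV"
    pos = y_true == POSITIVE_CLASS
    neg = ~pos
    acc = 100.0 * float(np.mean(y_pred == y_true))
    sens = 100.0 * float(np.mean(y_pred[pos] == POSITIVE_CLASS)) if pos.any() else np.nan
    spec = 100.0 * float(np.mean(y_pred[neg] != POSITIVE_CLASS)) if neg.any() else np.nan
    auc = float(roc_auc_score(pos.astype(int), scores)) if pos.any() and neg.any() else np.nan
    return {"family": family, "scheme": scheme, "seed": seed, "n": int(X.shape[0]),
            "accuracy": acc, "sensitivity": sens, "specificity": spec, "auc": auc}


@dataclass
class EvalReport:
    """Per model x response metrics plus boosted-trees feature importances."""

    regression: list = field(default_factory=list)
    classification: list = field(default_factory=list)
    importances: dict = field(default_factory=dict)
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "meta": self.meta,
                "regression": self.regression,
                "classification": self.classification,
                "importances": {k: list(map(float, v))
                                for k, v in self.importances.items()}}

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_model_suite(features, responses, k: int = 10, seed: int = 0,
                    regression_families=REGRESSION_FAMILIES,
                    classifier_families=CLASSIFIER_FAMILIES,
                    responses_to_fit=("w_plus", "w_minus", "v_before", "v_after"),
                    ) -> EvalReport:
    """Train and evaluate every requested family on every response.

    ``features`` is the (n_turns, 18) predictor table, ``responses`` the
    matching per-turn table with the continuous targets and the ``side``
    labels.  Boosted-trees feature importances (refit on the full data) are
    reported per continuous response.
    """
    X = np.asarray(features, dtype=float)
    report = EvalReport(seed=seed, meta={"k_folds": k, "n_turns": int(X.shape[0])})
    for resp in responses_to_fit:
        y = responses[resp].to_numpy(dtype=float)
        for fam in regression_families:
            res = crossval_regress(X, y, fam, k=k, seed=seed)
            res["response"] = resp
            report.regression.append(res)
        if "boosted_trees" in regression_families:
            bt = TurnRegressor(family="boosted_trees", random_state=seed).fit(X, y)
            report.importances[resp] = bt_feature_importance(bt)
    if "side" in responses:
        y = responses["side"].to_numpy()
        for fam in classifier_families:
            res = crossval_classify(X, y, fam, k=k, seed=seed)
            report.classification.append(res)
    return report
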