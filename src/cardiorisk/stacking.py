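"""Base learners, grid-search tuning, and stacking-ensemble risk classifiers.

The model surface follows the fitted-model convention: a `ZoneStackingModel`
is built from a (preprocessed, labeled) table, its `fit()` returns a
`ZoneStackingResults` holding the fitted ensemble, training diagnostics and
a `summary()` table, and prediction/evaluation hang off the results object.

Stacking uses out-of-fold class-probability vectors from k-fold
cross-validation as meta-features and a logistic-regression meta-learner;
base learners are refit on the full training data afterwards.  Default
base-learner sets are {KNN, XGB, MLP} for the two-zone scheme and
{SVM, KNN, XGB} for the three-zone scheme.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
    StackingClassifier,
)
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .errors import ConfigurationError, InvalidInputError
from .metrics import MetricReport, evaluate_classifier, roc_auc_report
from .preprocess import ZONE_COLUMN, FeatureTable

#: Canonical short names of the ten candidate base learners.
LEARNER_NAMES = (
    "knn", "naive_bayes", "random_forest", "svm", "gradient_boosting",
    "sgd", "xgb", "mlp", "decision_tree", "adaboost",
)

DEFAULT_BASE_LEARNERS = {
    "two": ("knn", "xgb", "mlp"),
    "three": ("svm", "knn", "xgb"),
}

#: Modest default hyperparameter grids for `tune_base_learner`.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": [3, 5, 9], "weights": ["uniform", "distance"]},
    "naive_bayes": {"var_smoothing": [1e-9, 1e-7]},
    "random_forest": {"n_estimators": [100, 200], "max_depth": [None, 8]},
    "svm": {"C": [0.5, 1.0, 4.0], "gamma": ["scale", 0.1]},
    "gradient_boosting": {"n_estimators": [100], "max_depth": [2, 3]},
    "sgd": {"alpha": [1e-4, 1e-3]},
    "xgb": {"n_estimators": [100, 200], "max_depth": [3, 5]},
    "mlp": {"hidden_layer_sizes": [(50,), (100,)], "alpha": [1e-4, 1e-3]},
    "decision_tree": {"max_depth": [None, 4, 8]},
    "adaboost": {"n_estimators": [50, 100]},
}


def make_learner(name: str, seed: int = 0, **params):
    """Instantiate a base learner by short name with sensible defaults.

    All learners expose ``predict_proba`` so they can feed probability
    stacking (SGD uses log loss; SVC enables Platt scaling).
    """
    builders = {
        "knn": lambda: KNeighborsClassifier(),
        "naive_bayes": lambda: GaussianNB(),
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed),
        "svm": lambda: SVC(probability=True, random_state=seed),
        "gradient_boosting": lambda: GradientBoostingClassifier(random_state=seed),
        "sgd": lambda: SGDClassifier(loss="log_loss", random_state=seed),
        "xgb": lambda: XGBClassifier(
            n_estimators=100, max_depth=3, eval_metric="logloss",
            random_state=seed, verbosity=0),
        "mlp": lambda: MLPClassifier(
            hidden_layer_sizes=(50,), max_iter=600, random_state=seed),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed),
    }
    if name not in builders:
        raise ConfigurationError(
            f"unknown learner {name!r}; choose from {LEARNER_NAMES}"
        )
    est = builders[name]()
    if params:
        est.set_params(**params)
    return est


#: Canonical ordering of zone names when labels arrive as strings.
ZONE_ORDER = ("green", "yellow", "red")


def _as_xy(table, label_col: str = ZONE_COLUMN):
    """Extract (X, y, feature_names, class_names) from a labeled table.

    String zone labels are encoded to 0..K-1 codes ordered green < yellow
    < red (several learners require consecutive integer classes);
    ``class_names`` maps the codes back, or is None for numeric labels.
    """
    df = table.data if isinstance(table, FeatureTable) else table
    if label_col not in df.columns:
        raise InvalidInputError(f"no label column {label_col!r} in table")
    y_raw = df[label_col]
    if y_raw.isna().any():
        raise InvalidInputError(f"label column {label_col!r} has missing values")
    if y_raw.dtype == object:
        present = [z for z in ZONE_ORDER if z in set(y_raw)]
        extra = sorted(set(y_raw) - set(present))
        if extra:
            raise InvalidInputError(f"unknown zone label(s): {extra}")
        mapping = {z: i for i, z in enumerate(present)}
        y = y_raw.map(mapping).to_numpy(dtype=int)
        class_names = tuple(present)
    else:
        y = y_raw.to_numpy()
        class_names = None
    drop = [c for c in (label_col, "num", ZONE_COLUMN) if c in df.columns]
    X = df.drop(columns=drop).to_numpy(dtype=float)
    feature_names = [c for c in df.columns if c not in drop]
    return X, y, feature_names, class_names


def tune_base_learner(
    name: str,
    train,
    grid: dict | None = None,
    n_folds: int = 5,
    seed: int = 0,
    label_col: str = ZONE_COLUMN,
):
    """Exhaustive grid search with k-fold CV scored by macro-F1.

    ``grid=None`` uses the declared default grid for the learner; an empty
    grid skips the search and fits the declared defaults directly.  Returns
    ``(fitted_model, trace)`` where the trace records every point scored.
    """
    X, y, _, _ = _as_xy(train, label_col)
    est = make_learner(name, seed=seed)
    if grid is None:
        grid = DEFAULT_GRIDS[name]
    if not grid:
        est.fit(X, y)
        return est, {"learner": name, "grid": {}, "searched": False,
                     "best_params": est.get_params()}
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid, scoring="f1_macro", cv=cv, refit=True)
    search.fit(X, y)
    trace = {
        "learner": name,
        "grid": grid,
        "searched": True,
        "best_params": search.best_params_,
        "best_score": float(search.best_score_),
        "cv_results": {
            "params": [dict(p) for p in search.cv_results_["params"]],
            "mean_test_score": search.cv_results_["mean_test_score"].tolist(),
        },
    }
    return search.best_estimator_, trace


@dataclass(frozen=True)
class StackingSpec:
    """Configuration of a stacking ensemble."""

    base_learners: tuple[str, ...]
    scheme: str = "three"
    n_folds: int = 5

    def __post_init__(self) -> None:
        if self.scheme not in ("two", "three"):
            raise InvalidInputError(f"scheme must be 'two' or 'three'")
        unknown = [b for b in self.base_learners if b not in LEARNER_NAMES]
        if unknown:
            raise ConfigurationError(f"unknown base learner(s): {unknown}")
        if len(self.base_learners) < 1:
            raise ConfigurationError("at least one base learner is required")

    @classmethod
    def default(cls, scheme: str = "three", n_folds: int = 5) -> "StackingSpec":
        return cls(DEFAULT_BASE_LEARNERS[scheme], scheme=scheme, n_folds=n_folds)


@dataclass(frozen=True)
class RiskPrediction:
    """A predicted risk zone with its class-probability vector."""

    zone: object
    probabilities: dict


class ZoneStackingModel:
    """Stacking-ensemble risk-zone classifier over a preprocessed table.

    Parameters
    ----------
    X, y : arrays
        Feature matrix and zone labels.
    spec : StackingSpec
        Base learners, scheme, fold count for out-of-fold meta-features.
    tuned_estimators : dict, optional
        Pre-tuned estimators keyed by learner name; untuned names fall back
        to `make_learner` defaults.
    """

    def __init__(self, X, y, spec: StackingSpec, feature_names=None,
                 class_names=None, tuned_estimators: dict | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        if self.X.shape[0] != self.y.shape[0]:
            raise InvalidInputError("X and y lengths differ")
        self.spec = spec
        self.feature_names = list(feature_names) if feature_names else [
            f"x{i}" for i in range(self.X.shape[1])
        ]
        self.class_names = tuple(class_names) if class_names else None
        self.tuned_estimators = dict(tuned_estimators or {})

    @classmethod
    def from_dataframe(
        cls,
        table,
        scheme: str = "three",
        base_learners=None,
        n_folds: int = 5,
        label_col: str = ZONE_COLUMN,
        tuned_estimators: dict | None = None,
    ) -> "ZoneStackingModel":
        X, y, names, class_names = _as_xy(table, label_col)
        spec = (
            StackingSpec(tuple(base_learners), scheme=scheme, n_folds=n_folds)
            if base_learners is not None
            else StackingSpec.default(scheme, n_folds)
        )
        return cls(X, y, spec, feature_names=names, class_names=class_names,
                   tuned_estimators=tuned_estimators)

    def fit(self, seed: int = 0) -> "ZoneStackingResults":
        """Fit base learners and the logistic meta-learner.

        Meta-features are out-of-fold probability vectors from
        ``spec.n_folds`` stratified CV on the training data; base learners
        are then refit on the whole training set.
        """
        _, counts = np.unique(self.y, return_counts=True)
        if len(counts) < 2:
            raise InvalidInputError("training labels contain a single class")
        if self.spec.n_folds > counts.min():
            raise InvalidInputError(
                f"n_folds={self.spec.n_folds} exceeds the minority-class "
                f"count {counts.min()}"
            )
        estimators = [
            (name, clone(self.tuned_estimators[name])
             if name in self.tuned_estimators else make_learner(name, seed=seed))
            for name in self.spec.base_learners
        ]
        cv = StratifiedKFold(n_splits=self.spec.n_folds, shuffle=True,
                             random_state=seed)
        stack = StackingClassifier(
            estimators=estimators,
            final_estimator=LogisticRegression(max_iter=1000, random_state=seed),
            cv=cv,
            stack_method="predict_proba",
        )
        stack.fit(self.X, self.y)
        return ZoneStackingResults(model=self, estimator=stack, seed=seed)


@dataclass
class ZoneStackingResults:
    """Fitted stacking ensemble with prediction and evaluation methods."""

    model: ZoneStackingModel
    estimator: StackingClassifier
    seed: int
    _train_report: MetricReport | None = field(default=None, repr=False)

    @property
    def classes_(self) -> np.ndarray:
        return self.estimator.classes_

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        return self.estimator.predict_proba(np.asarray(X, dtype=float))

    def predict_risk(self, X) -> list[RiskPrediction]:
        """Per-record zone + probability vector; ties break to the lowest
        class index."""
        proba = self.predict_proba(X)
        names = self.model.class_names or tuple(self.classes_)
        out = []
        for row in proba:
            k = int(np.argmax(row))  # argmax takes the first (lowest) index
            out.append(RiskPrediction(
                zone=names[k],
                probabilities={n: float(p) for n, p in zip(names, row)},
            ))
        return out

    def evaluate(self, X, y_true, labels=None) -> MetricReport:
        return evaluate_classifier(self.predict(X), np.asarray(y_true),
                                   labels=labels)

    def evaluate_table(self, table, label_col: str = ZONE_COLUMN) -> MetricReport:
        """Evaluate against a labeled FeatureTable/DataFrame directly."""
        X, y, _, _ = _as_xy(table, label_col)
        return self.evaluate(X, y)

    def roc_auc(self, X, y_true) -> dict:
        return roc_auc_report(self.predict_proba(X), np.asarray(y_true),
                              labels=self.classes_)

    @property
    def train_report(self) -> MetricReport:
        if self._train_report is None:
            self._train_report = self.evaluate(self.model.X, self.model.y)
        return self._train_report

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Zone stacking classifier results",
            "=" * 40,
            f"scheme:         {spec.scheme}-zone",
            f"base learners:  {', '.join(spec.base_learners)}",
            f"meta-learner:   logistic regression",
            f"meta-features:  out-of-fold probabilities ({spec.n_folds}-fold)",
            f"n obs:          {self.model.X.shape[0]}",
            f"n features:     {self.model.X.shape[1]}",
            f"classes:        {', '.join(map(str, self.classes_))}",
            f"seed:           {self.seed}",
            "-" * 40,
            "training-set fit",
            self.train_report.summary(),
        ]
        return "\n".join(lines)


def build_stacking(spec: StackingSpec, train, seed: int = 0,
                   label_col: str = ZONE_COLUMN,
                   tuned_estimators: dict | None = None) -> ZoneStackingResults:
    """Functional wrapper: build and fit a stack from a labeled table."""
    model = ZoneStackingModel.from_dataframe(
        train, scheme=spec.scheme, base_learners=spec.base_learners,
        n_folds=spec.n_folds, label_col=label_col,
        tuned_estimators=tuned_estimators,
    )
    return model.fit(seed=seed)


def enumerate_stack_combinations(
    candidates,
    train,
    test,
    seed: int = 0,
    scheme: str = "three",
    n_folds: int = 5,
    label_col: str = ZONE_COLUMN,
) -> pd.DataFrame:
    """Evaluate every size-3/4/5 subset of five candidate learners.

    Returns a table of macro precision/recall/F1 on the test set, one row
    per combination (16 in total), sorted by F1 descending.
    """
    candidates = tuple(candidates)
    if len(candidates) != 5:
        raise InvalidInputError(
            f"exactly 5 candidate learners are required, got {len(candidates)}"
        )
    X_test, y_test, _, _ = _as_xy(test, label_col)
    rows = []
    for size in (3, 4, 5):
        for combo in itertools.combinations(candidates, size):
            spec = StackingSpec(combo, scheme=scheme, n_folds=n_folds)
            result = build_stacking(spec, train, seed=seed, label_col=label_col)
            report = result.evaluate(X_test, y_test)
            rows.append({
                "base_learners": "+".join(combo),
                "size": size,
                "precision": report.macro_precision,
                "recall": report.macro_recall,
                "f1": report.macro_f1,
            })
    out = pd.DataFrame(rows).sort_values(
        by=["f1", "base_learners"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
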