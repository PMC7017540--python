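"""Nested cross-validation harness for stacked ensembling.

The stacking recipe: fit each base learner in a k-fold cross-validation and
collect the out-of-fold (OOF) predictions into a matrix ``Z`` with one
column per learner — row ``i`` of ``Z`` never comes from a model that saw
row ``i`` in training. Simplex weights are then fitted on ``(Z, y)`` by any
of the weighters in this package, and the blend ``Z @ w`` is the stacked
prediction.

To report an honest generalization estimate the whole procedure is nested:
an outer k-fold loop holds out a test fold; inside each outer training set
an inner k-fold builds ``Z`` and fits the weights; the base learners are
then refit on the full outer training set, their outer-test predictions are
blended with the inner-fitted weights, and the metric on the outer test
fold is recorded. The reported value for each method is the mean across
outer folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from greedystack.errors import AlgorithmError, InputError, UndefinedMetricError
from greedystack.greedy import StoppingRule, WeightVector, greedy_weights
from greedystack.metrics import MetricSpec, spearman
from greedystack.weighters import GAConfig, brute_force_weights, genetic_weights, qp_weights

__all__ = [
    "LearnerSpec",
    "CVPlan",
    "StackingReport",
    "oof_prediction_matrix",
    "nested_cv_evaluate",
    "correlated_ensemble_fixture",
    "default_learners",
    "default_weighters",
]

WeighterFn = Callable[[np.ndarray, np.ndarray], WeightVector]


@dataclass(frozen=True)
class LearnerSpec:
    """A named base learner the harness can fit and query for predictions.

    ``build`` returns a fresh unfitted estimator (sklearn-style ``fit`` /
    ``predict`` / ``predict_proba``). For classification the prediction
    column is the class-1 probability; for regression the point prediction.
    """

    name: str
    task: Literal["classification", "regression"]
    build: Callable[[], object]

    def fit(self, X, y):
        est = self.build()
        return est.fit(X, y)

    def predict(self, fitted, X) -> np.ndarray:
        if self.task == "classification":
            proba = fitted.predict_proba(X)
            classes = list(getattr(fitted, "classes_", [0, 1]))
            col = classes.index(1) if 1 in classes else proba.shape[1] - 1
            out = np.asarray(proba[:, col], dtype=float)
        else:
            out = np.asarray(fitted.predict(X), dtype=float)
        if out.shape[0] != _n_rows(X):
            raise AlgorithmError(
                f"learner {self.name!r} returned {out.shape[0]} predictions "
                f"for {_n_rows(X)} rows"
            )
        return out


@dataclass(frozen=True)
class CVPlan:
    """Fold layout for the nested harness: outer x inner k-fold, one seed."""

    outer_k: int = 5
    inner_k: int = 5
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.outer_k < 2 or self.inner_k < 2:
            raise InputError("outer_k and inner_k must both be >= 2")

    def outer_splitter(self):
        cls = StratifiedKFold if self.stratified else KFold
        return cls(n_splits=self.outer_k, shuffle=True, random_state=self.seed % (2**31))

    def inner_splitter(self, outer_fold: int):
        cls = StratifiedKFold if self.stratified else KFold
        rs = (self.seed * 1009 + outer_fold + 1) % (2**31)
        return cls(n_splits=self.inner_k, shuffle=True, random_state=rs)


def _n_rows(X) -> int:
    return X.shape[0] if hasattr(X, "shape") else len(X)


def _take(X, idx: np.ndarray):
    if isinstance(X, (pd.DataFrame, pd.Series)):
        return X.iloc[idx]
    return np.asarray(X)[idx]


def _fold_ids_from(folds, n: int) -> np.ndarray:
    """Normalize a fold assignment to an integer label per row."""
    arr = np.asarray(folds)
    if arr.shape != (n,):
        raise InputError(f"fold assignment must label each of the {n} rows")
    return arr


def oof_prediction_matrix(
    learners: Sequence[LearnerSpec],
    X,
    y,
    folds,
    seed: int = 0,
) -> np.ndarray:
    """Build the out-of-fold prediction matrix ``Z``.

    ``folds`` assigns a fold label to every row. Entry ``(i, j)`` of the
    returned n x d matrix is learner ``j``'s prediction for row ``i`` from
    the model fitted on all rows *outside* row ``i``'s fold, so no
    prediction is informed by its own row. ``seed`` is currently only part
    of the reproducibility contract: learners draw their own randomness
    from their ``build`` closures, which should be seeded.
    """
    if len(learners) < 1:
        raise InputError("need at least one learner")
    n = _n_rows(X)
    outcome = np.asarray(y)
    if outcome.shape[0] != n:
        raise InputError(f"y must have length {n}")
    fold_ids = _fold_ids_from(folds, n)
    Z = np.empty((n, len(learners)), dtype=float)
    for fold in np.unique(fold_ids):
        test = np.flatnonzero(fold_ids == fold)
        train = np.flatnonzero(fold_ids != fold)
        if train.size == 0:
            raise InputError(f"fold {fold!r} covers every row; nothing to train on")
        for j, learner in enumerate(learners):
            try:
                fitted = learner.fit(_take(X, train), outcome[train])
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise AlgorithmError(
                    f"learner {learner.name!r} failed to fit on fold {fold!r}: {exc}"
                ) from exc
            Z[test, j] = learner.predict(fitted, _take(X, test))
    return Z


def default_weighters(
    metric: MetricSpec,
    methods: Sequence[str] = ("greedy", "qp", "brute", "genetic"),
    stop: StoppingRule | None = None,
    return_best: bool = False,
    brute_step: float = 0.01,
    ga_config: GAConfig | None = None,
) -> dict[str, WeighterFn]:
    """Bind the four standard weighters to a metric, keyed by short name."""
    out: dict[str, WeighterFn] = {}
    for m in methods:
        if m == "greedy":
            out[m] = lambda Z, y, _m=metric: greedy_weights(
                Z, y, _m, stop=stop, return_best=return_best
            )[0]
        elif m == "qp":
            out[m] = lambda Z, y: qp_weights(Z, y)
        elif m == "brute":
            out[m] = lambda Z, y, _m=metric: brute_force_weights(Z, y, _m, step=brute_step)
        elif m == "genetic":
            out[m] = lambda Z, y, _m=metric: genetic_weights(Z, y, _m, config=ga_config)
        else:
            raise InputError(f"unknown weighting method {m!r}")
    return out


@dataclass
class StackingReport:
    """Per-outer-fold and mean metric for every method and single learner.

    ``fold_scores[name][f]`` is the metric of method (or learner) ``name``
    on outer test fold ``f`` (NaN if the metric was undefined there);
    ``weights[name][f]`` the weight vector fitted in that fold's inner CV.
    """

    metric_name: str
    fold_scores: dict[str, list[float]] = field(default_factory=dict)
    weights: dict[str, list[WeightVector]] = field(default_factory=dict)
    flagged_folds: list[int] = field(default_factory=list)

    @property
    def mean_scores(self) -> dict[str, float]:
        return {
            name: float(np.nanmean(scores)) for name, scores in self.fold_scores.items()
        }

    def to_frame(self) -> pd.DataFrame:
        """Method x fold table with a trailing across-fold mean column."""
        df = pd.DataFrame(self.fold_scores).T
        df.columns = [f"fold{f}" for f in range(df.shape[1])]
        df["mean"] = df.mean(axis=1, skipna=True)
        return df

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_name,
            "fold_scores": {k: list(map(float, v)) for k, v in self.fold_scores.items()},
            "mean_scores": self.mean_scores,
            "weights": {
                k: [list(map(float, wv.w)) for wv in v] for k, v in self.weights.items()
            },
            "flagged_folds": self.flagged_folds,
        }


def nested_cv_evaluate(
    learners: Sequence[LearnerSpec],
    weighters: Mapping[str, WeighterFn],
    X,
    y,
    metric: MetricSpec,
    plan: CVPlan,
) -> StackingReport:
    """Run the full nested cross-validation benchmark.

    For each outer fold: build the inner-CV out-of-fold matrix on the outer
    training rows, fit every weighter on it, refit the learners on the full
    outer training set, blend their outer-test predictions with the fitted
    weights, and score the blend and each single learner on the outer test
    fold. Folds where the metric is undefined (e.g. a single-class test
    fold) are flagged and excluded from the mean.
    """
    if len(learners) < 1:
        raise InputError("need at least one learner")
    n = _n_rows(X)
    outcome = np.asarray(y, dtype=float)
    if outcome.shape[0] != n:
        raise InputError(f"y must have length {n}")

    names = [ln.name for ln in learners]
    if len(set(names)) != len(names):
        raise InputError(f"learner names must be unique, got {names}")

    report = StackingReport(metric_name=metric.name)
    for name in list(weighters) + names:
        report.fold_scores[name] = []
    for name in weighters:
        report.weights[name] = []

    splitter = plan.outer_splitter()
    split_y = outcome if plan.stratified else None
    for fold_idx, (train, test) in enumerate(splitter.split(np.zeros(n), split_y)):
        X_tr, y_tr = _take(X, train), outcome[train]
        X_te, y_te = _take(X, test), outcome[test]

        inner = plan.inner_splitter(fold_idx)
        inner_ids = np.empty(train.size, dtype=int)
        inner_y = y_tr if plan.stratified else None
        for k, (_, val) in enumerate(inner.split(np.zeros(train.size), inner_y)):
            inner_ids[val] = k
        Z_inner = oof_prediction_matrix(learners, X_tr, y_tr, inner_ids, seed=plan.seed)

        fitted_weights = {name: fn(Z_inner, y_tr) for name, fn in weighters.items()}

        Z_test = np.column_stack(
            [ln.predict(ln.fit(X_tr, y_tr), X_te) for ln in learners]
        )

        fold_ok = True
        for name, wv in fitted_weights.items():
            report.weights[name].append(wv)
            try:
                score = metric.evaluate(Z_test @ wv.w, y_te)
            except UndefinedMetricError:
                score, fold_ok = np.nan, False
            report.fold_scores[name].append(float(score))
        for j, lname in enumerate(names):
            try:
                score = metric.evaluate(Z_test[:, j], y_te)
            except UndefinedMetricError:
                score, fold_ok = np.nan, False
            report.fold_scores[lname].append(float(score))
        if not fold_ok:
            report.flagged_folds.append(fold_idx)
            warnings.warn(
                f"metric {metric.name!r} undefined on outer fold {fold_idx}; "
                "fold excluded from the mean",
                stacklevel=2,
            )
    return report


def default_learners(task: str, seed: int = 0) -> list[LearnerSpec]:
    """The conventional diverse base-learner trio for each task.

    Classification: logistic regression, random forest, Gaussian naive
    Bayes — linear discrimination, trees, and posterior-probability
    approaches that capture different aspects of a data set. Regression:
    random forest, linear regression, RBF-kernel support vector
    regression.
    """
    if task == "classification":
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.linear_model import LogisticRegression
        from sklearn.naive_bayes import GaussianNB

        return [
            LearnerSpec("logistic", "classification",
                        lambda: LogisticRegression(max_iter=1000)),
            LearnerSpec("random_forest", "classification",
                        lambda: RandomForestClassifier(n_estimators=100, random_state=seed)),
            LearnerSpec("naive_bayes", "classification", lambda: GaussianNB()),
        ]
    if task == "regression":
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.linear_model import LinearRegression
        from sklearn.svm import SVR

        return [
            LearnerSpec("random_forest", "regression",
                        lambda: RandomForestRegressor(n_estimators=100, random_state=seed)),
            LearnerSpec("linear", "regression", lambda: LinearRegression()),
            LearnerSpec("svr_rbf", "regression", lambda: SVR(kernel="rbf")),
        ]
    raise InputError(f"task must be classification or regression, got {task!r}")


def correlated_ensemble_fixture(
    X=None,
    y=None,
    base_seed: int = 0,
    n_copies: int = 3,
    rho_threshold: float = 0.95,
    check_k: int = 5,
    **rf_params,
) -> list[LearnerSpec]:
    """Random-forest copies differing only in seed: a collinearity stress test.

    Returns ``n_copies`` classifiers with identical hyperparameters and
    distinct random seeds. Their out-of-fold prediction columns are nearly
    collinear (typically pairwise Spearman rho > 0.95), the regime in which
    linear stackers become unstable. If ``X`` and ``y`` are given, the
    pairwise rho of the OOF columns is measured with a ``check_k``-fold
    split and a warning (not an error — the value is data-dependent) is
    emitted if it falls at or below ``rho_threshold``.
    """
    if n_copies < 2:
        raise InputError(f"n_copies must be >= 2, got {n_copies}")
    from sklearn.ensemble import RandomForestClassifier

    params = {"n_estimators": 100, **rf_params}
    learners = [
        LearnerSpec(
            name=f"rf_seed{base_seed + k}",
            task="classification",
            build=lambda s=base_seed + k: RandomForestClassifier(random_state=s, **params),
        )
        for k in range(n_copies)
    ]
    if X is not None and y is not None:
        n = _n_rows(X)
        rng = np.random.default_rng(base_seed)
        fold_ids = rng.integers(0, check_k, size=n)
        Z = oof_prediction_matrix(learners, X, y, fold_ids, seed=base_seed)
        rhos = [
            spearman(Z[:, a], Z[:, b])
            for a in range(n_copies)
            for b in range(a + 1, n_copies)
        ]
        if min(rhos) <= rho_threshold:
            warnings.warn(
                f"minimum pairwise Spearman rho of OOF columns is {min(rhos):.3f}, "
                f"at or below the requested {rho_threshold}",
                stacklevel=2,
            )
    return learners
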