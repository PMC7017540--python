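"""Evaluation metrics under a single maximize/minimize contract.

Every weight-fitting routine in this package optimizes a
:class:`MetricSpec`: a named scalar function of ``(predicted, observed)``
together with an optimization direction. Routines always maximize the
*signed* score (:meth:`MetricSpec.signed`), which negates
minimize-direction metrics such as MAE, so a single argmax loop serves
all five metrics.

Tie conventions are fixed so results are exactly reproducible: AUROC
counts ties between a positive and a negative score as half a concordant
pair (the Mann-Whitney convention), AUPR is the step-curve area with no
interpolation between precision-recall points, and Spearman uses average
ranks for ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score

from greedystack.errors import InputError, UndefinedMetricError

__all__ = [
    "MetricSpec",
    "accuracy",
    "auroc",
    "aupr",
    "mae",
    "spearman",
    "get_metric",
    "METRICS",
]


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _check_lengths(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[0] != b.shape[0]:
        raise InputError(
            f"length mismatch: predicted has {a.shape[0]} entries, "
            f"observed has {b.shape[0]}"
        )
    if a.shape[0] < 1:
        raise InputError("sequences must contain at least one entry")


def _check_binary(observed: np.ndarray) -> None:
    if not np.all(np.isin(observed, (0.0, 1.0))):
        bad = np.unique(observed[~np.isin(observed, (0.0, 1.0))])
        raise InputError(f"observed must be binary 0/1; found values {bad}")


def accuracy(predicted, observed, threshold: float = 0.5) -> float:
    """Fraction of correct hard predictions after thresholding.

    ``predicted`` holds class-1 probabilities (or any scores on the
    threshold's scale); a prediction counts as class 1 when it is >= the
    threshold. The default threshold of 0.5 is the convention used for
    blended probability columns.
    """
    p = _as_1d(predicted, "predicted")
    y = _as_1d(observed, "observed")
    _check_lengths(p, y)
    _check_binary(y)
    if not 0.0 < threshold < 1.0:
        raise InputError(f"threshold must lie in (0, 1), got {threshold}")
    return float(np.mean((p >= threshold).astype(float) == y))


def auroc(scores, observed) -> float:
    """Area under the ROC curve via the Mann-Whitney U relation.

    Equals the probability that a randomly chosen positive receives a
    higher score than a randomly chosen negative, with ties counted as
    one half. Requires both classes to be present.
    """
    s = _as_1d(scores, "scores")
    y = _as_1d(observed, "observed")
    _check_lengths(s, y)
    _check_binary(y)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "AUROC is undefined when only one class is present "
            f"(positives={n_pos}, negatives={n_neg})"
        )
    ranks = stats.rankdata(s, method="average")
    u = float(np.sum(ranks[y == 1])) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def aupr(scores, observed) -> float:
    """Area under the precision-recall step curve.

    Computed as the average-precision sum ``sum_k (R_k - R_{k-1}) P_k``
    over descending score thresholds — the step-curve estimator, with no
    linear interpolation between PR points. Requires at least one
    positive.
    """
    s = _as_1d(scores, "scores")
    y = _as_1d(observed, "observed")
    _check_lengths(s, y)
    _check_binary(y)
    if np.sum(y == 1) == 0:
        raise UndefinedMetricError("AUPR is undefined without any positive observation")
    if np.sum(y == 0) == 0:
        # Precision is identically 1 whatever the threshold.
        return 1.0
    return float(average_precision_score(y, s))


def mae(predicted, observed) -> float:
    """Mean absolute error between prediction and observation."""
    p = _as_1d(predicted, "predicted")
    y = _as_1d(observed, "observed")
    _check_lengths(p, y)
    return float(np.mean(np.abs(p - y)))


def spearman(a, b) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Invariant to strictly monotone transforms of either argument.
    Undefined (raises) when either sequence is constant.
    """
    x = _as_1d(a, "a")
    y = _as_1d(b, "b")
    _check_lengths(x, y)
    if x.shape[0] < 2:
        raise InputError("spearman requires at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("spearman is undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class MetricSpec:
    """A named evaluation function with an optimization direction.

    ``evaluate(predicted, observed)`` returns a scalar; ``direction`` says
    whether larger is better. :meth:`signed` returns the score on a
    maximize-me scale so optimizers never need to branch on direction.
    """

    name: str
    direction: Literal["maximize", "minimize"]
    evaluate: Callable[[np.ndarray, np.ndarray], float] = field(repr=False)

    def signed(self, predicted, observed) -> float:
        value = self.evaluate(predicted, observed)
        return -value if self.direction == "minimize" else value

    def better(self, a: float, b: float) -> bool:
        """True if signed score ``a`` strictly beats signed score ``b``."""
        return a > b


METRICS: dict[str, MetricSpec] = {
    "accuracy": MetricSpec("accuracy", "maximize", accuracy),
    "auroc": MetricSpec("auroc", "maximize", auroc),
    "aupr": MetricSpec("aupr", "maximize", aupr),
    "mae": MetricSpec("mae", "minimize", mae),
    "spearman": MetricSpec("spearman", "maximize", spearman),
}


def get_metric(name: str) -> MetricSpec:
    """Look up a built-in metric by name (case-insensitive)."""
    try:
        return METRICS[name.lower()]
    except KeyError:
        raise InputError(
            f"unknown metric {name!r}; available: {', '.join(sorted(METRICS))}"
        ) from None
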