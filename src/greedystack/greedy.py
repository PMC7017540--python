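"""Greedy assignment of integer weight counts to columns of a prediction matrix.

The algorithm maintains an unnormalized accumulator ``P`` (the running sum of
chosen columns) and an integer count per column. At iteration ``i`` it
tentatively adds each column ``j`` to ``P``, normalizes by ``i``, scores the
candidate blend ``(P + Z[:, j]) / i`` against the outcome with the metric,
and permanently adds the best-scoring column, incrementing its count. After
``t`` iterations the counts divided by ``t`` form a simplex weight vector
whose entries are integer multiples of ``1/t`` — directly readable as
percentages when ``t = 100``.

Stopping is either a fixed iteration budget or a relative-distance
criterion: successive estimates differ by exactly one unit count, so with
the L1 norm the relative change is ``1 / i`` and the epsilon test reduces to
``1 <= epsilon * i`` — at the default ``epsilon = 0.01`` the loop stops at
exactly iteration 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from greedystack.errors import AlgorithmError, InputError, UndefinedMetricError
from greedystack.metrics import MetricSpec

__all__ = [
    "WeightVector",
    "StoppingRule",
    "GreedyState",
    "GreedyTrace",
    "TraceRecord",
    "blend",
    "convergence_reached",
    "greedy_weights",
]

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class WeightVector:
    """A point on the probability simplex with a record of which method made it.

    ``w`` holds ``d`` non-negative reals summing to 1 (within 1e-12);
    ``provenance`` names the producing method (``"greedy"``, ``"qp"``,
    ``"brute_force"``, ``"genetic"``, ...).
    """

    w: np.ndarray
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        arr = np.asarray(self.w, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise InputError(f"weights must be a non-empty 1-D vector, got shape {arr.shape}")
        if np.any(arr < -_SIMPLEX_TOL):
            raise InputError(f"weights must be non-negative, got {arr}")
        if abs(arr.sum() - 1.0) > _SIMPLEX_TOL:
            raise InputError(f"weights must sum to 1, got sum {arr.sum()!r}")
        object.__setattr__(self, "w", np.clip(arr, 0.0, None))

    def __len__(self) -> int:
        return self.w.size

    def __array__(self, dtype=None, copy=None):
        return np.array(self.w, dtype=dtype)

    def as_percentages(self) -> list[float]:
        """Weights on the 0-100 scale, for human-readable reporting."""
        return [round(100.0 * x, 6) for x in self.w]


@dataclass(frozen=True)
class StoppingRule:
    """When the greedy loop stops.

    ``fixed_iter`` runs exactly ``iter_`` iterations. ``epsilon_l1`` /
    ``epsilon_l2`` stop once the relative distance between successive count
    estimates falls to ``epsilon`` or below, measured in the L1 resp. L2
    norm. Because one iteration changes the counts by exactly one unit, the
    L1 test is ``1 <= epsilon * i`` (i = current total count) and the L2
    test is ``1 <= epsilon * ||counts_prev||_2``.
    """

    mode: Literal["fixed_iter", "epsilon_l1", "epsilon_l2"] = "fixed_iter"
    iter_: int = 100
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_iter", "epsilon_l1", "epsilon_l2"):
            raise InputError(f"unknown stopping mode {self.mode!r}")
        if self.iter_ < 1:
            raise InputError(f"iter must be >= 1, got {self.iter_}")
        if not 0.0 < self.epsilon < 1.0:
            raise InputError(f"epsilon must lie in (0, 1), got {self.epsilon}")


@dataclass
class GreedyState:
    """Internal loop state: accumulator P, per-column counts, total count t."""

    P: np.ndarray
    counts: np.ndarray
    t: int = 0


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    chosen_column: int
    metric_value: float
    counts: np.ndarray


@dataclass
class GreedyTrace:
    """Per-iteration diagnostics: chosen column, blend metric, counts snapshot."""

    metric_name: str
    records: list[TraceRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def metric_values(self) -> np.ndarray:
        return np.array([r.metric_value for r in self.records])

    def best_iteration(self, direction: str) -> TraceRecord:
        values = self.metric_values()
        signed = -values if direction == "minimize" else values
        return self.records[int(np.argmax(signed))]


def blend(w, Z) -> np.ndarray:
    """Weighted column combination ``sum_j w_j * Z[:, j]``."""
    weights = np.asarray(w, dtype=float)
    matrix = np.asarray(Z, dtype=float)
    if matrix.ndim != 2:
        raise InputError(f"Z must be a 2-D matrix, got shape {matrix.shape}")
    if weights.ndim != 1 or weights.size != matrix.shape[1]:
        raise InputError(
            f"weight length {weights.size} does not match "
            f"{matrix.shape[1]} columns of Z"
        )
    return matrix @ weights


def convergence_reached(
    state_prev_counts: Sequence[int],
    state_counts: Sequence[int],
    stop: StoppingRule,
) -> bool:
    """Whether the stopping rule fires after the step prev_counts -> counts.

    The two count vectors must differ by a single unit increment. For
    ``fixed_iter`` the rule fires once the total count reaches ``iter_``;
    the epsilon modes implement the relative-distance test described in the
    module docstring (non-strict, so epsilon = 0.01 under L1 fires at
    exactly i = 100).
    """
    prev = np.asarray(state_prev_counts, dtype=float)
    cur = np.asarray(state_counts, dtype=float)
    i = float(cur.sum())
    if i < 1:
        raise InputError("convergence is undefined before the first iteration")
    diff = cur - prev
    if not (np.sum(np.abs(diff)) == 1 and np.sum(diff) == 1):
        raise InputError("count vectors must differ by exactly one unit increment")
    if stop.mode == "fixed_iter":
        return i >= stop.iter_
    if stop.mode == "epsilon_l1":
        return 1.0 <= stop.epsilon * i
    # epsilon_l2: ||w_i - w_{i-1}||_2 = 1, compared to epsilon * ||w_{i-1}||_2.
    return 1.0 <= stop.epsilon * float(np.linalg.norm(prev, ord=2))


# Hard ceiling for epsilon-mode loops; generous — epsilon_l1 at the smallest
# allowed epsilon above 1e-6 stops far earlier.
_MAX_ITERATIONS = 1_000_000


def greedy_weights(
    Z,
    y,
    metric: MetricSpec,
    stop: StoppingRule | None = None,
    return_best: bool = False,
) -> tuple[WeightVector, GreedyTrace]:
    """Fit simplex weights by greedy unit-count assignment.

    Parameters
    ----------
    Z
        n x d matrix; one column per learner or index domain.
    y
        Outcome vector of length n.
    metric
        The :class:`~greedystack.metrics.MetricSpec` to optimize; its
        direction is handled internally.
    stop
        Stopping rule; defaults to 100 fixed iterations.
    return_best
        If true, return the counts snapshot of the iteration whose blend
        scored best (renormalized by its own total) instead of the final
        counts. Only this variant guarantees the returned blend is at
        least as good as the best single column on the fitting data.

    Returns
    -------
    (WeightVector, GreedyTrace)
        The fitted weights and the per-iteration trace.

    Notes
    -----
    Candidates on which the metric is undefined (e.g. a constant blend
    under Spearman) are skipped; if every candidate in an iteration is
    undefined an :class:`AlgorithmError` is raised. Argmax ties break to
    the lowest column index.
    """
    if stop is None:
        stop = StoppingRule()
    matrix = np.asarray(Z, dtype=float)
    outcome = np.asarray(y, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 1:
        raise InputError(f"Z must be a 2-D matrix with >= 1 column, got shape {matrix.shape}")
    n, d = matrix.shape
    if n < 2:
        raise InputError("Z must have at least 2 rows; no metric is meaningful on one observation")
    if outcome.shape != (n,):
        raise InputError(f"y must have length {n}, got shape {outcome.shape}")

    state = GreedyState(P=np.zeros(n), counts=np.zeros(d, dtype=np.int64), t=0)
    trace = GreedyTrace(metric_name=metric.name)
    max_iter = stop.iter_ if stop.mode == "fixed_iter" else _MAX_ITERATIONS

    while state.t < max_iter:
        i = state.t + 1
        best_j = -1
        best_signed = -np.inf
        best_value = np.nan
        for j in range(d):
            candidate = (state.P + matrix[:, j]) / i
            try:
                value = metric.evaluate(candidate, outcome)
            except UndefinedMetricError:
                continue
            signed = -value if metric.direction == "minimize" else value
            if signed > best_signed:  # ties keep the lowest column index
                best_signed = signed
                best_value = value
                best_j = j
        if best_j < 0:
            raise AlgorithmError(
                f"metric {metric.name!r} is undefined on every candidate blend "
                f"at iteration {i}"
            )
        prev_counts = state.counts.copy()
        state.P += matrix[:, best_j]
        state.counts[best_j] += 1
        state.t = i
        trace.records.append(
            TraceRecord(
                iteration=i,
                chosen_column=best_j,
                metric_value=float(best_value),
                counts=state.counts.copy(),
            )
        )
        if convergence_reached(prev_counts, state.counts, stop):
            break
    else:
        if stop.mode != "fixed_iter":
            raise AlgorithmError(
                f"epsilon stopping did not fire within {_MAX_ITERATIONS} iterations"
            )

    if return_best:
        record = trace.best_iteration(metric.direction)
        counts = record.counts
    else:
        counts = state.counts
    weights = counts / counts.sum()
    return WeightVector(weights, provenance="greedy"), trace
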