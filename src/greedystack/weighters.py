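"""Comparator weight-fitting methods: grid brute force, constrained QP, GA.

These are the three benchmarks the greedy method is measured against:

- an exhaustive sweep of every simplex weight vector on a fixed-step grid
  (step 0.01 gives the classic "weights as whole percentages" grid, whose
  size is the stars-and-bars count ``C(g + d - 1, d - 1)`` with ``g = 1/step``);
- simplex-constrained least squares solved as a quadratic program — the
  standard linear/super-learner stacker;
- a real-coded genetic algorithm evolving simplex points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import optimize

from greedystack.errors import AlgorithmError, InputError, ResourceError, UndefinedMetricError
from greedystack.greedy import WeightVector, blend
from greedystack.metrics import MetricSpec

__all__ = [
    "WeightGrid",
    "GAConfig",
    "count_weight_grid",
    "enumerate_weight_grid",
    "brute_force_weights",
    "qp_weights",
    "genetic_weights",
    "project_to_simplex",
]

#: Refuse to enumerate grids larger than this (the 7-column step-0.01 grid
#: has 1.7e9 points; counting it is instant, sweeping it is not).
DEFAULT_GRID_CAP = 10_000_000


def _granularity(step: float) -> int:
    if step <= 0:
        raise InputError(f"step must be positive, got {step}")
    g = round(1.0 / step)
    if g < 1 or abs(step * g - 1.0) > 1e-9:
        raise InputError(f"1/step must be an integer, got step={step}")
    return g


@dataclass(frozen=True)
class WeightGrid:
    """The simplex grid of step ``1/g`` over ``d`` components."""

    d: int
    step: float

    def __post_init__(self) -> None:
        if self.d < 1:
            raise InputError(f"d must be >= 1, got {self.d}")
        _granularity(self.step)

    @property
    def g(self) -> int:
        return _granularity(self.step)

    @property
    def size(self) -> int:
        return count_weight_grid(self.d, self.step)


def count_weight_grid(d: int, step: float) -> int:
    """Exact number of simplex weight vectors on the step-``step`` grid.

    Each grid point is a vector of ``d`` non-negative integer counts summing
    to ``g = 1/step``, so the count is the number of weak compositions of
    ``g`` into ``d`` parts: ``C(g + d - 1, d - 1)``. Closed form — instant at
    any size (e.g. 1,705,904,746 for ``d=7, step=0.01``).
    """
    if d < 1:
        raise InputError(f"d must be >= 1, got {d}")
    g = _granularity(step)
    return math.comb(g + d - 1, d - 1)


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    """All weak compositions of ``total`` into ``parts``, lexicographic."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first, *rest)


def enumerate_weight_grid(
    d: int, step: float, cap: int = DEFAULT_GRID_CAP
) -> Iterator[WeightVector]:
    """Yield every grid weight vector once, in lexicographic count order.

    Each yielded vector is an exact ratio of integer counts to the
    granularity ``g``, so it sums to 1 to machine precision. Raises
    :class:`ResourceError` if the grid exceeds ``cap`` points.
    """
    g = _granularity(step)
    size = count_weight_grid(d, step)
    if size > cap:
        raise ResourceError(
            f"grid for d={d}, step={step} has {size:,} points, over the cap of "
            f"{cap:,}; use a coarser step"
        )
    for counts in _compositions(g, d):
        yield WeightVector(np.array(counts, dtype=float) / g, provenance="grid")


def brute_force_weights(
    Z,
    y,
    metric: MetricSpec,
    step: float = 0.01,
    cap: int = DEFAULT_GRID_CAP,
) -> WeightVector:
    """Exhaustively search the weight grid for the metric-optimal blend.

    Evaluates the metric on the blend at every grid point and returns the
    first point attaining the best direction-signed score (ties keep the
    earliest point in enumeration order). This is the global optimum
    restricted to the grid; for fine steps and many columns it is
    combinatorially expensive, which is exactly the cost the greedy method
    avoids.
    """
    matrix = np.asarray(Z, dtype=float)
    outcome = np.asarray(y, dtype=float)
    if matrix.ndim != 2:
        raise InputError(f"Z must be 2-D, got shape {matrix.shape}")
    best: WeightVector | None = None
    best_signed = -np.inf
    for wv in enumerate_weight_grid(matrix.shape[1], step, cap=cap):
        try:
            signed = metric.signed(matrix @ wv.w, outcome)
        except UndefinedMetricError:
            continue
        if signed > best_signed:
            best_signed = signed
            best = wv
    if best is None:
        raise AlgorithmError(
            f"metric {metric.name!r} is undefined on every grid blend"
        )
    return WeightVector(best.w, provenance="brute_force")


_CLIP_TOL = 1e-9


def qp_weights(Z, y) -> WeightVector:
    """Simplex-constrained least squares: the linear (super-learner) stacker.

    Minimizes ``sum_i (y_i - sum_j beta_j Z_ij)^2`` subject to
    ``sum_j beta_j = 1`` and ``beta_j >= 0``. The problem is convex; with a
    rank-deficient ``Z`` the minimizer may be non-unique and one minimizer
    is returned. Solved with SLSQP followed by an exact KKT polish on the
    active support; components below 1e-9 are clipped to zero and the
    vector renormalized.
    """
    matrix = np.asarray(Z, dtype=float)
    outcome = np.asarray(y, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 1:
        raise InputError(f"Z must be 2-D with >= 1 column, got shape {matrix.shape}")
    n, d = matrix.shape
    if outcome.shape != (n,):
        raise InputError(f"y must have length {n}, got shape {outcome.shape}")
    if n < d:
        import warnings

        warnings.warn(
            f"fewer rows ({n}) than columns ({d}); the QP minimizer may be non-unique",
            stacklevel=2,
        )
    if d == 1:
        return WeightVector(np.ones(1), provenance="qp")

    gram = matrix.T @ matrix
    lin = matrix.T @ outcome

    def objective(b):
        r = matrix @ b - outcome
        return 0.5 * float(r @ r)

    def gradient(b):
        return gram @ b - lin

    x0 = np.full(d, 1.0 / d)
    res = optimize.minimize(
        objective,
        x0,
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * d,
        constraints=[{"type": "eq", "fun": lambda b: b.sum() - 1.0,
                      "jac": lambda b: np.ones(d)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success and res.status != 8:  # 8: positive directional derivative
        raise AlgorithmError(f"QP solver failed: {res.message} (status {res.status})")
    beta = np.clip(res.x, 0.0, None)

    # KKT polish: resolve the equality-constrained LS exactly on the support
    # found by SLSQP; accept only if it stays feasible and does not worsen
    # the objective.
    support = beta > 1e-7
    if support.sum() >= 1:
        zs = matrix[:, support]
        k = int(support.sum())
        kkt = np.zeros((k + 1, k + 1))
        kkt[:k, :k] = zs.T @ zs
        kkt[:k, k] = 1.0
        kkt[k, :k] = 1.0
        rhs = np.concatenate([zs.T @ outcome, [1.0]])
        try:
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
            cand = np.zeros(d)
            cand[support] = sol[:k]
            if np.all(cand >= -_CLIP_TOL) and objective(np.clip(cand, 0, None)) <= objective(beta) + 1e-12:
                beta = np.clip(cand, 0.0, None)
        except np.linalg.LinAlgError:
            pass

    beta[beta < _CLIP_TOL] = 0.0
    total = beta.sum()
    if total <= 0:
        raise AlgorithmError("QP produced an all-zero weight vector")
    return WeightVector(beta / total, provenance="qp")


def project_to_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of a real vector onto the probability simplex."""
    v = np.asarray(v, dtype=float)
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u + (1.0 - css) / np.arange(1, v.size + 1) > 0)[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.clip(v - theta, 0.0, None)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings; fully determines the run given the data."""

    population_size: int = 50
    generations: int = 100
    mutation_scale: float = 0.1
    crossover_rate: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise InputError(f"population_size must be >= 2, got {self.population_size}")
        if self.generations < 1:
            raise InputError(f"generations must be >= 1, got {self.generations}")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise InputError(f"crossover_rate must lie in [0, 1], got {self.crossover_rate}")


def genetic_weights(
    Z,
    y,
    metric: MetricSpec,
    config: GAConfig | None = None,
    return_history: bool = False,
):
    """Evolve simplex weights with a real-coded genetic algorithm.

    A conventional reference design: Dirichlet-initialized population,
    tournament selection (size 2), arithmetic blend crossover, Gaussian
    mutation followed by Euclidean projection back onto the simplex, and
    elitism of one (the best-ever individual survives every generation, so
    the best fitness is monotone non-decreasing). Fully reproducible from
    ``config.seed``.

    Returns the best-ever :class:`WeightVector`; with ``return_history``
    also the per-generation best signed fitness.
    """
    if config is None:
        config = GAConfig()
    matrix = np.asarray(Z, dtype=float)
    outcome = np.asarray(y, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] < 1:
        raise InputError(f"Z must be 2-D with >= 1 column, got shape {matrix.shape}")
    d = matrix.shape[1]
    rng = np.random.default_rng(config.seed)

    def fitness(w: np.ndarray) -> float:
        try:
            return metric.signed(matrix @ w, outcome)
        except UndefinedMetricError:
            return -np.inf

    def init_population() -> np.ndarray:
        return rng.dirichlet(np.ones(d), size=config.population_size)

    pop = init_population()
    if d > 1 and np.allclose(pop, pop[0]):
        pop = init_population()
        if np.allclose(pop, pop[0]):
            raise AlgorithmError("degenerate GA population after reseeding")
    fit = np.array([fitness(w) for w in pop])
    if not np.any(np.isfinite(fit)):
        raise AlgorithmError(
            f"metric {metric.name!r} is undefined on every initial blend"
        )

    best_idx = int(np.argmax(fit))
    best_w = pop[best_idx].copy()
    best_fit = float(fit[best_idx])
    history = [best_fit]

    for _ in range(config.generations):
        children = np.empty_like(pop)
        for c in range(config.population_size):
            i1, i2 = rng.integers(config.population_size, size=2)
            p1 = pop[i1] if fit[i1] >= fit[i2] else pop[i2]
            i3, i4 = rng.integers(config.population_size, size=2)
            p2 = pop[i3] if fit[i3] >= fit[i4] else pop[i4]
            if rng.random() < config.crossover_rate:
                alpha = rng.random()
                child = alpha * p1 + (1.0 - alpha) * p2
            else:
                child = p1.copy()
            child = child + rng.normal(0.0, config.mutation_scale, size=d)
            children[c] = project_to_simplex(child)
        pop = children
        fit = np.array([fitness(w) for w in pop])
        # elitism: the best-ever individual replaces the current worst
        worst = int(np.argmin(fit))
        pop[worst] = best_w
        fit[worst] = best_fit
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_fit = float(fit[gen_best])
            best_w = pop[gen_best].copy()
        history.append(best_fit)

    result = WeightVector(best_w / best_w.sum(), provenance="genetic")
    if return_history:
        return result, np.array(history)
    return result
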