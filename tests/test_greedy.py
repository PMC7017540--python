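"""Greedy weight assignment: examples, stopping rules, and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greedystack.errors import InputError
from greedystack.greedy import (
    StoppingRule,
    WeightVector,
    blend,
    convergence_reached,
    greedy_weights,
)
from greedystack.metrics import get_metric

MAE = get_metric("mae")
SPEARMAN = get_metric("spearman")


def composition_optimum(Z, y, metric, total):
    """Oracle: best direction-signed metric over all count compositions.

    Enumerates every way of writing ``total`` as ordered non-negative
    integer counts over the columns, scores each normalized blend directly,
    and returns the best signed score. Independent of the package's grid
    enumeration.
    """
    d = Z.shape[1]
    best = -np.inf
    for cuts in itertools.combinations(range(total + d - 1), d - 1):
        counts = np.diff([-1, *cuts, total + d - 1]) - 1
        w = counts / total
        best = max(best, metric.signed(Z @ w, y))
    return best


class TestWeightVector:
    def test_validates_simplex(self):
        with pytest.raises(InputError):
            WeightVector(np.array([0.5, 0.6]))
        with pytest.raises(InputError):
            WeightVector(np.array([1.5, -0.5]))

    def test_percentages_view(self):
        wv = WeightVector(np.array([0.25, 0.75]))
        assert wv.as_percentages() == [25.0, 75.0]


class TestBlend:
    def test_unit_vector_selects_column(self, rng):
        Z = rng.normal(size=(10, 3))
        assert np.allclose(blend([0, 1, 0], Z), Z[:, 1])

    def test_uniform_is_rowwise_mean(self, rng):
        Z = rng.normal(size=(10, 4))
        assert np.allclose(blend(np.full(4, 0.25), Z), Z.mean(axis=1))

    def test_linearity(self, rng):
        Z = rng.normal(size=(8, 3))
        w1 = np.array([0.2, 0.3, 0.5])
        w2 = np.array([0.6, 0.1, 0.3])
        for alpha in (0.0, 0.25, 1.0):
            lhs = blend(alpha * w1 + (1 - alpha) * w2, Z)
            rhs = alpha * blend(w1, Z) + (1 - alpha) * blend(w2, Z)
            assert np.allclose(lhs, rhs)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(InputError):
            blend([0.5, 0.5], rng.normal(size=(5, 3)))


class TestConvergence:
    def test_l1_criterion_fires_exactly_at_one_over_epsilon(self):
        # with epsilon = 0.01 the loop aborts at exactly iteration 100
        stop = StoppingRule("epsilon_l1", epsilon=0.01)
        for i in range(1, 100):
            prev = np.array([i - 1, 0])
            assert not convergence_reached(prev, prev + [1, 0], stop)
        prev = np.array([99, 0])
        assert convergence_reached(prev, [100, 0], stop)

    def test_l1_coarse_epsilon(self):
        stop = StoppingRule("epsilon_l1", epsilon=0.5)
        assert not convergence_reached([0, 0], [1, 0], stop)
        assert convergence_reached([1, 0], [2, 0], stop)

    def test_l2_single_column_fires_at_101(self):
        # prev counts all on one column: ||prev||_2 = i - 1, so the test
        # 1 <= 0.01 * (i - 1) first holds at i = 101
        stop = StoppingRule("epsilon_l2", epsilon=0.01)
        assert not convergence_reached([99, 0], [100, 0], stop)
        assert convergence_reached([100, 0], [101, 0], stop)

    def test_fixed_iter(self):
        stop = StoppingRule("fixed_iter", iter_=3)
        assert not convergence_reached([1, 0], [2, 0], stop)
        assert convergence_reached([2, 0], [3, 0], stop)

    def test_requires_unit_increment(self):
        with pytest.raises(InputError):
            convergence_reached([0, 0], [2, 0], StoppingRule())
        with pytest.raises(InputError):
            convergence_reached([0, 0], [0, 0], StoppingRule())

    def test_bad_rule_parameters(self):
        with pytest.raises(InputError):
            StoppingRule(epsilon=1.5)
        with pytest.raises(InputError):
            StoppingRule(iter_=0)


class TestGreedyWeights:
    def test_single_column_gets_all_weight(self, rng):
        Z = rng.normal(size=(20, 1))
        w, _ = greedy_weights(Z, rng.normal(size=20), MAE, StoppingRule(iter_=5))
        assert np.allclose(w.w, [1.0])

    def test_perfect_column_absorbs_everything(self, rng):
        y = rng.normal(size=30)
        Z = np.column_stack([y, rng.normal(size=30), rng.normal(size=30)])
        w, trace = greedy_weights(Z, y, MAE, StoppingRule(iter_=100))
        assert np.allclose(w.w, [1.0, 0.0, 0.0])
        assert all(r.chosen_column == 0 for r in trace)

    def test_first_iteration_is_best_single_column(self, rng):
        Z = rng.normal(size=(50, 3))
        y = Z @ np.array([0.6, 0.3, 0.1]) + rng.normal(0, 0.3, size=50)
        _, trace = greedy_weights(Z, y, SPEARMAN, StoppingRule(iter_=10))
        singles = [SPEARMAN.evaluate(Z[:, j], y) for j in range(3)]
        assert trace.records[0].chosen_column == int(np.argmax(singles))
        assert trace.records[0].metric_value == pytest.approx(max(singles))

    def test_epsilon_l1_default_runs_100_iterations(self, rng):
        Z = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        _, trace = greedy_weights(Z, y, MAE, StoppingRule("epsilon_l1", epsilon=0.01))
        assert len(trace) == 100

    def test_bounded_by_composition_oracle(self, rng):
        Z = rng.normal(size=(50, 3))
        y = Z @ np.array([0.5, 0.25, 0.25]) + rng.normal(0, 0.2, size=50)
        t = 10
        w, trace = greedy_weights(Z, y, SPEARMAN, StoppingRule(iter_=t))
        greedy_score = SPEARMAN.signed(Z @ w.w, y)
        assert greedy_score <= composition_optimum(Z, y, SPEARMAN, t) + 1e-12

    def test_weights_are_count_multiples(self, rng):
        t = 17
        Z = rng.normal(size=(40, 4))
        w, _ = greedy_weights(Z, rng.normal(size=40), MAE, StoppingRule(iter_=t))
        counts = w.w * t
        assert np.allclose(counts, np.round(counts))
        assert counts.sum() == pytest.approx(t)

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.normal(size=(30, 4))
        y = Z @ np.array([0.4, 0.3, 0.2, 0.1]) + rng.normal(0, 0.1, size=30)
        perm = rng.permutation(4)
        w, _ = greedy_weights(Z, y, MAE, StoppingRule(iter_=12))
        w_perm, _ = greedy_weights(Z[:, perm], y, MAE, StoppingRule(iter_=12))
        assert np.allclose(w.w[perm], w_perm.w)

    def test_path_determinism_split_run(self, rng):
        Z = rng.normal(size=(40, 3))
        y = Z @ np.array([0.5, 0.3, 0.2]) + rng.normal(0, 0.2, size=40)
        _, trace_full = greedy_weights(Z, y, MAE, StoppingRule(iter_=20))
        _, trace_short = greedy_weights(Z, y, MAE, StoppingRule(iter_=8))
        full_choices = [r.chosen_column for r in trace_full]
        assert [r.chosen_column for r in trace_short] == full_choices[:8]

    def test_return_best_dominates_single_columns(self, rng):
        Z = rng.normal(size=(60, 3))
        y = Z @ np.array([0.2, 0.5, 0.3]) + rng.normal(0, 0.5, size=60)
        w, _ = greedy_weights(Z, y, SPEARMAN, StoppingRule(iter_=100), return_best=True)
        stacked = SPEARMAN.evaluate(Z @ w.w, y)
        singles = [SPEARMAN.evaluate(Z[:, j], y) for j in range(3)]
        assert stacked >= max(singles) - 1e-12

    def test_undefined_candidates_are_skipped(self, rng):
        # a constant column is undefined under spearman but must not halt the sweep
        y = np.arange(20.0)
        Z = np.column_stack([np.ones(20), y + rng.normal(0, 0.1, size=20)])
        w, _ = greedy_weights(Z, y, SPEARMAN, StoppingRule(iter_=5))
        assert w.w[1] > 0

    def test_rejects_degenerate_input(self, rng):
        with pytest.raises(InputError):
            greedy_weights(np.ones((1, 2)), [1.0], MAE)
        with pytest.raises(InputError):
            greedy_weights(rng.normal(size=(5, 2)), np.ones(4), MAE)
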