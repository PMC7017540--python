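import numpy as np
import pytest

from greedystack.stacking import LearnerSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


class _MeanModel:
    """Memorizes the training-outcome mean and predicts it everywhere."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        n = X.shape[0] if hasattr(X, "shape") else len(X)
        return np.full(n, self.mean_)


@pytest.fixture
def mean_learner():
    return LearnerSpec("train_mean", "regression", _MeanModel)


class _ConstantModel:
    def __init__(self, c):
        self.c = c

    def fit(self, X, y):
        return self

    def predict(self, X):
        n = X.shape[0] if hasattr(X, "shape") else len(X)
        return np.full(n, self.c)


@pytest.fixture
def constant_learner():
    return LearnerSpec("const", "regression", lambda: _ConstantModel(0.7))
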