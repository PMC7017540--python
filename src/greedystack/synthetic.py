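"""Synthetic fixtures with known ground truth for every weighting scenario.

Three generators, all pure functions of their spec (seed included):

- a regression ensemble where the outcome is a known simplex blend of the
  prediction columns plus Gaussian noise — weight recovery is checkable;
- a binary-classification ensemble of probability columns sharing a latent
  signal — separability controls each column's AUROC;
- a composite-deprivation-index scenario: positively skewed domain scores
  for a set of districts and a mortality-ratio outcome that is a noisy
  monotone transform of a hidden weighted blend, so rank-correlation
  weighting can approximately recover the hidden weights.

Correlation between columns is induced by a single shared latent factor:
each column is ``sqrt(c) * factor + sqrt(1 - c) * noise``, giving pairwise
(Pearson) correlation ``c`` with one knob.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from greedystack.errors import InputError
from greedystack.greedy import WeightVector

__all__ = [
    "RegressionEnsembleSpec",
    "GimdLikeSpec",
    "make_regression_ensemble",
    "make_classification_ensemble",
    "make_gimd_like",
]


def _correlated_columns(rng: np.random.Generator, n: int, d: int, c: float) -> np.ndarray:
    factor = rng.standard_normal(n)
    noise = rng.standard_normal((n, d))
    return np.sqrt(c) * factor[:, None] + np.sqrt(1.0 - c) * noise


@dataclass(frozen=True)
class RegressionEnsembleSpec:
    """Settings for :func:`make_regression_ensemble`."""

    n: int = 200
    d: int = 3
    true_w: tuple[float, ...] = (0.5, 0.3, 0.2)
    noise_sd: float = 0.1
    column_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2 or self.d < 1:
            raise InputError("need n >= 2 rows and d >= 1 columns")
        if len(self.true_w) != self.d:
            raise InputError(f"true_w must have length d={self.d}")
        WeightVector(np.asarray(self.true_w))  # validates simplex
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if not 0.0 <= self.column_correlation < 1.0:
            raise InputError("column_correlation must lie in [0, 1)")


def make_regression_ensemble(
    spec: RegressionEnsembleSpec,
) -> tuple[np.ndarray, np.ndarray, WeightVector]:
    """Draw (Z, y, true_w) with ``y = Z @ true_w + N(0, noise_sd)``.

    At ``noise_sd = 0`` the simplex-constrained least-squares fit recovers
    ``true_w`` exactly (zero residual); at ``column_correlation`` near 1
    the columns enter the near-collinear regime (pairwise Spearman rho
    above 0.95) that destabilizes unconstrained linear stackers.
    """
    rng = np.random.default_rng(spec.seed)
    Z = _correlated_columns(rng, spec.n, spec.d, spec.column_correlation)
    true_w = WeightVector(np.asarray(spec.true_w, dtype=float), provenance="truth")
    y = Z @ true_w.w + rng.normal(0.0, spec.noise_sd, size=spec.n) if spec.noise_sd > 0 else Z @ true_w.w
    return Z, y, true_w


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def make_classification_ensemble(
    n: int = 500,
    d: int = 3,
    separability: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw binary ``y`` and ``d`` probability columns sharing a signal.

    Each column's logit is ``separability * (2y - 1)`` plus independent
    unit noise, then squashed to [0, 1]. At ``separability = 0`` every
    column is pure noise (AUROC about 0.5); as it grows each column's
    AUROC approaches 1. Resamples ``y`` until both classes are present.
    """
    if n < 10:
        raise InputError(f"n must be >= 10, got {n}")
    if d < 1:
        raise InputError(f"d must be >= 1, got {d}")
    if separability < 0:
        raise InputError("separability must be >= 0")
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    while y.min() == y.max():
        y = rng.integers(0, 2, size=n)
    signal = separability * (2.0 * y - 1.0)
    logits = signal[:, None] + rng.standard_normal((n, d))
    return _sigmoid(logits), y.astype(float)


@dataclass(frozen=True)
class GimdLikeSpec:
    """Settings for :func:`make_gimd_like`.

    Defaults mirror the structure of an area-level multiple-deprivation
    index: 412 districts scored on 7 deprivation domains (income,
    employment, education, ...), with income and employment carrying the
    largest hidden weights — the ordering such indices conventionally use.
    The outcome plays the role of a standardized mortality ratio (SMR):
    a noisy, exponentiated (hence monotone, rank-preserving) transform of
    the hidden weighted domain blend.
    """

    n_districts: int = 412
    n_domains: int = 7
    hidden_w: tuple[float, ...] = (0.25, 0.25, 0.15, 0.10, 0.10, 0.10, 0.05)
    outcome_noise: float = 0.1
    domain_correlation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_districts < 2 or self.n_domains < 1:
            raise InputError("need n_districts >= 2 and n_domains >= 1")
        if len(self.hidden_w) != self.n_domains:
            raise InputError(f"hidden_w must have length n_domains={self.n_domains}")
        WeightVector(np.asarray(self.hidden_w))
        if self.outcome_noise < 0:
            raise InputError("outcome_noise must be >= 0")
        if not 0.0 <= self.domain_correlation < 1.0:
            raise InputError("domain_correlation must lie in [0, 1)")


def make_gimd_like(spec: GimdLikeSpec) -> tuple[np.ndarray, np.ndarray, WeightVector]:
    """Draw (domains, smr, hidden_w): a deprivation-index weighting scenario.

    Domain scores are positively skewed (exponentiated correlated normals,
    like real deprivation-domain scores, which are non-negative with a
    long right tail). The SMR outcome is
    ``exp(standardized(domains @ hidden_w) * 0.3 + noise)``: an increasing
    transform of the hidden blend, so at ``outcome_noise = 0`` the blend's
    Spearman correlation with the outcome is exactly 1 and the best
    attainable rank correlation degrades smoothly as noise grows.
    """
    rng = np.random.default_rng(spec.seed)
    latent = _correlated_columns(rng, spec.n_districts, spec.n_domains, spec.domain_correlation)
    domains = np.exp(0.5 * latent)  # positive, right-skewed scores
    hidden_w = WeightVector(np.asarray(spec.hidden_w, dtype=float), provenance="hidden")
    index = domains @ hidden_w.w
    z = (index - index.mean()) / index.std()
    noise = rng.normal(0.0, spec.outcome_noise, size=spec.n_districts) if spec.outcome_noise > 0 else 0.0
    smr = np.exp(0.3 * z + noise)
    return domains, smr, hidden_w
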