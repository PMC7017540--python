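# Methods

## Model and notation

All weighters operate on the same objects: an `n × d` column matrix `Z`
(out-of-fold predictions of `d` learners, or `d` domain scores of a
composite index), an outcome `y` of length `n`, and a metric — a scalar
function of `(predicted, observed)` with a declared direction. A weight
vector lives on the probability simplex (`w_j ≥ 0`, `Σ w_j = 1`, enforced
to 1e−12) and the fitted prediction is the blend `Z w`. Optimizers always
maximize the direction-signed score, so MAE is negated internally and no
algorithm branches on direction.

## Metrics and tie conventions

- **accuracy(p, y, threshold=0.5)** — fraction of positions where
  `p ≥ threshold` equals `y`. Blended probability columns are continuous,
  so a dichotomization rule is needed; 0.5 is the fixed default.
- **AUROC** — computed from average ranks via the Mann–Whitney U relation;
  a tie between a positive and a negative counts one half. Undefined
  (raises) with a single observed class.
- **AUPR** — the step-curve area `Σ_k (R_k − R_{k−1}) P_k` (average
  precision); linear interpolation between PR points is deliberately not
  used because it is optimistically biased. Undefined without positives;
  defined as 1 when there are no negatives.
- **MAE** — mean absolute error; direction `minimize`.
- **Spearman ρ** — Pearson correlation of average ranks; undefined for a
  constant sequence.

In classification stacking the blended columns are class-1 probabilities,
not hard labels: blending labels is lossy and AUROC/AUPR need scores. The
alternative (majority-vote label blending before accuracy) is not offered.

## Greedy weighting

State: accumulator `P` (unnormalized sum of chosen columns), integer
counts `c`, total `t`. Iteration `i` scores `(P + Z_:,j)/i` for each `j`
and commits the argmax. Choices fixed for reproducibility:

- **Tie-break**: lowest column index wins. This makes the algorithm
  deterministic and permutation-equivariant (permuting columns permutes
  the weights), both property-tested.
- **Stopping**: `fixed_iter` (default 100), or a relative-distance rule in
  L1 or L2 norm. Successive estimates differ by exactly one unit count, so
  the L1 test is `1 ≤ ε·i` with the norm taken at the current step —
  non-strict, so `ε = 0.01` stops at exactly iteration 100. The strict
  variant (`1 < ε·i`) would stop one iteration later; the non-strict
  convention is pinned because "weights as whole percentages at the
  default settings" is the behavior users expect and tests freeze. The L2
  rule compares against the previous estimate's norm,
  `1 ≤ ε·‖c_{i−1}‖₂`.
- **Undefined candidates** (e.g. a constant blend under Spearman) are
  skipped rather than raised, since one degenerate candidate should not
  halt the sweep; if every candidate is undefined the iteration errors.
- **`return_best`** (off by default): return the counts snapshot of the
  best-scoring iteration instead of the final one. Only this variant
  guarantees the blend is at least as good as the best single column on
  the fitting data — iteration 1 always picks the best single column, and
  the best-over-iterations score can only match or improve on it. The
  guarantee is about the fitting data; held-out performance can still
  trail the best single learner.
- Inputs with one row are rejected: no metric in scope is meaningful on a
  single observation.

## Comparators

**Grid brute force.** The step-`s` simplex grid is the set of vectors
`c/g` with integer counts summing to `g = 1/s`; its size is the
stars-and-bars count `C(g + d − 1, d − 1)`, computed in closed form at any
size. Enumeration is lexicographic in the count vectors (a fixed order
makes tie behavior testable), each vector formed as an exact integer
ratio. A safety cap (default 10⁷ points) refuses sweeps that would take
hours — the 7-column step-0.01 grid alone has 1.7 × 10⁹ points — while
the count remains instant. The optimum keeps the first best point in
enumeration order; correctness is defined by this naive full evaluation.

**Constrained QP.** `min ‖y − Zβ‖²` s.t. `Σβ = 1, β ≥ 0`, the standard
super-learner weighting. The non-negativity constraint is the closed
simplex: a strict `β > 0` constraint admits no attainable boundary
optimum, and boundary solutions (a learner weighted exactly zero) are
meaningful. Solved with SLSQP (analytic gradient, ftol 1e−14), then
polished by solving the equality-constrained KKT system exactly on the
active support; the polish is accepted only if feasible and not worse.
Weights below 1e−9 are clipped to zero and the vector renormalized. With
rank-deficient `Z` the problem stays convex and one (possibly non-unique)
minimizer is returned; fewer rows than columns triggers a warning.

**Genetic algorithm.** A conventional real-coded reference design, not a
reproduction of any published variant: Dirichlet(1) initial population,
tournament selection of size 2, arithmetic (blend) crossover with rate
0.9, Gaussian mutation (scale 0.1) followed by Euclidean projection back
onto the simplex, elitism of one via best-ever reinsertion, fully
reproducible from the config seed. Its role is a sanity comparator that
produces valid simplex weights close to greedy/QP on easy landscapes;
population 50 × 100 generations is enough for the scales used here.

## Nested cross-validation harness

Outer k-fold (default 5, shuffled, stratified for classification to avoid
single-class folds) for reporting; inner k-fold (default 5) inside each
outer training set to build the out-of-fold matrix `Z` and fit the
weights. The base learners are then refit on the full outer training set,
their outer-test predictions blended with the inner-fitted weights, and
the metric recorded per fold; the reported value is the across-fold mean.
Refitting on the full outer-training set (rather than reusing inner-fold
models) is the standard super-learner convention. A fold where the metric
is undefined is flagged, excluded from the mean, and warned about. The
whole pipeline is a pure function of (data, plan, seeds) for
deterministic learners, verified bit-for-bit in tests; an instrumented
learner that records its training rows verifies that no prediction in `Z`
or on an outer test fold ever comes from a model that saw that row.

## Synthetic generators

All generators are pure functions of their spec, seed included.
Correlated columns come from one shared latent factor:
`sqrt(c)·f + sqrt(1−c)·noise` gives pairwise correlation `c` with a
single knob; `c = 0.99` lands the pairwise Spearman ρ of the columns
above 0.95, the stress regime for linear stacking.

- **Regression ensemble** (default n=200, d=3, true_w=(0.5, 0.3, 0.2),
  noise_sd=0.1): `y = Z·w* + N(0, σ)`. At σ = 0 the QP recovers `w*` to
  below 1e−6 (zero-residual recovery); recovery error grows monotonically
  with σ, checked at three noise levels.
- **Classification ensemble** (default n=500, d=3, separability=1):
  columns are `sigmoid(separability·(2y−1) + N(0,1))`. Separability 0
  gives AUROC ≈ 0.5 per column; large separability drives it to 1. `y` is
  resampled if a class is missing.
- **Deprivation-index scenario** (default 412 districts × 7 domains):
  domain scores are exponentiated correlated normals — positive and
  right-skewed like real deprivation-domain scores — and the
  mortality-ratio outcome is `exp(0.3·standardized(domains·w_hidden) +
  N(0, outcome_noise))`. The exponential keeps the transform monotone, so
  ranks are preserved: at zero noise the hidden blend's Spearman ρ with
  the outcome is exactly 1, and rank-based greedy weighting can exploit
  structure that the squared-error QP objective does not target. The
  hidden weights default to (0.25, 0.25, 0.15, 0.10, 0.10, 0.10, 0.05) —
  income and employment heaviest, the ordering conventional for
  multiple-deprivation indices — and outcome_noise to 0.1, chosen once as
  a realistic signal level (best attainable ρ around 0.93–0.95).

What the generators do *not* emulate: real learners' correlated errors,
the actual distributions of any published deprivation index or mortality
data, geographic autocorrelation, class imbalance pathologies. Passing
tests show the algorithms are implemented correctly and behave as the
theory predicts on clean structure, not that any particular real-data
ranking of methods will reproduce.

## Numerical choices and limitations

- Simplex membership is enforced at 1e−12; QP zero-clipping at 1e−9;
  exact-recovery assertions at 1e−6.
- Problem sizes throughout tests and examples (n ≤ 500, d ≤ 7, greedy
  t ≤ 100, brute-force grids ≤ 5,151 points) keep every run in seconds;
  they are the scales at which the guarantees are exactly checkable (the
  composition-enumeration oracle is exhaustive up to d=4, g=12).
- Multi-class tasks are out of scope: a single weighting column per
  learner has no canonical encoding of a k-class prediction. Missing
  values in input tables are a hard error, not imputed. The brute-force
  sweep is single-process by design; the count function tells you when a
  sweep is not worth launching.
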