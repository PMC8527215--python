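# Methods

## The task as a budget problem

Each trial of the multi-attribute visual choice (MAVC) task shows an
exemplar cube with an orientation on the X- and Y-axis, then — after a
retention interval (RI) of 0–30 s — five candidate cubes, and asks which is
most similar to the remembered exemplar.  The candidates are built as a
linear budget problem: a budget of `m = 100` tokens, per-axis token prices
`p_x`, `p_y` (one drawn uniformly from [1, 3], the other from [1, 10], the
assignment of ranges to axes a fair coin per trial), and five options at
fractions {0, ¼, ½, ¾, 1} of the X-intercept of the budget line
`x·p = m`.  A token buys 0.3° of rotation toward the exemplar on its axis;
0 tokens means a 30° offset, 100 tokens an exact match.  Because every
option exhausts the budget, no option dominates: the task forces a trade-off
between X- and Y-similarity, which is what makes revealed-preference
machinery applicable.

Prices are **continuous** uniform by default.  The source description of the
price draw is ambiguous between continuous and integer sampling; an
`integer` switch exists on all generators for sensitivity analysis.  Under
the defaults, the random-chooser benchmark (below) reproduces the published
simulation summaries closely but not exactly; the integer variant trades
which summary statistics match best, so neither convention can be singled
out after the fact.

## Consistency scoring

For a block of `n` chosen bundles, `C[i, j] = x_j · p_i` is the cost of
bundle `j` at trial `i`'s prices.  Bundle `x_i` is *directly revealed
preferred* to `x_j` (written `x_i R_D x_j`) when `C[i, j] ≤ m_i` and the
bundles differ; the relation is *strict* (`P_D`) when the inequality is
strict.  `R` is the transitive closure of `R_D` (computed by repeated
boolean squaring).  GARP requires that `x_i R x_j` never coexist with
`x_j P_D x_i`.

* **CCEI** — the supremum of deflation factors `e ∈ [0, 1]` such that the
  relations built from deflated budgets (`C[i, j] ≤ e·m_i`, strict side
  `< e·m_i`) satisfy GARP.  Violations grow monotonically with `e`, so
  binary search (default tolerance 1e-6) is valid; an exact
  breakpoint-enumeration oracle over the candidate set `{C[i, j]/m_i}`
  cross-checks it in the test suite.  A `paper-literal` variant deflates
  only the strict comparison while keeping relations at full budgets, which
  yields systematically lower values; both are exposed because the two
  formulations circulate in the literature.
* **Houtman–Maks** — minimal number of observations to drop for GARP
  consistency.  Exact by iterative deepening over the observations involved
  in violations; above a configurable node budget a greedy fallback runs and
  the result is flagged inexact.
* **Money pump** — mean, over simple violating cycles of length ≤ 3
  (configurable), of the expenditure fraction an arbitrageur could extract:
  `Σ(x_k·p_k − x_{k+1}·p_k) / Σ x_k·p_k` around the cycle.
* **Minimum cost** — each relation carries weight `(m_i − C[i, j])/m_i`;
  the index is the minimum total weight of relations whose removal breaks
  every violating cycle, divided by `n`, solved by branch-and-bound on
  violating cycles with a greedy seed.

Numerical choices: affordability comparisons use an absolute tolerance of
1e-9 (knife-edge equality counts as affordable, never as strictly cheaper);
bundles within 1e-12 sup-norm are treated as identical and hence mutually
unrelated; all indices are invariant to observation reordering and to joint
rescaling of `(p_i, m_i)`.

## Synthetic participants

The generators define the study conditions used throughout the tests:

* **Random choosers** (the task-sensitivity benchmark): uniform over the
  five options, 1000 participants × 20 trials.  This reproduces the
  published design check that random behaviour is detectably inconsistent
  (≈99–100% of simulated participants violate GARP, median CCEI ≈ 0.39–0.41,
  median of 16–17 choices involved in violations).
* **Utility choosers** (test harness): argmax of `w·x + (1−w)·y`, optionally
  plus Gumbel noise (the logit discrete-choice form; Gaussian would work as
  well but Gumbel is the standard), or of a CES aggregator.  Noiseless
  monotone maximizers must score CCEI = 1 (Afriat's theorem direction), a
  property test of the whole scoring stack.
* **Forgetting-curve data**: `t ~ U(0, 30)`, `CCEI ~ N(μ_t, σ)` truncated to
  [0, 1] with `μ_t = a + (1−a)·b·e^(−αt)`; demonstration defaults
  a = 0.4, b = 0.9, α = 0.3, σ = 0.1, n = 300.
* **Reconstruction responses**: a mixture of a point mass of exact reports
  (probability falling in the RI, rising in presentation time; calibrated so
  the mean rate at the 5 s presentation-time setting over the RI grid
  {1, 5, 10, 30} s is 42%) and half-normal error magnitudes with random
  sign, wrapped to [0, 360), scale `(5 + 1.2·t)·(5/pt)^0.3` degrees.  The
  observed features this mimics are the point mass, strong positive skew
  and the two monotone trends; real response distributions (e.g. swap
  errors, oblique biases) are not modelled, so passing tests certify the
  pipeline's arithmetic, not human behaviour.

All generators are deterministic given a seed; identical seeds produce
byte-identical CSVs.

## Forgetting-model comparison

Both models share a truncated-normal observation model on [0, 1] and
uniform Beta(1, 1) priors on all parameters; the exponential model's mean is
`a + (1−a)·b·e^(−αt)`, the null model's a constant `c`.  Truncation is
applied to both models alike for comparability (the null model's truncation
is explicit in its definition; the exponential model's is assumed shared).

`BF10` is estimated by the product-space (Carlin–Chib) method: a
transdimensional chain over the model indicator and both parameter vectors,
with pseudo-priors for the inactive model moment-matched as independent
Beta distributions to pilot single-model posteriors.  The reported estimate
is the Rao-Blackwellized average of the conditional model probabilities
(numerically stable to BF ~ 1e300 because both conditional probabilities
are computed directly in log space); raw indicator counts and pilot
convergence go to the diagnostics, and the Monte-Carlo error is a batch-means
standard error of log BF.

Sampling is adaptive random-walk Metropolis over the unit hypercube: 4
chains, isotropic Gaussian proposals whose scale tracks a 0.234 acceptance
target during warm-up, with the proposal correlation structure learned
midway through warm-up from pooled chain history.  Defaults are 10 000
draws after 2 000 warm-up; split-R̂ above 1.01 triggers a warning.  For the
weakly identified exponential model on null-like data (a ridge along
`α ≈ 0`), R̂ for the ridge parameters can stay above 1.01 at short chain
lengths; the Bayes factor estimate is nevertheless stable (checked against
quadrature).

The independent oracle integrates the likelihood directly: with uniform
priors the marginal likelihood is `∫ L dθ` over the hypercube, evaluated on
a Gauss–Legendre tensor grid concentrated on ±8 Laplace standard deviations
around the posterior mode, with a coarser-grid refinement check (warning
above 1% disagreement).  Product-space and quadrature estimates agree
within a few percent on n = 50 datasets from either generator.

A caveat established during development: for data generated from the null
model (c = 0.5, σ = 0.1, n = 300), the true Bayes factor against the
exponential model typically lands between 0.03 and 0.3 — the exponential
model retains enough prior mass near `α ≈ 0` or `b ≈ 0` that the Occam
penalty is modest.  Conclusive rejection (BF ≤ 0.1) therefore occurs in
only roughly half of such datasets; this is a property of the models as
defined, not of the estimator (quadrature agrees).

## Directional test and reliability

Kendall's tau-b (tie-corrected, since CCEI values tie at 1) measures the
RI–consistency association.  The Bayes factor uses the asymptotic normal
likelihood of the standardized Kendall statistic, `T* | τ ~ N(1.5·√n·τ, 1)`,
against a prior on τ yoked from a stretched Beta(1/κ, 1/κ) prior on
Pearson's ρ through `ρ = sin(πτ/2)`; default width κ = 1 (uniform on ρ).
One-sided tests restrict and renormalize the prior to the hypothesized
sign; the one-dimensional marginal integrals are evaluated by adaptive
quadrature, which is numerically identical to the Savage–Dickey ratio for
this model.  Test–retest reliability is the Pearson correlation of an index
across each participant's two blocks.

## Pipeline and interpretation

The full analysis splits each participant's two blocks into train/test by a
fair coin, runs the tau Bayes factor on the training set, and maps Bayes
factors to verdicts at the conventional thresholds (≥ 10 strong support,
≤ 0.1 strong support against, otherwise inconclusive).  The model
comparison and the replication Bayes factor (BF on combined data divided by
BF on training data) run only when the directional test finds strong
support, mirroring the preregistered gate.  Quality controls always run:
a one-sided rank-sum comparison of participants' CCEI against an
equal-sized random-chooser sample (flagging non-discernability at p ≥ 0.05),
test–retest reliability of all four indices, the reconstruction
manipulation-check table, and a 10 000-resample percentile bootstrap of
mean reconstruction error minus mean choice-set orientation increment
(`0.3·(m/p_axis)/4` degrees per adjacent option).

The reconstruction error metric is the circular distance
`min(|a−b| mod 360, 360 − |a−b| mod 360)`; the printed-formula variant
`||a−b|−180|` is kept under `paper_literal_error` for audit only, because it
returns 180 for identical orientations.

## Problem sizes in the shipped tests

The test-suite defaults are chosen to exercise every claim at meaningful
scale on a single CPU: 1000-participant sensitivity replicates (pooled ×3),
500 random instances for the CCEI oracle equivalence, 20 + 20 model-recovery
replicates at n = 300 with 4 × 2500-draw chains, 50 coverage replicates,
and two n = 50 quadrature cross-checks.

## Known limitations

* The Houtman–Maks and minimum-cost searches are exponential in the worst
  case; beyond their node budgets results are flagged upper bounds.
* The money-pump index enumerates cycles up to length 3 by default (the
  approximation used in practice); longer cycles are configurable but
  combinatorially expensive for very inconsistent data.
* Pseudo-priors are independent Beta fits and cannot represent posterior
  correlation of the inactive model; this costs indicator-chain efficiency
  (compensated by Rao-Blackwellization), not correctness.
* The asymptotic normal likelihood for the Kendall statistic is an
  approximation that deteriorates below n ≈ 10.
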