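# Methods

## Model

Each protein-coding gene *i* carries a latent relative loss-of-function (LOF)
rate η_i ∈ (0, 1): the ratio of its observed LOF variant rate in a population
sample to the rate expected under a neutral mutation model. Strong negative
selection drives η toward 0. The package models

- a per-gene beta prior in the mean/concentration parameterization,
  η_i ~ Beta(μ_i κ_i, (1 − μ_i) κ_i), so E[η_i] = μ_i and Var[η_i] shrinks as
  κ_i grows;
- a Poisson likelihood for the observed LOF count, y_i ~ Poisson(η_i n_i),
  where n_i > 0 is the expected LOF count from the neutral model (the
  statistical "length" of the gene);
- a prior network mapping a gene's standardized feature vector x_i to
  (μ_i, κ_i): either affine maps with logistic/exponential links (the linear
  variant), or one hidden ReLU layer with inverted dropout before the same
  two heads (the nonlinear variant). A model with zero features degenerates
  to a single prior shared by all genes (the flat model).

Training minimizes the mean negative log marginal likelihood
−(1/|Ψ|) Σ log P(y_i | x_i, n_i) over mini-batches Ψ, plus an L2 penalty on
weights (never biases). The marginal P(y | x, n) = ∫ f(η|x) P(y|η, n) dη has
no closed form; it is approximated by a midpoint Riemann sum on a fixed
K-point grid (k − ½)/K. Because the grid is fixed, differentiating through
the sum gives the exact gradient of the discretized objective; the
derivatives of the log marginal with respect to (μ, κ) reduce to
posterior-weighted expectations of log η and log(1 − η) plus digamma terms,
and are chained through the links and the network by ordinary
backpropagation. The forward/backward passes and the Adam optimizer are
implemented directly in numpy/scipy; a finite-difference check in the test
suite pins the hand-derived gradients to ~1e-10.

Prediction fixes the fitted network, forms each gene's posterior over η by
Bayes' rule on the same grid, and reports the posterior mean E[η_i] and the
intolerance score 1 − E[η_i] (the estimated fraction of LOF mutations
removed by selection; higher = more intolerant).

## Numerical choices

- All densities are evaluated in log space (log-gamma for the beta function,
  log-sum-exp for the integral), which keeps κ up to ~1e8 and n up to ~1e4
  finite. A probability-scale marginal that underflows to exactly zero
  raises instead of propagating −inf.
- The midpoint grid never touches η = 0 or 1, so beta densities with
  boundary singularities (μκ < 1 or (1 − μ)κ < 1) are always finite.
- Grid resolution: K = 4096 by default, shared by the marginal, the
  posterior density and the posterior mean. The midpoint rule is
  second-order: doubling K shrinks the log-marginal error ~4-fold. The
  steepest integrands we exercise (y = 0, n = 50 under a uniform prior)
  carry a doubling difference of ~5e-6 at K = 4096, reaching 1e-8 only near
  K = 131072; conversely the *posterior mean* is accurate to ~2.5e-7 at
  K = 4096 because numerator and denominator errors largely cancel. A prior
  whose standard deviation sqrt(μ(1−μ)/κ) falls below the grid spacing 1/K
  is not resolved (e.g. κ = 1e8 needs K ≳ 65536); the training ranges never
  approach this regime.
- Training fits in this repository use K = 1024: the relative quadrature
  error (~1e-6) is orders of magnitude below the sampling noise of the
  objective, and the fit cost scales linearly in K. All closed-form oracle
  comparisons use K = 4096 or 8192.
- The logistic head is clipped to [1e-12, 1 − 1e-12] and the exponential
  head to [1e-12, 1e12]: beyond |s| ≈ 37, float64 `expit` saturates to
  exactly 0/1, which would be an invalid beta mean.
- Optimizer: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8). Defaults: batch size 64,
  at most 1000 epochs, early stopping after 10 epochs without validation
  improvement, parameters restored from the best-validation epoch. The
  validation loss used for stopping is the unpenalized mean NLL; the
  recorded training history is the epoch mean of the penalized mini-batch
  losses. One seeded generator drives the split, the per-epoch shuffles and
  the dropout masks, so a (config, seed) pair reproduces a fit exactly.
- Hyperparameter search sweeps the full Cartesian grid (L2 ∈ {0, 1e-2 …
  1e-6}, learning rate ∈ {1e-3, 1e-4, 1e-5}, hidden units ∈ {64 … 1024} for
  the nonlinear variant) and selects the lowest validation loss; exact ties
  break toward fewer hidden units, then stronger L2, then declaration order.

## Feature preprocessing

Continuous features flagged as right-skewed are transformed as
x′ = log(x + δ) with δ the column's minimum observed positive value; every
continuous feature is then z-scored with the sample (G − 1) standard
deviation, and missing entries are imputed last, with the column's
post-transform mean (≈ 0 by construction). Binary features must be exactly
{0, 1} and pass through untouched; a missing value in a binary column is an
error rather than silently imputed, since a fractional fill would break the
{0, 1} contract. Constant columns standardize to zeros with a warning
instead of erroring. Transform statistics are fitted on the full table
before the 80/20 split; the model is unsupervised in the label sense (it
never sees essentiality annotations), so the usual leakage concern does not
apply, and the frozen state (δ, mean, sd, fill) can be re-applied bit-exactly
to new genes.

## Synthetic data

The generator emulates a gnomAD-style constraint table. Defaults: 19,197
genes; 12 continuous features (half plain Gaussian, half exponentiated
Gaussian — right-skewed, nonnegative, flagged for log transform) and 6
binary Bernoulli features with inclusion probabilities spread over
0.05–0.5, mirroring the published mix of 12 continuous and 6 gene-set
features; 5% missing entries in continuous columns; prior mean
μ_i = logistic(w*ᵀx_i + b*) with configurable generative weights (drawn
N(0, 0.5²) when unspecified); constant generative concentration κ = 5 by
default, optionally feature-linked; expected counts n log-normal with
median 5 and log-sd 1.5, clipped to [0.1, 200] (with this spread ~⅔ of
genes have n ≤ 10, keeping the short-gene regime that motivates the
feature-informed prior well populated); y ~ Poisson(ηn). An optional
override supplies an arbitrary per-gene prior-mean array, used to generate
data whose feature→μ map is deliberately nonlinear.

What the generator does **not** emulate: realistic mutation-rate models,
correlated features, site-level sequence context, population structure, or
annotation error in curated essential-gene sets. Passing tests on these
simulations therefore demonstrates the estimator's internal correctness and
its qualitative behavior (prior influence concentrated in short genes,
weight recovery, model selection), not field performance on real cohorts.

On calibration: binning genes by *estimated* posterior mean and comparing
with the bin-average true η gives slope ≈ 1.0 (max bin discrepancy < 0.02
at G = 10,000, κ = 5). Binning by *true* η instead yields an apparent slope
of ~0.84 — ordinary shrinkage of Bayes estimates toward the prior, not a
defect — so the calibration test conditions on the estimate.

## Evaluation toolkit

- Matched control sets: greedy 1:1 nearest-neighbor matching on expected
  LOF count, without replacement, processing essential genes in descending
  n (ties by gene id; pool ties by order). This is a deterministic stand-in
  for propensity-matching tools and can diverge from optimal matching when
  the pool is tight near large n.
- ROC/AUC via scikit-learn (equivalent to pair counting with ties at ½;
  verified against brute-force enumeration in the tests).
- DeLong test for correlated AUCs from placement values, two-sided normal
  p-value; degenerate zero-variance comparisons report p = 1 when the AUCs
  are equal.
- TPR at fixed FPR: the maximum TPR over thresholds whose empirical FPR
  does not exceed the target (inclusive thresholds throughout), with a
  stratified bootstrap SE (resampling within each class).
- Enrichment: log OR with SE sqrt(Σ 1/n_ij) and a ±1.96·SE Wald interval;
  zero cells raise (no continuity correction).
- Deletion-overlap permutation test: 0-based half-open intervals, overlap =
  nonempty same-chromosome intersection, strand ignored. Each permutation
  redraws |target| genes from the pool without replacement; the one-tailed
  p is the fraction of permutations with overlap proportion ≤ observed,
  reported without a pseudo-count by default (p = 0 is possible); a
  (b+1)/(B+1) estimator and an exact subset-enumeration mode are available.
- Prior-influence summary: per-gene |Δscore| between a feature model and a
  flat model, averaged within n-quantile bins, with the Spearman correlation
  between bin median n and bin mean |Δ| as the trend statistic (undefined —
  reported as NaN — when all deltas are identical).

## Problem sizes used in the shipped checks

Closed-form and convergence checks run on the y ∈ {0..20} × n ∈ {0.1, 1, 5,
10, 50} lattice at K = 4096/8192. Weight recovery and the prior-influence
trend use 10,000 genes with 8 continuous features and known weights
(1.2, −0.8, 0.6, −0.4, 0.25, −0.15, 0.1, 0); model selection uses 6,000
genes with a U-shaped (squared-feature) prior-mean map and a reduced
hyperparameter grid; the evaluation-statistic oracles use 20–200-gene
fixtures, 2,000 simulated 2×2 tables and a 12-gene pool enumerated
exhaustively. These sizes are the package's own defaults for a
single-workstation reproduction.

## Known limitations

- Contribution scores are defined only for the linear variant; the package
  deliberately offers no saliency-style attribution for the nonlinear model.
- The matching routine is greedy nearest-neighbor; it does not implement
  calipers or optimal matching.
- The quadrature-based fit treats the grid as part of the objective; results
  at very small K differ slightly from the continuous-integral optimum.
- Scores depend on the neutral-model expected counts supplied in the input
  table; the package does not model uncertainty in n.
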