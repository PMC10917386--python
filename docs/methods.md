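# Methods

This note documents the statistical model, the synthetic study the
package emulates, the numerical choices, and the known limitations. It
describes what the code does and why; every number quoted here is
computed by the tests or by `scripts/acceptance.py` at run time.

## Connectome construction

Subject connectomes are Pearson correlations between regional (node)
time courses, Fisher z-transformed: `z = atanh(r)`. Correlations are
clipped to `±(1 − 1e−7)` before the transform so that numerically
perfect (anti)correlations map to large finite values rather than
`±inf`; the number of clipped edges is logged. The diagonal is stored as
exactly 0 and never enters any edge statistic — all analyses operate on
the canonical edge vector, the row-major upper triangle (`(0,1), (0,2),
…, (1,2), …`), which is the single edge ordering used by selection,
masks, consensus networks, and all file exports (`E = N(N−1)/2`; 12720
edges for the 160-node atlas). A zero-variance node column is an error
naming the offending nodes, not a silent NaN.

## Subject filtering

Exclusion criteria expressible on a phenotype table are applied in a
documented order (user-supplied image-QC flags, handedness, full-scale
IQ < 70, scan length < 100 timepoints, gross motion > 2 mm / 2°, mean
framewise displacement > 0.2 mm, missing target score), with the
per-site minimum (20 subjects) applied afterwards to the survivors. The
reported exclusion reason is the first violated criterion. Filtering is
idempotent because site sizes are re-evaluated on the filtered table.
Criteria that require the images themselves (signal loss, normalization
quality, brain coverage) are accepted as pre-computed boolean columns.
Subjects missing a particular subscore are dropped per-analysis, not
globally, so different scores may run at different `n`.

## Multisite harmonization (ComBat)

Each edge is modelled as `x = α + Cβ + γ_site + δ_site·ε` with
biological covariates `C` (by default diagnosis/group, age, sex, FIQ,
mFD, where present and non-constant). Per-site location and scale
estimates are shrunk by empirical Bayes across edges and removed;
covariate effects are fit, removed for standardization, and restored.
Estimation conventions deliberately match the reference implementations
(pooled variance with `1/n`, site variances with `1/(n_i − 1)`,
moment-matched normal/inverse-gamma priors, fixed-point iteration to
1e−4), and the parametric and nonparametric modes are verified against
`sva::ComBat` in the test suite (the nonparametric mode agrees to
machine precision, the parametric to the iteration tolerance).

Choices worth knowing:

* **Parametric EB is the default.** The nonparametric prior (a
  leave-one-feature-out Monte Carlo integration) is available via
  `mode="nonparametric"`, but it is O(E²) per site and intended for
  feature counts in the thousands. Both modes must and do pass the same
  recovery simulations.
* **A single-site dataset is returned unchanged.** With one batch there
  is no between-site variability to remove; the literal algorithm would
  still rescale deviations by `sqrt((n−1)/n)` purely because of the
  ddof conventions above, so identity pass-through is the honest
  behaviour.
* **A site with one subject is an error** unless
  `allow_singleton_sites=True`, in which case its scale is fixed at 1
  (a variance cannot be estimated from one observation) and its
  location is still shrunk.
* **Harmonization order.** The pipeline harmonizes each pooled sample
  once, before CPM — the common order of operations. This means fold
  test subjects contributed to the site estimates; the leakage is
  documented here and is second-order (site parameters are pooled over
  all edges and subjects). Model, validation, and control samples are
  harmonized separately — they play the role of independently processed
  datasets, and nothing from the model sample leaks into the transfer
  samples.

## CPM, cross-validation, and permutation inference

Edge selection uses the partial correlation of each edge with behaviour
given the covariates; an edge is selected iff `|r| > r_crit(df, p)` with
`df = n_train − 2 − k`, which is algebraically identical to the
two-sided `p < 0.01` rule. Positive and negative tails are modelled and
evaluated as **separate single-predictor models** (network strength =
sum of the subject's edge weights over the selected edges of one sign);
a joint two-predictor model over both strengths is available behind
`tail="combined"`.
Covariates are z-scored within each training fold before
residualization; because z-scoring is affine and the design contains an
intercept, fold residuals are mathematically unchanged by it — the
property is stated here so that the fast engine's reliance on it is
explicit.

**The leave-one-out engine.** Rerunning selection + fit `n` times per
permutation is the computational bottleneck of the protocol, so the
engine uses a projection identity: partialling an indicator column for
the held-out subject out of the *full* sample is exactly equivalent to
computing the partial correlation on the training subjects alone. One
residualization of the edge matrix therefore serves all `n` folds, and
each new behaviour vector (observed or shuffled) costs one matrix-vector
product plus O(nE) elementwise work. The identity is exact, and the test
suite verifies bit-identical fold masks against a literal
train-subjects-only recomputation.

* Folds that select no edges (or have zero strength variance) predict
  the training mean and are flagged; a result where *every* fold is
  empty is marked invalid.
* The consensus network is the intersection of all fold masks.
* Evaluation is the covariate-adjusted correlation between pooled
  held-out predictions and observed scores (`df = n − 2 − k`).
* Permutations shuffle the behaviour vector only; covariates stay
  paired with the connectomes, and the evaluation uses the permuted
  behaviour. `p_perm` is the one-sided add-one estimator; degenerate
  permutations contribute `r = 0` and are counted. The mean of the null
  correlations is reported as the chance-level summary.
* FDR: Benjamini–Hochberg, applied within each pre-registered family
  (the pipeline treats each transfer sample's batch of tests as one
  family).

**Covariate usability.** A two-level covariate whose minority level has
fewer than 3 subjects is dropped from leave-one-out analyses
(`usable_covariates`): a near-singleton level gives that subject
leverage 1, making the training fold's design rank deficient when they
are held out. Heavily male samples make this a live case (a 36-subject
control group with one female is realistic). Plain (non-CV) partial
correlations only require the covariate to be non-constant.

**Transfer.** The coefficients applied to new samples are a
deterministic refit of the tail model on the full model sample using
consensus-mask strengths (not an average of fold models). Specificity on
controls is a null test: "pass" is non-rejection at α = 0.05, which is
evidence of absence only in the usual limited sense.

## The synthetic study

The generator's defaults are the frozen study conditions: a 150-subject
model sample over 4 sites, a 170-subject validation sample over 2 sites,
and 36 controls at one site; 160-node connectomes in six networks; 40
planted negative edges. The behavioural score is ADOS-total-like
(patient mean ≈ 11.9, SD ≈ 4; subscores for social, communication and
repetitive-behaviour domains are loadings on the same latent severity),
built as baseline + covariate effects + noise, with age ~ U(7, 40)
years, sex ~ Bernoulli(0.94 male), and mFD lognormal with mean ≈ 0.09 mm
— the covariates are genuinely confounded with behaviour so covariate
adjustment has something to do. Planted edges add
`sign · β · standardize(y)` to their baseline weight with β = 1.5
Fisher-z units per behaviour SD against unit edge noise; this is the
calibrated effect at which the whole pipeline must recover ≥ 90% of
planted edges (it is deliberately a strong effect — the acceptance
property is about pipeline correctness, not about detection at marginal
power). Sites add a per-edge additive offset (site-level mean spread
0.10, per-edge spread 0.20) and a multiplicative noise scale (log-SD
0.15). Site sizes are mildly unbalanced (1.3× ratio between adjacent
sites), chosen so the default model sample leaves every site at ≥ 20
subjects, consistent with the filtering rule. Controls draw scores from
N(1.33, 1.66) truncated at zero and get **no** edge coupling, making
specificity tests expected-null by construction.

One integer seed drives a fixed hierarchy of `SeedSequence` substreams
(truth → baseline connectome → model → validation → control → time
series), so datasets are bit-reproducible and adding a sample never
perturbs another sample's draws.

Time-series emission inverts the pipeline: node series are Gaussian with
population correlation `tanh(z_target)`, after an eigenvalue-clipping
repair to the nearest positive-definite correlation matrix (clip at
1e−6, renormalize the diagonal; repairs are logged). What the generator
does **not** emulate: haemodynamic autocorrelation, non-Gaussian BOLD
noise, motion artefacts correlated with behaviour, or missing-data
patterns — so green tests demonstrate the statistical machinery is
correct, not that effect sizes of this magnitude exist in real
resting-state data.

## Problem sizes used by tests and the acceptance script

The packaged checks run at sizes chosen to exercise every code path at
full study scale at least once: oracle comparisons on tiny random inputs
(≤ 1e−10 agreement), the leakage audit at 20 nodes / 40 subjects,
permutation-test calibration over 200 replicate null datasets (60
subjects, 30 nodes, 200 permutations; empirical type-I error required in
[0.02, 0.09] at α = 0.05), and 20 replicate full-scale planted studies
(150 subjects, 160 nodes, 200 permutations) for recovery, replication
and specificity. `scripts/acceptance.py` runs one full-scale study
end-to-end. The permutation default in the pipeline remains 1000;
analyses here use 200 where a null distribution is recomputed hundreds
of times.

## Known limitations

* The evaluation correlation is computed on predictions pooled across
  folds (fold-wise averaging is a defensible alternative the package
  does not implement).
* LOOCV-pooled evaluation r has a known pessimistic bias under the null
  (training means anti-correlate with held-out outcomes); the
  permutation null inherits and absorbs this bias, which is why
  `mean_null_r` is reported and slightly negative.
* ComBat here is location/scale only — no covariance (CovBat) or
  nonlinear-age (GAM) variants.
* The strict fold-wise harmonization variant (refit ComBat inside every
  training fold) is not wired into the pipeline driver; the library
  function can be applied per fold by hand where that methodological
  comparison is wanted.
* k-fold / split-half CV and sparse or robust selection variants are
  out of scope by design.
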