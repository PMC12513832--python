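# Methods

`tmesig` implements a signature-discovery workflow for spatial multi-omics
cohorts of immunotherapy-treated patients: compartment-specific (tumor /
stroma) cell-type signatures learned by sign-constrained LASSO-Cox
stability selection, gene signatures derived from the signature cell types'
marker sets, frozen-cutpoint survival validation, and spatial
neighborhood/interaction analysis. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Survival model and the sign-constrained solver

All signature fitting is built on the Cox proportional-hazards partial
likelihood. Ties are handled by the Breslow approximation by default;
Efron is available for unpenalized fits (`ties="efron"`). The two differ
only on tied event times, which the synthetic generators (continuous
exponential times) never produce.

The penalized estimator minimizes

    -(1/n) * log PL(beta)  +  lambda * sum_j |beta_j|

subject to `beta_j >= 0` (resistance) or `beta_j <= 0` (response). The
sign constraint is what makes a signature directional: a resistance score
can only accumulate risk-increasing features. The solver is iteratively
reweighted least squares on the Breslow log partial likelihood (diagonal
Hessian weights) with cyclic coordinate descent on the working response;
each coordinate update is a soft-threshold followed by projection onto the
sign orthant. Because the objective is convex and the feasible set is an
orthant, the solution can be checked against any generic box-constrained
optimizer of the same objective; the test suite and the acceptance script
do exactly that with L-BFGS-B and require agreement to 1e-4 in objective
value. Inner loops are compiled with numba.

Choices worth knowing:

- **Standardization.** Columns are z-scored internally before penalization
  so the penalty is scale-free; coefficients are reported on the original
  scale. Disable with `standardize=False`.
- **Penalty path.** A geometric grid of 40 values from the smallest lambda
  that zeroes every coefficient (computed from the sign-feasible entry
  gradients) down to 1% of it.
- **Penalty selection.** Ten-fold cross-validation stratified by event
  status, scored by the Verweij–van Houwelingen partial-likelihood
  deviance `-2*(ll_full(beta_k) - ll_train(beta_k))`; the deviance-
  minimizing lambda is the default, the one-standard-error rule is an
  option (`use_1se`). Fold assignment is seeded and logged.
- **Unpenalized refits.** Newton with step halving on z-scored covariates.
  A monotone likelihood (perfect separation) is detected either by a
  per-SD coefficient escaping ±20 or by a per-SD standard error above 100
  (a flat likelihood direction); the fit is capped and flagged
  non-converged instead of failing the pipeline.
- **Sign-constrained refits** (the final signature models) reuse the
  penalized solver at lambda=0; standard errors are reported only for
  coefficients strictly inside the orthant.

Kaplan–Meier curves, log-rank tests and hazard ratios are implemented
directly (and are cross-checked against lifelines in the tests). The
one-sided log-rank takes the hypothesized higher-risk group as a required
explicit argument — it is never inferred from the data, so validation
cannot peek at the observed effect direction.

## Cell-type signature pipeline

Input: a patients × 14 cell-fraction matrix per compartment and a survival
table administratively censored at the endpoint horizon (24 or 60 months).
For each of M splits (defaults: M=100 tumor, M=50 stroma), ten folds are
drawn fresh, CV picks lambda, and one sign-constrained LASSO-Cox model is
fit on the pooled training cohort at that lambda — splits differ only
through fold randomization. Cell types with nonzero coefficients in at
least t of the M models are retained, with t the largest threshold keeping
at least three cell types (computed per compartment × direction). A final
unpenalized Cox model, still sign-constrained, gives the coefficients
`beta_final`; the patient score is `S_i = sum_j beta_final_j * M_ij`. The
median (or upper-tertile) score of the training cohort is frozen into the
serialized model; validation cohorts are dichotomized at that stored value
and tested with a one-sided log-rank in the training-established
direction. Ties at the cutpoint go to the low group.

## Cell-to-gene pipeline

Candidate genes are the union of the signature cell types' marker lists
intersected with the measured panel. The stability ensemble runs 50
train/test splits (80/20, event-stratified). Within each split:

1. genes differentially expressed between 2-year progressors and
   non-progressors in the *training half only* (NB exact test, P < 0.05);
2. 100 seeded runs of tenfold-CV + sign-constrained LASSO on the training
   half; any gene selected by any run joins the split's union;
3. an unpenalized sign-constrained Cox on the union ("the split's
   signature") is scored on the held-out fifth, and the median-dichotomized
   hazard ratio of those test scores is recorded.

Splits pass the HR gate when the held-out HR exceeds 1.5 (resistance) or
falls below 0.7 (response). A gene's support is the fraction of *gated*
splits in which it carried a nonzero coefficient; genes with support ≥ 5%
are retained, capped at ten by support (ties by mean |coefficient|, then
name). The final model is refit unpenalized and sign-constrained on the
whole discovery cohort, with an upper-tertile frozen cutpoint for PFS
endpoints (median for OS).

Two design points deserve emphasis:

- **Expression representation.** Models are fit and scored on
  `log1p(counts / library_size * 1e4)`. Raw counts are not comparable
  across cohorts with different sequencing depth, and a frozen cutpoint is
  meaningless on a non-transferable scale. The DE filter, by contrast,
  works on raw counts with library sizes equalized to the geometric mean,
  as the exact test requires.
- **Missing genes in validation.** If more than 20% of a model's genes are
  absent from a validation panel the validation refuses to run; up to 20%
  it proceeds on the intersection with a warning and no imputation.

### NB exact test

Two-sided exact test for overdispersed counts. Library sizes are equalized
by scaling to the geometric mean and rounding; a common dispersion φ is
estimated by conditional (negative-hypergeometric) maximum likelihood
pooled over genes and groups — the smallest model consistent with an exact
conditional test. Per gene, the group-A sum given the total is distributed
as the convolution ratio of two NB sums; the p-value sums the conditional
probabilities of all outcomes no more likely than the observed one. For
φ < 1e-8 the test switches exactly to the Poisson-limit conditional, which
is binomial. P-values within 1e-12 of 1 are snapped to 1 so that identical
groups report exactly p = 1.

### Deconvolution consistency check

`nnls_deconvolve` solves `B × F_i ≈ M_i` by non-negative least squares on
the genes shared between the reference signature matrix (e.g. LM22) and
the sample, renormalizes the fractions to sum to 1 and reports the
residual norm. It is a consistency check of compartment cell-type
estimates against expression, not a reimplementation of any particular
deconvolution suite.

## Spatial analysis

Coordinates are physical µm; neighbor relations never cross region (tissue
core) boundaries.

- **Interaction scores.** The radius method: neighbors are the cells within
  30 µm, capped at the 10 nearest (both constraints honored; a pure-kNN
  mode exists). `score(A→B)` is the mean over type-A cells of the fraction
  of their neighbors of type B. The null permutes labels within each
  region (geometry preserved), 1000 permutations by default, seeded;
  z-scores and two-sided permutation p-values are reported per ordered
  pair. k-NN relations are directed; no symmetry is assumed or enforced.
- **Neighborhoods.** Each cell's feature vector is the type composition of
  its 10 nearest neighbors (self excluded; short lists in small regions are
  flagged). Vectors are clustered by seeded k-means into 10 groups (the
  cited upstream neighborhood pipelines use k-means; ten neighbors and ten
  clusters follow that literature), annotated post hoc by dominant centroid
  types.
- **Outcome comparisons.** Per neighborhood and cell type, the per-patient
  within-neighborhood composition (log2, pseudocount 1e-3) is regressed on
  the binary outcome by OLS, with BH adjustment across all performed tests;
  per-patient neighborhood frequencies are compared by Welch t-tests.

## Synthetic cohorts

The generator produces the structure the analysis assumes, nothing more:

- **Fractions**: symmetric Dirichlet(1) rows over the 14 cell types per
  compartment. The concentration is a free parameter of the generator, not
  an estimate of any real cohort.
- **Survival**: exponential baseline (0.04 events/month by default, median
  ≈ 17 months, typical of advanced NSCLC on first-line ICIs), hazard
  multiplied by `exp(score)`, independent exponential censoring (0.01 /
  month) and an administrative horizon (60 months). Exponential rather
  than Weibull: the simplest law satisfying proportional hazards, which is
  what the pipeline assumes.
- **Planted effects are per-SD log hazard ratios**: the planted score is
  `sum_j c_j * z_ij` with z-scored features. On raw simplex fractions
  (SD ≈ 0.07) a unit coefficient would be an undetectably small effect;
  per-SD coefficients are the scale on which effect sizes are comparable
  across features.
- **Expression**: NB counts with `log mean = log(baseline) + loading ×
  fraction(cell type of the gene) + planted log-FC × group + log library
  size`; dispersion 0.2, library-size CV 0.2, baseline mean 8 — modest
  targeted-panel-like depths that keep exact-test enumeration cheap.
- **Spatial fields**: uniform points; disk niches draw labels from their
  own mixture, first-declared niche wins on overlap (deterministic).

What the benchmarks therefore show: that the pipeline recovers planted
structure of realistic effect size under its own assumptions
(proportional hazards, linear programs, independent patients). What they
do not show: robustness to batch effects, non-proportional hazards,
segmentation/phenotyping error, compositional artifacts of real panels, or
cohort shift — none of which the generator emulates.

## Benchmark problem sizes

The acceptance script (`scripts/acceptance.py`) runs: 50 random solver
instances (n ≤ 40, p ≤ 5); 10,000 null log-rank simulations at n=60; 100
exact-test enumeration cases (totals ≤ 30); 20 cell-type recovery
replicates (n=200, M=50); 10 gene-pipeline replicates at a scaled ensemble
of 20 splits × 20 seeds (n=150, ~500 candidates, 8 planted genes at 0.8
per-SD log HR) with an independent validation cohort each; a 5000-cell
3-niche field plus 100 CSR fields at 1000 permutations; and a byte-level
determinism re-run (n=150, M=50). The scaled-down gene ensemble keeps the
stability-selection logic identical while making the experiment cheap
enough to replicate ten times.

## Known limitations

- Penalized fits support Breslow ties only; Efron is unpenalized-only.
- The per-split HR gate uses median-dichotomized held-out scores; with
  very small test splits (<10 patients) the dichotomized HR is noisy and
  occasionally flagged unstable (recorded as NaN and excluded from gating).
- `multivariable_adjustment` drops unidentifiable (constant or collinear)
  terms greedily in column order rather than refitting a best subset.
- The NB exact test estimates one common dispersion per call; tagwise
  (per-gene) dispersions are out of scope.
- No plotting: all outputs are tidy tables/JSON; KM curves are returned as
  step-function DataFrames for external plotting.
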