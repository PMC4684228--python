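# Methods

## Counting model and hypotheses

Each gene *i* in blastomere *j* is modeled as negative binomial (NB2):
`r_ij ~ NB(mu_ij, alpha_i)` with `Var = mu + alpha mu^2`. Library sizes
`s_j` — column sums of raw counts after removing excluded features (rRNA
and other non-gene-model sequences) — enter as fixed offsets on the log
scale, so all hypotheses are log-linear models:

* null: `log mu_ij = log s_j + beta_null`
* single axis *a*: `log mu_ij = log s_j + a_j beta_a + (1-a_j) beta_abar`
* multi-axis: additive indicator terms for two or three axes.

Dispersion is estimated per gene per hypothesis by joint maximum
likelihood — re-estimated under the alternative, with no information
sharing across genes (no empirical-Bayes shrinkage). The LRT statistic
`-2(l_null - l_alt)` is referred to chi-square with degrees of freedom equal
to the design-rank difference: 1 for a single axis, 1 more per additional
orthogonal axis (a duplicated or complementary axis collapses by rank
reduction; an axis with all samples on one side is an error). Q-values are
Benjamini–Hochberg within each family: all converged genes for one axis in
one mode (pooled, or one embryo). Genes whose fits do not converge are
excluded from the family and listed in a side report.

Normalized counts (per 25 million counted reads) are used only for the
expression filter and for reporting pole means and fold-changes; tests
always run on raw counts with offsets. A gene is testable if at least one
single embryo has >= 4 blastomeres with >= 10 normalized counts (both bounds
inclusive; the condition is per-embryo by design, so weak ubiquitous
expression spread across embryos does not qualify). The filter is applied
to normalized counts even when libraries are near the standard size.

## Fitting

For a fixed dispersion, the coefficients of an NB2 log-link GLM are
obtained by iteratively reweighted least squares, batched across all genes
(shared design, per-gene weights). The dispersion is then profiled out on
the log scale: a 28-point grid on `log alpha` in `[log 1e-6, log 1e4]`,
followed by golden-section refinement of each gene's bracketing interval
(34 iterations, interval width ~1e-7 in log alpha). The Poisson limit
(`alpha = 0`) is always evaluated explicitly and wins ties, so zero-variance
genes land exactly on the boundary; internally any `alpha < 1e-8` uses the
Poisson log-likelihood. Everything is deterministic — there is no seed in
the fitting path.

Numerical guards: linear predictors are clipped at ±35 (a group with all
zero counts walks its log-mean to the clip and contributes its boundary
likelihood, which is the correct limit); a tiny ridge (1e-10) stabilizes the
batched solves; if an alternative's optimum falls below the null's (possible
only through failed optimization, since the models are nested), the
alternative is re-profiled at the null's dispersion, which restores nesting
because the null design is a subspace of the alternative's. Residual
negative statistics within -1e-6 are clamped to zero. Fitted MLEs were
validated against dense grid searches of the likelihood surface (scipy pmf
evaluations, exhaustive over `beta` x `log alpha`): agreement to ~1e-3 in
log-likelihood and a few tenths of a percent in the parameters, with the
optimizer never below the grid optimum.

Fold-changes are ratios of pole means of normalized counts, >= 1 by
construction, with the enriched pole attached. Exact ties report fold 1
with no pole; a single zero mean gives an infinite fold (serialized as
"Inf" and flagged); no pseudocount is added, since testable genes make zero
pole means rare.

## Synthetic experiments

The generator emulates the design of a single-blastomere screen: `n_embryos`
embryos x 8 blastomeres with the full 2x2x2 octant labeling; library sizes
log-normal around 25 million reads with CV 0.3 (stresses the offset
handling); counts NB2 with gene-specific dispersion. Defaults: 2,000 genes,
4 embryos, 7% of genes asymmetric on the animal–vegetal axis split
448:460 vegetal:animal, and no dorsal–ventral or left–right effects.

Choices the data do not dictate, and why:

* **Baselines** are log-normal (sdlog 2.0, a realistic RNA-seq dynamic
  range) and rescaled to sum to 25 million, so the expected column sum of a
  simulated matrix equals the drawn library size. Without this, library
  sizes recomputed from column sums (which is what the pipeline does) would
  put normalized counts on a scale that drifts with the number of genes.
* **Folds** are applied symmetrically about the baseline (x sqrt(f) on the
  enriched side, / sqrt(f) opposite) so baseline and fold stay separately
  identifiable in recovery tests. Log-folds are Gamma distributed; the
  shape is derived from the target mean fold via the Gamma MGF
  (`E[fold] = (1 - scale)^-shape`), giving mean folds of exactly 4.2
  (vegetal, scale 0.75) and 1.5 (animal, scale 0.30). The exponential fold
  tail puts ~0.16% of vegetal folds above 134 and ~1.6% of animal folds
  above 3.8, matching the observed extremes. A log-normal *of the
  log-fold* was rejected: its tail is so heavy that a mean-4.2 calibration
  is dominated by astronomically rare folds (samples of 1e8-fold appear).
* **Dispersions** are log-normal with median 0.02 (sdlog 1.0). The value
  follows from the screen's detection floor: pooled tests over 16 vs 16
  blastomeres can only call ~1.1-fold changes significant if
  `alpha + 1/mu` is of order 0.01-0.02 for well-expressed genes.

What the generator does **not** model: polyadenylation-state differences
between library chemistries, correlated dispersion across genes, positional
effects within a pole, or partial-blastomere dissection. Passing recovery
tests therefore demonstrates correctness of the estimator under the stated
model, not robustness to those real-data features.

## Known properties and limitations

* **Small-sample liberality.** With dispersion re-estimated under the
  alternative, the chi-square(1) reference is anticonservative at small n:
  in null simulations the raw p < 0.05 rate is ~6.5-7.5% pooled (32
  blastomeres) and ~10% per embryo (8 blastomeres). BH keeps realized
  q < 0.05 rates far below nominal (~1e-4 pooled, ~8e-4 per embryo), but
  over very many single-embryo tests occasional two-embryo coincidences
  with opposite poles can appear in the opposing-asymmetry scan (observed
  once in 80,000 gene-axis trials). Holding the dispersion at its null
  estimate would flip the test conservative; the re-estimation convention
  is retained as the method's literal definition.
* **Compositional bias of total-count offsets.** Library sizes computed as
  total counts transfer mass asymmetry into the offsets: strongly
  vegetally-enriched genes inflate vegetal library sizes, deflating
  normalized counts (and fold estimates) of every other gene on that side.
  At the default 7% asymmetric fraction the effect on fold estimates is
  ~10%; planting far more asymmetric mass (15% of genes, many at 25-fold)
  pushes it to ~25%. Median-of-ratios or TMM normalization would remove
  this but would be a different method.
* **Per-gene dispersion at n=8** is noisy; no shrinkage is applied by
  design, so per-embryo results are substantially less powered than pooled
  ones (the pooled >= per-embryo power ordering is asserted in tests).
* **Fisher-test sidedness.** Two-sided tests (summing hypergeometric
  probabilities <= observed) reproduce the published enrichment p-values
  (0.049 for all asymmetric genes, 0.001 for the animal cohort) and are the
  default; a one-sided option exists.
* **Cross-reference voting** treats direct and indirect routes as equal,
  unweighted votes, and "clear majority" is implemented as a strict
  majority (> 50% of routes). Best-hit filtering keeps one hit per
  (query, target) pair — bit score, then e-value, then lexicographic
  target — and votes over targets.

## Problem sizes used in the shipped checks

Simulation-based checks run at 2,000 genes x 4 embryos: 20 replicate null
experiments for FDR calibration and the opposing-asymmetry scan, and one
recovery experiment with 50 genes planted at each fold in {1.5, 4, 25}
(7.5% of genes asymmetric, the observed asymmetric fraction). Optimizer
validation uses 50 random 8-sample genes against dense likelihood grids.
The full suite runs in a few minutes on one CPU.
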