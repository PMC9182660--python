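# Methods

This note documents the models behind `gspanel`, the choices made where the
design was genuinely open, and what the synthetic panel does and does not
establish about real breeding data.

## The setting

A closed, inbreeding-based breeding program evaluates a panel of
near-homozygous lines in multi-environment field trials (an environment is a
location-year; replicates are nested in environments and incomplete blocks
in replicates) and genotypes the panel with a SNP array.  The package
implements the full evaluation chain for genomics-based selection in such a
program: stage one reduces plot data to line means and heritabilities with
linear mixed models; stage two performs marker-based analyses — genomic
relationships, structure-corrected association scans with a resampling
stability screen, and GBLUP genomic prediction assessed by cross-validation
within and between environments.  Plot data never reach the genomic models;
the two-stage boundary is deliberate and mirrors standard LSMEANS-based
practice.

## Synthetic panel generator (`simpanel`)

Founders are fully inbred; founder allele frequencies are uniform on
`founder_maf_range` (default 0.1–0.5).  The crossing recipe — two large
founder-pair full-sib families plus round-robin crosses among the remaining
founders — reproduces the relatedness anatomy of a breeding panel: two
strongly related blocks embedded in weaker admixed background.  Gametes
recombine with no interference (Poisson crossover count, i.e. Haldane's map
function), and single-seed descent through `selfing_generations` rounds
(default 6) drives heterozygosity down as `2^-t`.  Physical positions are
genetic positions times a fixed 400 kb/cM constant; downstream code uses
them only as labels.

Trial phenotypes follow

    y_ijkl = mu + g_i + e_j + (ge)_ij + r_k(j) + b_l(k) + eps_ijkl

with independent normal effects at the configured variances and the genetic
value `g_i` built from marker dosages: optional major QTLs (each assigned a
proportion of `var_g`) plus a polygenic tail over every marker.  Genetic
effects are rescaled so the realized panel variance of `g` equals `var_g`
exactly; this removes one layer of sampling noise from parameter-recovery
checks without touching the stochastic trial layers.  G×E is generated as
i.i.d. line-by-environment deviates, matching the variance-component model
the analysis fits, not as environment-specific marker effects.  Missingness
is completely at random.  Defaults — 80 lines, 2,000 SNPs on 5 chromosomes
of 1.5 Morgans, 14 environments (7 locations × 2 years), 2 replicates of 4
incomplete blocks — are the study conditions the package is exercised
under; replicate count is a knob because real trials ranged from two to
four.

What the generator does *not* emulate: dominance and epistasis, selection
across cycles, spatial field trend, informative missingness, and
environment covariates.  Passing tests therefore demonstrate correctness of
the estimators under the stated generative model, not robustness to those
violations.

## Line means and heritability (`trial_means`)

Per environment, genotype is fixed with replicate and block-in-replicate
random; the reported line mean is the GLS genotype estimate.  Overall means
use a cell-means parameterization (genotype × environment fixed) with
rep(env) and block(rep) random; a line's overall mean is the average of its
estimable cells — lines unobserved in an environment contribute nothing
there and lines observed nowhere are reported missing, never zero-filled.

Heritability uses the all-random model (line; line × environment, an
environment main effect, replicate and block when in scope) and the
family-mean formula

    H2 = sigma2_G / (sigma2_G + sigma2_GE / n_env + sigma2_e / (n_env * n_rep))

for the overall scope, and `sigma2_G / (sigma2_G + sigma2_e / n_rep)` per
environment, with `n_env` and `n_rep` as harmonic means over lines (cells)
under imbalance.  Design variances are excluded from the denominator: they
cancel from genotype-mean contrasts.  The standard error is the delta
method on the asymptotic covariance of the variance components (numeric
central-difference Hessian of the unprofiled restricted likelihood).  Traits
with H2 < 0.01 in an environment are flagged for exclusion from that
environment's downstream analysis.

### REML engine

All models above share one REML core.  The scaled covariance is
`V/sigma2_e = A + gamma_g Z Z'` with `A` block-diagonal by environment, so
each likelihood evaluation is a set of small per-environment factorizations
plus one Woodbury correction of dimension `n_lines`.  Two structured fast
paths matter in practice: the line-by-environment term is diagonal on
per-line plot groups within an environment (a second, analytic Woodbury
layer), and one-hot cell-means fixed effects make `X'V^-1 X` diagonal minus
a rank-`q` correction.  Both paths are verified against the generic dense
path to machine precision in the test suite.

The criterion is profiled over `sigma2_e` and optimized over log variance
ratios with bounded L-BFGS-B from the better of two fixed starts, then
polished by Nelder-Mead when tight convergence matters (the balanced-ANOVA
equivalence check requires ~1e-6 agreement).  Ratios pinned at the lower
bound are truncated to zero — the floor-during-optimization convention for
negative variance estimates.  A coordinate pinned at the upper bound is
accepted as a boundary solution (noiseless data make the restricted
likelihood unbounded; H2 then approaches 1).  Degenerate directions that
break a Cholesky factorization evaluate to +inf so the optimizer retreats;
an escalating-ridge fallback covers numerically semidefinite tail solves.

## Relationships and structure (`relatedness`)

Markers with minor allele frequency ≤ 0.05 *within the analyzed line set*
are removed (strict inequality; frequency is mean dosage / 2 folded at
0.5).  Missing dosages are mean-imputed per marker; columns are centered
and scaled by the sample (n−1) standard deviation — under that convention
`mean(diag(K)) = (n-1)/n` exactly for `K = W W'/m`, which the tests pin.
Structure correction uses the first five principal components of `K`
(eigenvectors scaled by the root eigenvalue, largest-magnitude loading made
positive for byte-stable output); the genomic inflation factor
`lambda_gc = median(chi2_1(1-p)) / 0.45494` is reported for 0–10 components
as a diagnostic so the five-component choice is reproducible, but p-values
are never genomic-control rescaled.

## Association and stability (`gwas`)

The scan is OLS of a line-mean trait on each marker plus the structure
covariates, two-sided t test on the marker coefficient; markers collinear
with the covariates are reported with missing p, counted, never dropped.
Benjamini–Hochberg is the classic step-up with missing p excluded from the
test count.  The RMIP screen draws 100 subsets of 80% of the lines (64 of
80 at the default panel size), re-filters MAF, re-standardizes and
recomputes the PCs within each subset (panel-wide PC reuse is available by
flag), scans, and applies BH at 20%, 5% and 1%; a marker's count is the
number of subsets that flagged it.  Hit identity is the marker id — no LD
clumping, since raw SNP–trait associations are the reporting unit.  A
marker is *stable* when detected (count ≥ 5 at FDR 20%) in at least three
environments; the full {FDR 20/5/1%} × {RMIP ≥ 5/≥ 25} grid is recorded for
every hit.

## Genomic prediction (`gblup`)

GBLUP uses the linear kernel `K` above with variance components by REML on
the spectral decomposition (one-dimensional profile in the ridge ratio
`delta = sigma2_e/sigma2_u`, bounded scalar search on `log delta`).  This
deterministic REML/ridge formulation targets the same estimand as a
Bayesian RKHS fit with a linear kernel (the posterior mean coincides with
BLUP under flat hyperpriors) and removes MCMC convergence ambiguity; a
Gibbs sampler is out of scope.  Held-out lines are predicted by the
conditional mean `K_cross (K_train + delta I)^-1 (y - Xb)`; the
masked-response Henderson solve is the internal test oracle, and
RR-BLUP with penalty `m * delta` is the exact-equivalence oracle.
Phenotypes are centered/scaled to mean 0, variance 1 with constants kept
from the training side only.  A GWAS hit enters as one fixed-effect column
of dosages standardized by training-set constants.

## Cross-validation (`crossval`)

Within-means CV: 100 random 80/20 line splits by default; each fold
re-filters markers for MAF > 0.05 in the training lines only, rebuilds the
kernel over train+test lines with that marker set, fits, predicts, and
records the Pearson correlation between predicted and observed test means —
the prediction ability, whose ceiling is sqrt(H2).  Between-environment CV
trains on the training lines' means in environment i and evaluates the
held-out lines' means in environment j for all ordered pairs (196 at 14
environments, diagonal = within-environment baseline); the same line folds
serve every pair within an iteration, and same-line train/test leakage is
excluded by construction.  Transfer is summarized by three strata of the
off-diagonal — same location/different year, same year/different location,
both different — each as a percent of the diagonal baseline, with the
easier-direction label decided by comparing the first two strata.
Augmentation re-runs the within-environment CV for each stable hit (only in
the environments it was detected in) with the hit as a fixed effect on
byte-identical folds, recording `delta r`; per threshold-grid cell the share
of improving hits is the summary surface.

Folds expand from one master seed through a counter, are hashed into the
results for replay verification, and degenerate folds (constant test means,
hit filtered out by MAF) are skipped and counted rather than propagated as
NaN.

## Problem sizes in the checks

The statistical acceptance tests run at the sizes the package treats as its
reference conditions: heritability recovery at 300 lines × 14 environments
× 2 replicates × 20 trait replicates per heritability level; the
prediction-ability ceiling at 300 lines × 3,000 markers × 3 panels; FDR
calibration over 200 simulated scans with an 80% null fraction; RMIP null
behavior at 5 × 100 resamples × 2,000 markers; transfer degradation and
threshold-grid enrichment on 60–70-line panels over 5 seeds and 8–15 CV
iterations.  The acceptance script reports every quantity from one
80-line / 2,000-SNP / 14-environment run with 100 RMIP resamples and
50 CV iterations.

## Known limitations

* The REML engine supports one crossed random factor; multi-trait and
  marker × environment models are out of scope.
* Delta-method standard errors are asymptotic; at variance boundaries
  (component estimated at zero) they degenerate with the estimate.
* Prediction ability on a 16-line test fold is noisy (sd across folds
  ~0.1–0.2); the per-iteration spread is reported for exactly that reason.
* The generator's G×E is exchangeable across environments; location- or
  year-specific correlation structure (e.g. weather) is not modeled, so
  transfer strata differ only by sampling noise unless the user injects
  structured effects.
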