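# Methods notes

This note documents the statistical machinery of `orchardgx`, the choices
made where the design was genuinely open, and what the synthetic data can
and cannot certify about behavior on real orchard data.

## The synthetic trial generator (`syndata`)

The generator emulates a clonally replicated reference population: a
diverse accession panel, an ancestor chain of configurable depth (default
five generations), and biparental progeny families, phenotyped as grafted
replicate trees in several location-year environments.

**Genotypes.**  Haplotype alleles come from a latent Gaussian AR(1) process
along each chromosome (autocorrelation `ld_rho`, default 0.9, between
adjacent markers) thresholded at the quantile of a per-marker allele
frequency drawn uniformly from `maf_range`.  This gives a single tunable LD
decay parameter; it is a stand-in for real LD maps, not a claim of fidelity
to any crop's demography.  Meiosis uses a Haldane model (Poisson crossovers,
no interference) at `recomb_rate_per_bp` (default 1e-8 Morgans/bp, i.e. 0.3
Morgans on a default 30-Mb chromosome).

**Phenotypes.**  Per tree,

    y = μ + env + g + gxe + spatial(row, col) + ε

with g = planted QTL part + polygenic tail.  Each variance component is
rescaled so its realized variance over trees equals the requested fraction
of a unit total exactly: QTL are spread out along the genome, the summed
QTL part is rescaled (residual LD between planted loci would otherwise
inflate it), and the polygenic tail is orthogonalized against the QTL part.
This makes variance bookkeeping assertable to ±0.05 at n ≥ 400.

**G×E deviations are marker-based.**  Deviations are environment-specific
polygenic effects — marker-effect vectors drawn with compound-symmetry
correlation `gxe_env_correlation` across environments — rather than iid
per-genotype noise.  Deviations without marker signal would be structurally
unpredictable for untested genotypes, and no interaction model could then
outperform the across-environment model under CV1; the marker-based
construction makes that qualitative ordering a testable property of the
generator while keeping the magnitude controllable.

**Spatial field.**  Two to four random Gaussian bumps plus linear
row/column gradients, rescaled to `spatial_field_sd`; smooth by
construction, so the adjustment stage can recover it.  The field is treated
as nuisance on top of the unit phenotypic variance, not as one of the trait
fractions.

**Skewed traits.**  `skewed=True` exponentiates the latent trait, so the
downstream natural-log transform recovers the additive scale exactly.  All
ground-truth components refer to the latent (log) scale.

What passing tests do *not* show: robustness to unbalanced replication,
missing plots, non-Gaussian residuals, dominance/epistasis, or selection —
none of which the generator produces.

## REML engine (`lmm`)

EM-REML on Henderson's mixed-model equations with Aitken acceleration every
four sweeps (a trial accelerated step is kept only if it does not decrease
the restricted likelihood).  Kernel-covariance random terms are rotated to
iid effects through the eigendecomposition of K (eigenvalues < 1e-8 of the
maximum dropped).  Convergence: relative change of the restricted
log-likelihood < 1e-10 and of the active parameters < 1e-7, max 500 sweeps;
components below 1e-5 of the response variance are treated as converged at
the zero boundary and reported as 0.  On balanced designs the estimates
match ANOVA closed forms to 1e-6, which the tests pin.  Call sites that
need only moderately converged components (the spline surface, the variance
decomposition) cap the sweep budget at 150–200.

## Spatial adjustment (`pheno`)

A low-rank tensor-product P-spline: cubic B-spline bases over rows and
columns (six segments each), second-order difference penalty in each
direction.  The penalty null space (linear row/column trends) is kept as a
*shrunken* random term rather than fixed effects, alongside the penalized
range whose REML variance acts as the smoothing parameter, jointly with
random genotype effects.  Shrinking the trends means a flat field yields an
(almost) identity adjustment — the package's contract — at the cost of
slightly conservative trend estimates.  Bit-compatibility with any published
spline package is not claimed; the contract is recovery of planted surfaces
(r > 0.9 in the tests) and identity on flat fields.  Grids smaller than
20 trees or 3 distinct rows/columns skip the surface.

Log-transformed traits: the library function `compute_clonal_values`
implements the adjust-then-log route and fails loudly on non-positive
adjusted values.  The pipeline instead logs skewed traits *before* spatial
adjustment, treating them as multiplicative; an additive spline correction
of a multiplicative trait can push small raw values below zero, and
adjusting on the log scale avoids that while keeping all later stages
unchanged.

## GWAS (`gwas`)

The scan iterates: (1) single-marker fixed-effect tests with the top two
principal components of the standardized marker matrix as covariates plus
the current pseudo-QTNs, where any pseudo-QTN in LD (r² ≥ 0.7) with the
tested marker — or the marker itself — is excluded from its covariate set;
(2) candidate pseudo-QTNs taken in p-value order under a greedy pairwise-LD
filter (r² < 0.7, at most min(50, n/10)); (3) the retained number chosen by
BIC over nested candidate sets; repeated until the set stabilizes (max 10
iterations).  Candidates must reach p < 1e-4 before they can become
covariates: the BIC's log-n penalty alone admits chance markers at p ≈ 0.01,
whose conditioned p-values are then selection-biased and generate false
clusters, while genuine QTL of a few percent of variance sit many orders of
magnitude below the entry bar.  Significance: p < α/m with m the number of
markers actually tested after the MAF ≥ 0.05 filter (both α and m are
reported).  Dosages are coded {0,1,2}; the 1–3 coding sometimes used for
the per-SNP R² regression is an affine shift and changes nothing.

Segment assignment uses left-closed thirds of the chromosome length
(estimated by the last marker's position); co-localization is
single-linkage with gaps strictly below 100 kb; allele-frequency dynamics
count the phenotype-increasing allele per pedigree generation, with
10×30-genotype resampling of the progeny group for a standard error.

## Gibbs samplers (`gp`, `multienv`)

All samplers work in the eigenbasis of their covariance kernel (one-time
eigendecomposition, eigenvalues < 1e-8 dropped) and impute masked
phenotypes by data augmentation, which keeps every full conditional
diagonal (or a small dense block).  Kronecker structures are never
materialized at n·r: the across-environment model samples one shared
genetic vector with an r-fold replicated likelihood; the interaction model
adds per-environment deviation vectors; the factor-analytic model samples
per-eigencomponent r-vectors with batched r×r linear algebra.

Priors (the originating analyses delegate these to a Bayesian regression
package without reporting them): scaled-inverse-χ² with 5 degrees of
freedom on every variance, scale chosen so the prior mode splits the
response variance 50/50 between the term and the residual (split further
across kernels/terms where several share it); inverse-Wishart with df = t+2
and identity scale for the unstructured t×t covariances; Gaussian with
variance 100 on factor loadings, first loading constrained positive for
identifiability.  The number of factor-analytic factors defaults to 1 and
is configurable.  A consequence worth knowing: on a trait with *no* genetic
signal the posterior mean of the genetic-variance share settles near 0.25
rather than 0 — the marginal posterior of a boundary variance keeps mass
away from zero under this standard prior (an REML oracle on the same data
returns exactly 0).  Null and heritable traits remain clearly separated and
BayesCπ's genomic heritability is unaffected (it recovers a planted h² of
0.5 within ±0.05 in the acceptance run).

BayesCπ uses a joint (indicator, effect) per-marker Gibbs update with a
numba-compiled inner loop; π is sampled from its Beta full conditional
under the uniform prior; genomic heritability is computed per retained
iteration as Vg/(Vg+Ve) with Vg the variance of the genetic values across
genotypes, then averaged.  The constant-response edge case returns the
zero fit directly.  The random-forest stage delegates to scikit-learn
(500 trees, mtry = ⌊m/3⌋, clamped to 1 with a warning below 3 markers) —
the contribution there is configuration, not algorithm.

Default chain settings are 12 000 iterations, thinning 5, burn-in 2000.
Repeated fits inside cross-validation loops use shorter chains (2500/500 in
the acceptance script, 1200–4000 in tests); posterior means of these
well-behaved conditionally-Gaussian models stabilize well before that, and
seed-to-seed agreement of the breeding values exceeds r = 0.99 in the
tests.

## Evaluation (`evaluation`)

Fold construction: the shuffled genotype list is split into k nearly equal
blocks; each repeat reshuffles independently with a sub-seed drawn from the
master seed.  Scenario masks: `main` blanks clonal values, CV1 blanks a
genotype's cells in every environment, CV2 in all but the reference
environments; ability is scored per predicted (non-reference) environment
on masked genotypes only.  Degenerate correlations (constant predictions or
fewer than 3 pairs) are reported missing and excluded from averages, with
counts logged.  Main-effect models default to 5×5 = 25 estimates; the
multi-environment repeat count is a configuration knob (the acceptance runs
use one repeat of the 5 folds per seed across 10 simulation seeds).

## Variance decomposition (`vardecomp`)

Environments enter as fixed effects; each significantly associated SNP as a
random 3-level dosage factor; genotype and genotype-by-environment as
further random terms.  The environment share is the variance of the fitted
values with all random effects zeroed — a descriptive rule, not an ANOVA
identity — so the residual is reported as the remainder.  SNP shares are
the variance across trees of the term's fitted values rather than the raw
REML component: the dosage factor is unbalanced, and the level-unweighted
component would overstate the explained share.  With only 3 levels these
components are noisy; constant SNPs are dropped with a warning and
estimates are clamped at zero.  SNP plus genotype shares sum to the
genotypic variance, which stays stable within ±0.05 when SNP terms are
removed.  Trait clustering: Ward (Ward.D2 on Euclidean distances) on the
centered/scaled profile table, dendrogram cut at the largest gap between
successive merge heights; at least 3 traits required.

## Pipeline and interfaces (`io`, `pipeline`, `cli`)

Text formats only: dosage TSV + marker-map CSV or a minimal GT-only VCF
(read via cyvcf2, multi-allelic sites skipped with a warning), long-format
phenotype CSV validated against the genotype ids with line-numbered errors,
pedigree and catalog CSV, YAML configuration, JSON manifests.  Environments
are keyed "LOCATION.YEAR"; marker positions are 1-based.  The pipeline
(adjust → heritability filter → clonal values → GWAS → prediction →
decomposition) persists every stage table, halts with the stage name on
failure while keeping prior outputs, and stamps a manifest with the
configuration, seed, package version and a content hash so a rerun with the
same inputs is verifiably identical.

## Problem sizes in the acceptance run

The acceptance script reports, per check, the population size it used:
oracle agreement at n = 300 with m = 2000; genomic-heritability recovery at
n = 500, m = 2000 over 10 seeds; variance decomposition at n = 400 in 4
environments over 10 seeds; the CV1 model-ordering and CV2-vs-CV1 checks at
n = 200, m = 1000, r = 4 over 10 seeds; GWAS recovery at n = 500, m = 5000
over 10 seeds.  These sizes were chosen as the smallest at which the
Monte-Carlo spread of each quantity is comfortably inside its assertion
band.

## Known limitations

* EM-REML is robust but slow near variance boundaries; the engine treats
  sub-1e-5 components as zero rather than polishing them.
* The spline adjustment assumes additive, smooth spatial effects on the
  (possibly log) trait scale and a complete row/column grid.
* The multi-locus scan is a faithful re-implementation of the quoted
  algorithmic sketch, not of any particular package; output identity with
  other implementations is not expected, planted-QTL recovery is.
* Multi-environment residuals are iid in the two G-BLUP variants
  (unstructured only in the factor-analytic model), and cross-environment
  genetic correlations are implicitly non-negative in the interaction
  model.
* Permanent non-genetic tree effects across years are not modeled anywhere.
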