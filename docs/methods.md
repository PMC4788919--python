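# Methods

This note documents the models implemented in `pleioscan`, the numerical
choices behind them, what the synthetic-cohort generator does and does
not emulate, and the design decisions taken where the problem was
genuinely open.

## Single-trait mixed model

Each trait is analysed under

y = Xb + s_i a_i + Zu + e, with u ~ N(0, A s2_a) and e ~ N(0, I s2_e).

`X` contains an intercept, dummy-coded categorical covariates (cohort,
sex, birth/rear type), centred numeric covariates (age), and the
pedigree-derived breed fractions with the last breed dropped against the
intercept. Aliased columns are removed by pivoted QR, so nested or
confounded factor levels do not break the fit. `A` is built by the
tabular method over the full pedigree (inbreeding accumulated exactly)
and subset to the phenotyped animals per trait.

Breed is handled as a fixed regression on breed fractions rather than a
random breed effect: at the cohort sizes this package targets, a random
breed variance is weakly identified, and the fixed regression removes
the same stratification. Optional extra random effects (maternal
permanent environment, sire-by-flock) are out of scope; the polygenic
term plus breed fractions carry the structure correction.

### REML

Variance components are estimated on the null model (no SNP) by
restricted maximum likelihood. With the eigendecomposition A = U D U',
the covariance V = s2 (h2 D + (1 - h2) I) is diagonal after rotating y
and X by U', so the profiled REML log-likelihood is evaluated in
O(n p^2) per candidate h2 and maximised by bounded scalar optimisation
(h2 in [1e-6, 1 - 1e-6], xatol 1e-8). Non-convergence is flagged on the
result, never raised. The eigendecomposition is the dominant cost
(~1.5 s at n = 2,000 on one CPU) and is cached and shared across traits
whose phenotyped-animal sets coincide.

### The association scan

The per-SNP pass holds the variance components fixed at their
null-model values and solves a generalized least-squares regression per
SNP (the two-stage strategy used by EMMAX-type software). The scan
whitens y, X and all SNP columns by V^(-1/2) (diagonal after rotation),
projects out X once via a QR decomposition, and computes every SNP's
effect and standard error with two matrix products. This deviates
deliberately from refitting the full mixed model per SNP: it is orders
of magnitude faster and asymptotically equivalent when per-SNP effects
are small, which is the regime of interest.

P-values use a Student t reference with the null-model residual degrees
of freedom (n - p - 1) — slightly conservative at small n, and
indistinguishable from the normal reference at cohort scale.

A SNP is flagged *inestimable* when the squared norm of its whitened,
X-projected dosage falls below 1e-10 of its unprojected squared norm
(constant SNPs, SNPs collinear with the covariates, and the lead SNPs
themselves under conditioning). Inestimable records carry NaN
statistics and are excluded listwise downstream.

Missing genotype dosages are mean-imputed per SNP before the scan; the
dosage is treated as a continuous covariate.

## Multi-trait statistic

For SNP i, chi2_i = t_i' V^{-1} t_i, where t_i stacks the signed
t-values across traits and V is the trait-by-trait Pearson correlation
of the t-values over all scanned SNPs. Under the null the t-values are
approximately jointly normal with correlation V (they share no
structure beyond the phenotypic correlation of the traits, which V
captures empirically), so chi2_i is chi-squared with df = number of
traits.

Choices:

* V is estimated over **all** SNPs, signal included — with a genome of
  SNPs the signal's contribution is diluted; an optional P-threshold
  exclusion exists but is off by default.
* SNPs inestimable in any trait are dropped listwise so df is constant
  across SNPs.
* If the correlation matrix's condition number exceeds 1e12, a ridge of
  1e-6 is added to the diagonal before inversion (many correlated
  traits can make V near-singular). The ridge actually applied is
  recorded on the `VMatrix`.
* The quadratic form is computed by Cholesky solve, not an explicit
  inverse.

## FDR estimator

FDR(P) = P (1 - A/T) / ((A/T)(1 - P)) for A of T tested SNPs
significant at threshold P. This is the expected false-positive count
P·(T - A_true) over the declared positives, rearranged under the
approximation that the A significant SNPs exhaust the true positives.
A = 0 makes the estimator undefined; the package returns +inf with a
warning rather than raising. A percent-rendering helper rounds to the
reporting precision.

## Lead SNPs and conditional analysis

Leads tag putatively independent pleiotropic QTL: per chromosome, SNPs
passing P <= 1e-5 are taken greedily in ascending P, accepting a SNP
only if it lies >= 4 Mb from every accepted lead on that chromosome, up
to three per chromosome. Ties in P break by genome order, so selection
is deterministic. The "visually distinct peaks" criterion sometimes
used for this task is not computable; the spacing rule alone
operationalises it.

Conditioning refits every per-trait scan with all leads as simultaneous
covariates and recomputes the multi-trait statistic. Each lead's own
conditional effect is its coefficient in the joint GLS regression
containing the other leads — computed directly from one multiple
regression per trait rather than one scan per lead, which is
algebraically identical and far cheaper.

Window-top selection (for validation) partitions each chromosome into
fixed half-open 1-Mb windows and keeps the minimum-P SNP per window if
it passes the threshold.

## Clustering effect patterns

Pairwise Pearson correlations of the leads' per-trait signed t-values
are clustered agglomeratively (average linkage by default) on distance
d = 1 - r, with the tree cut at k groups (default 5) and the dendrogram
order and a Newick export provided for heatmap rendering.

Because the sign of an effect vector depends on the arbitrary A/B
allele labelling, rows are sign-aligned first. A per-row rule (make the
largest-|t| entry positive) is not robust: two members of the same
pattern group whose largest effects happen to fall on different traits
can end up anti-correlated (r ~ -1), splitting real groups. The package
instead aligns signs greedily by correlation: the row with the largest
effect norm anchors the orientation (its largest entry made positive),
and each remaining row, taken in order of its strongest absolute
correlation with the already-aligned set, is flipped if that
correlation is negative; rows essentially orthogonal to everything
aligned (|r| < 0.3) keep their own max-entry-positive orientation.
After alignment the sign of r is biologically meaningful and 1 - r
(not 1 - |r|) is the right distance.

## Linear indices, missing-data fill, validation

For a SNP with per-trait effects b (trait units) and trait covariance C,
the index y_I = b' C^{-1} y maximises correlation with the SNP's
genotype when b and C are the regression quantities of the same data.
C is estimated as the covariance of per-trait SNP-effect estimates
across all scanned SNPs (an estimator of the genetic covariance among
traits); a phenotypic-covariance alternative gives the exactly-optimal
least-squares index and is what the optimality tests use.

Index construction needs complete trait records. Phenotypes are first
corrected for fixed effects (per-trait OLS; when a discovery/validation
split is active the coefficients are estimated on the discovery side
only and applied to both, so no validation information leaks), then
missing cells are filled with their conditional expectation given the
animal's observed traits under a joint normal with the estimated trait
covariance — computed per missing-pattern group via one symmetric solve
each. Animals with no observed traits are dropped with a warning.
Observed cells are never modified.

Validation splits are made at the sire-family level: sires are permuted
and dealt round-robin into five sets; all offspring of a sire share one
label, so the randomly chosen validation set contains no paternal half
sibs of any discovery animal (asserted on every split). One 4:1
division is used per run.

Validation of a discovery hit regresses the validation-side index on
the SNP with a polygenic animal effect (variance components
re-estimated for the index as a new trait) and compares the sign of the
effect with the discovery-side association. Reports count validated
SNPs at thresholds 1e-4, 1e-3, 0.01 and 0.05, with the FDR formula
applied at T = number of SNPs tested.

Index GWAS for group expansion scans the genome for each lead's index
with *all* leads fitted as covariates; SNPs reaching P < 5e-7 for at
least one index join the group of the lead with which they associate
most strongly.

## Candidate genes and cross-species overlap

Significant SNPs are thinned to one per 60-kb neighbourhood (greedy by
ascending P), then annotated with the nearest gene within +-30 kb
(distance to the nearest gene edge, zero inside the gene, strand
ignored); where several genes crowd a 2-Mb region only the nearest is
kept, and optionally a SNP with no gene in the window takes the single
nearest gene flagged `expanded`. BED input (0-based half-open) is
converted to the package's 1-based inclusive convention on read; GFF3
contributes `gene` features only.

The overlap permutation test counts (a) significant SNPs (default
P < 1e-3) within 30 kb of any target-list gene and (b) target genes hit
by at least one such SNP, then draws |target| genes uniformly without
replacement from the gene universe 1,000 times. The empirical P is
add-one corrected, (1 + #{permutations with both counts >= observed}) /
(n_perm + 1), so it is never zero; single-count P-values are also
reported. Sampling is uniform (no matching on gene length or SNP
density); length-matching is a known confounder left as an option for
the caller via a custom universe.

## The synthetic-cohort generator

The generator produces the data structure the analysis assumes, with
every ground-truth quantity recorded:

* **Pedigree** — `n_sires` founder sires x `n_dams_per_sire` dams x
  `n_offspring_per_dam` genotyped, phenotyped offspring (defaults
  100 x 4 x 5 = 2,000 offspring). Founders are purebred across
  `n_breeds` = 9 breeds; a dam crosses breeds with probability
  `breed_mixing` = 0.2, and offspring breed fractions are parental
  means. Family sizes are uniform — real cohorts have long-tailed
  family-size distributions, which is noted as a simplification.
* **Genotypes** — founder haplotypes from a first-order latent-uniform
  chain: each haplotype's latent uniform is carried to the next SNP
  with probability `ld_decay` = 0.7 and redrawn otherwise, preserving
  per-SNP allele frequencies (drawn from `maf_range` = (0.05, 0.5))
  while creating local LD; per-breed allele-frequency shifts
  (SD 0.1) create genuine stratification. Offspring arise by Mendelian
  gamete sampling with Poisson crossovers (mean 1 per 100 Mb).
  Defaults: 5,000 SNPs on five 100-Mb chromosomes.
* **QTL** — `n_qtl_groups` x `qtl_per_group` (default 3 x 3) SNPs with
  MAF >= 0.05, >= 4 Mb apart within a chromosome so lead selection can
  isolate them. Each group has a trait-effect template (by default
  mutually orthogonal random patterns, sparsified to ~2/3 of traits,
  RMS effect 0.2 trait SD); each QTL's effect vector is its template
  times a log-normal scalar (SD 0.2 on the log scale, settable to 0
  for exact effects) plus N(0, 0.02) jitter on the non-zero entries.
* **Phenotypes** — trait value = breed intercept + cohort + sex +
  birth/rear + age slope + QTL effects + polygenic value + residual.
  Polygenic values follow the pedigree (founders N(0, s2_poly),
  non-founders midparent plus Mendelian-sampling noise at half the
  founder variance), correlated across traits with the same correlation
  as the residuals (compound symmetry 0.3 by default). Per trait the
  polygenic variance is the target h2 minus the variance contributed by
  the planted QTL, and the residual variance is 1 - h2, so realized
  narrow-sense heritability matches the target (within +-0.05 at
  n >= 2,000, measured against fixed-effect-corrected phenotypic
  variance — fixed effects are not part of V_p). Default heritabilities
  span 0.05-0.50 across 12 traits. Missingness is MCAR per trait at
  `missing_rate` = 0.05.

Every stage draws from an independent stream derived from the master
seed, so a fixed seed gives bit-identical cohorts.

**What passing tests do and do not show.** The generator reproduces the
family, breed, LD and pleiotropy structure the method exploits, but not
sequence-level realism: no recombination hotspots, no genotyping or
imputation error, MCAR (not trait-dependent) missingness, uniform
family sizes, and exact multivariate-normal residuals. Tests passing on
these cohorts demonstrate the statistical machinery is correct and
calibrated under its own assumptions; they do not certify performance
under model misspecification in real data.

## Problem sizes used in the test suite

The statistical acceptance tests run the full pipeline at the cohort
size the method targets (2,000 phenotyped animals, 12 traits) with SNP
counts chosen per question: 5,000 SNPs for null calibration and lead
recovery, 2,000 for the power and clustering replicates, 1,000 for
index-recruitment replicates, and 400-600 for the 20-replicate
validation studies, where the genome size is irrelevant to the quantity
under test. Calibration and power tests use complete phenotypes so the
property being measured is not confounded with the missing-data fill;
the fill itself is tested separately. Per-trait calibration is asserted
via the median Kolmogorov-Smirnov P across traits (the minimum over
dozens of correlated KS tests would reject a calibrated scan ~30% of
the time); the multi-trait scan's KS and type-I checks are per seed.

## Known limitations

* Two-stage GLS understates the variance of large-effect SNPs compared
  with a full per-SNP refit; effects of a few per cent of phenotypic
  variance or more are better re-estimated jointly.
* The FDR estimator assumes the significant set captures all true
  positives; it is a coarse (though monotone and closed-form) summary.
* With per-trait missingness every distinct phenotyped-animal set costs
  its own A-matrix eigendecomposition; traits sharing records share the
  factorisation automatically.
* The multi-trait df equals the trait count even when V needs a ridge;
  with extremely redundant traits the test is slightly conservative.
* Uniform gene sampling in the overlap test ignores gene length and
  local SNP density.
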