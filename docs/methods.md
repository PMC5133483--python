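# Methods

`fameqtl` maps cis-acting expression quantitative trait loci (eQTLs) in
family samples, where relatedness makes ordinary regression invalid and
ordinary sample permutation destroys the null's correlation structure.
This note records the model, the procedure, the numerical choices, and what
the synthetic data generator does and does not emulate.

## The mixed model

For probe expression $Y_{ij}$ of individual $j$ in family $i$ and SNP
dosage $s_{ij}$ (count of the alternate allele, 0/1/2):

$$
Y_{ij} = \beta_0 + \beta_1\,\mathrm{age} + \beta_2\,\mathrm{sex}
       + \beta_3\,\mathrm{smoking} + \beta_4\,Pc_1 + \beta_5\,Pc_2
       + \beta_s\, s_{ij} + g_{ij} + \varepsilon_{ij}
$$

with a polygenic random effect $g \sim N(0,\ \sigma_g^2 K)$ and residual
$\varepsilon \sim N(0,\ \sigma_\varepsilon^2 I)$. $K = 2\Phi$ is the
expected additive relationship matrix from the pedigree kinship $\Phi$
(diagonal 1 for non-inbred individuals), block diagonal by family.
$Pc_1, Pc_2$ are the first two sample-score components of the per-probe
centred expression matrix, included to absorb batch structure.

We use $K = 2\Phi$ rather than $\Phi$ so that
$h^2 = \sigma_g^2/(\sigma_g^2+\sigma_\varepsilon^2)$ carries its standard
narrow-sense meaning. The simulator and the fitter use the **same** matrix,
so inference is self-consistent regardless of the scaling convention.

### REML and the rotation trick

Variance components are estimated by REML (preferred over ML for variance
estimation). Each family block of $K$ is eigendecomposed once per sample
set, $K = U\Lambda U^T$; rotating $y$ and the design by $U^T$ makes the
covariance diagonal, $\sigma_\varepsilon^2(\gamma\lambda_i + 1)$ with
$\gamma = \sigma_g^2/\sigma_\varepsilon^2$. $\beta$ (by GLS) and
$\sigma_\varepsilon^2$ are profiled out in closed form, leaving a 1-D
bounded Brent search over $\log\gamma \in [\log 10^{-6}, \log 10^{6}]$ at
tolerance $10^{-8}$. Boundary hits are reported on the fit object, not
raised. The rotation is computed once and reused across all probes, SNPs
and permutations; this is what makes the permutation stage affordable
(a full SNP fit costs well under a millisecond at $n = 300$).

The SNP coefficient is tested by a two-sided Wald test,
$(\beta_s/\mathrm{se})^2$ against $\chi^2_1$. Missing dosages are
mean-imputed per SNP at association time (counts logged); missing
covariates drop samples listwise.

## Kinship

$\Phi$ is computed by the standard recursion (founders unrelated,
$\phi_{ii} = \tfrac12(1+\phi_{fm})$,
$\phi_{ij} = \tfrac12(\phi_{fj}+\phi_{mj})$) with samples ordered
family-major, parents before offspring, so the matrix is literally block
diagonal and per-family eigendecompositions are exact. A Monte-Carlo
gene-dropping estimator (founder alleles uniquely labelled, transmitted
through the pedigree over replicate loci) serves as an independent oracle
in the tests. Genotyped individuals absent from the pedigree become
singleton founder blocks ($\phi = 0.5$ diagonal), logged.

## The cis scan

- **Window.** A SNP is cis to a probe if it lies on the same chromosome
  within 1 Mb of the transcript start **or** end (boundaries inclusive).
  A transcript-start-site-only window is available via
  `model.cis_anchor: tss` for users who prefer that convention.
- **Per-probe statistic.** The minimum raw Wald p over the probe's $N_g$
  cis SNPs, multiplied by the effective-tests factor $(N_g+1)/2$ and capped
  at 1. The factor approximates the effective number of tests among
  LD-correlated cis SNPs; it is applied as specified even though the gene
  dropper simulates linkage-equilibrium SNPs, where it is conservative.
- **MAF.** VCF reading filters minor allele frequency below 0.05 by
  default (configurable); the common-variant focus is the convention for
  scans at these sample sizes.

## Surrogate permutation null

Expression is often non-normal (the pipeline reports a per-probe
Shapiro-Wilk scan with Bonferroni flags), and naive permutation breaks the
familial correlation that the null must retain. The null here:

1. Estimate $h^2$ per probe from the covariates-only model; bin probes
   into seven fixed heritability bins with edges
   $\{0, .1, .2, .3, .4, .5, .6, 1\}$ (left-closed, last bin closed).
2. For each probe, draw a surrogate probe uniformly from its bin
   (excluding itself; with replacement across repeats) and reorder the
   probe's values by the surrogate's sample ranking — the sample holding
   the surrogate's rank-$r$ value receives the probe's rank-$r$ value,
   ties broken by sample index. The permuted vector keeps the probe's
   marginal distribution but carries the familial correlation pattern of a
   heritability-matched random transcript.
3. Rerun the probe's cis scan on the permuted phenotype, take the minimum
   adjusted p; repeat three times per probe; pool statistics per bin.
4. The observed adjusted p becomes an empirical p against its bin pool,
   $(r+1)/(B+1)$ with $r$ the count of null statistics at or below it —
   positive and valid by construction.
5. Benjamini-Hochberg at $q = 0.05$ across probe-level empirical p values
   flags eGenes. All cis SNPs of flagged probes whose own adjusted p
   reaches the same empirical threshold are reported as eSNPs, so one SNP
   can target several eGenes.

Bins too sparse to supply surrogates (fewer than two probes after the
$h^2$ estimate) are merged with adjacent bins, deterministically, before
permutation; the published per-bin summary keeps the original seven bins.

**Resolution.** The empirical p cannot go below $1/(B+1)$ where $B$ is
3 x (bin occupancy). At panel sizes in the hundreds of probes this floor
interacts with the BH threshold: detection requires the occupied bins to
hold enough probes. The planted-recovery scenario therefore concentrates
its panel in the top heritability bin (see below). At the panel sizes of a
real microarray study (tens of thousands of probes) the floor is orders of
magnitude below any plausible threshold.

## Enrichment

The tested-SNP universe is every SNP that entered any cis scan. eSNP
status is crossed with a binary annotation — membership in BED intervals
(e.g. DNase hypersensitive sites), or membership in a GWAS seed list
expanded to LD proxies (same chromosome, distance strictly under 1 kb,
dosage $r^2$ strictly above 0.9) — and tested by a two-sided Fisher exact
test (point-probability criterion), reported with the sample odds ratio
and the fold enrichment $(a/(a+b))/(c/(c+d))$. Zero margins yield p = 1
with the odds ratio flagged undefined.

The expression-to-trait scan fits the same mixed model with the trait as
response and one probe's expression as the focal predictor, adjusting for
the covariates, the expression PCs (kept for consistency with the eQTL
model) and the kinship random effect.

## Synthetic data generator

The generator emulates exactly the structure the analysis assumes:

- **Pedigrees**: repeated family units (default: founder couple + 4
  offspring, 50 families, $n = 300$; multigeneration structures
  available), family-major ordering.
- **Genotypes**: Mendelian gene drop; founder alleles i.i.d.
  Bernoulli(MAF), MAF ~ U(0.05, 0.5), SNPs evenly spaced on two synthetic
  250 Mb chromosomes (~133 kb spacing at the default densities, ~15 SNPs
  per 2 Mb cis window).
- **Expression**: per probe, fixed covariate effects (age ~ U(20, 80),
  sex from the pedigree, smoking ~ Bernoulli(0.5); small nonzero
  coefficients so adjustment is exercised), two latent batch factors with
  N(0, 0.3^2) per-probe loadings (recoverable by PCA), a polygenic term
  drawn per family block from $N(0, h^2\, 2\Phi)$, an optional single
  causal cis SNP, and i.i.d. Gaussian noise with
  $\sigma_g^2 + \sigma_\varepsilon^2 = 1$.
- **Effect scaling**: a causal SNP's $\beta_s$ is set so the SNP explains
  a requested fraction of the probe's total non-covariate variance
  (polygenic + noise + batch + SNP), making single-SNP regression $R^2$
  match that fraction in expectation.

Canonical scenarios (used by the tests and the acceptance script):

- `planted_eqtl_study`: 200 probes, 10% causal, SNP explains 20% of
  variance, $h^2 \sim U(0.6, 0.9)$. The high-heritability panel reflects
  the empirical observation that eGenes are predominantly a
  moderate-to-high-heritability class, and keeps the bin pool (the
  empirical-p resolution, above) adequate at 200 probes. Probes are
  megabases apart, so cis windows of distinct probes do not overlap —
  as for a sparse panel on a real genome; overlapping windows would let a
  surrogate's own strong cis signal leak into a target's null scan, an
  artefact of dense toy layouts rather than of the method.
- `global_null_study`: 500 probes, no causal SNPs, $h^2 \sim U(0, 0.9)$
  spanning all seven bins; used to verify per-bin uniformity of the
  empirical p and probe-level type-I error.

**Not emulated**: linkage disequilibrium between simulated SNPs (loci are
dropped independently, so the $(N_g+1)/2$ factor is conservative here);
array amplification/hybridisation noise beyond Gaussian error; inbreeding,
X-linked dosage, imprinting; multi-SNP or trans architecture. Passing
tests therefore demonstrate the statistical machinery under the model's
own assumptions, not robustness to array-specific artefacts.

## Numerical choices and degenerate inputs

- Variance-ratio search range $[10^{-6}, 10^6]$, Brent tolerance
  $10^{-8}$ on $\log\gamma$; residual sum of squares floored at
  $10^{-300}$ so noiseless responses fit cleanly with
  $\sigma_\varepsilon^2$ at the lower bound.
- Eigenvalues of $K$ clipped at 0 (tolerance $-10^{-8}$ before erroring).
- PCA sign fixed by making each component's largest-magnitude probe
  loading positive; constant expression matrices are an error.
- Rank-deficient designs error naming the collinear columns; constant
  probes are skipped (trait scan) or flagged non-testable (normality scan).
- Raw p-values are floored at $10^{-300}$ before the effective-tests
  multiplication; adjusted p capped at 1.
- One-parent-known pedigree records are rejected rather than
  auto-completed: explicit data errors should surface early.
- Chromosome names match exactly after stripping an optional `chr` prefix.

## Problem sizes

The test-suite and acceptance-script simulations use 50 six-member
families ($n = 300$, the few-hundred-sample scale typical of family
expression cohorts), 200-1000 probes and ~15 cis SNPs per probe. These
sizes make every Monte-Carlo check (kinship vs gene dropping at 200,000
loci, heritability recovery at 1000 probes, permutation calibration at 500
probes, planted recovery over multiple seeds) reproducible in minutes on
one CPU.

## Known limitations

- Significance resolution is bounded by the per-bin pool size (above);
  small panels need merged or well-occupied bins.
- A single variance component; dominance, shared-household and
  GRM-from-SNPs relatedness are out of scope.
- The Wald test is used for $\beta_s$; for very small samples or extreme
  MAF the likelihood-ratio test may differ (available on the fit object's
  REML log-likelihoods for cross-checking).
- No rank-based inverse-normal transformation: non-normality is handled by
  the permutation procedure instead.
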