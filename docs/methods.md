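# Methods

This note documents the statistical models, algorithms, defaults and
limitations of the package, in the order the pipeline runs them.

## Synthetic data generator

The generator exists so every downstream stage — QC, relationship
matrices, REML, prediction, cross-validation — can be exercised and tested
end to end without external data. It emulates a slaughter-cohort design
for purebred finishing pigs.

**Pedigree.** Discrete non-overlapping generations with random mating and
no selection: `n_founders` unrelated founders, then `n_generations`
rounds of `matings_per_generation` random sire x dam pairs (distinct
parents from the previous generation) with `offspring_per_mating`
offspring each. This is the simplest structure that yields a deep
pedigree in which every non-founder has both parents known, which is what
the numerator-relationship algebra assumes. The default profile
(1498 founders + 3 x 500 x 2) gives 4498 animals, matching the cohort
scale the package is designed around.

**Genotypes.** Unlinked SNPs are gene-dropped: founder alleles are drawn
independently at frequency p_j ~ Uniform(0.05, 0.95) per SNP; every
non-founder receives one allele per parent per SNP, chosen uniformly at
heterozygous sites. There is no linkage or LD, no mutation, and no
selection, so genotypes carry exactly the pedigree-expected relatedness:
E[genomic relationship] = A entry, which the tests exploit. Consequences:
passing tests demonstrate correctness of the matrix algebra and the
estimation machinery, not robustness to LD structure, assortative mating
or selection sweeps present in real livestock data.

**Phenotypes.** SNP effects are drawn N(0, sigma_a^2 / sum_j 2 p_j(1-p_j))
at the founder frequencies, so the true breeding values (centered genotype
rows times effects) have variance ~ h2_true * sigma_p_true on the same
scale the VanRaden G assumes — pedigree- and marker-based variance
components are then commensurable. Residuals are
N(0, (1 - h2_true) sigma_p_true). Fixed effects follow the slaughter-cohort
design: herd (5 levels), slaughter year (8), slaughter month (12), drawn
once per simulation from centered normals with SDs 1.5 / 1.0 / 0.5 trait
units (roughly the magnitude of management and seasonal effects on a
lightness-scale trait; explicit per-level vectors can be supplied), plus a
slaughter-weight-like covariate N(97.25, 8.78^2) entering centered with
slope 0.1. The default trait profile is lightness-like:
sigma_p^2 = 9.10, h2 = 0.45, intercept 49.24.

Phenotypes go to `n_phenotyped` (default 1237) animals drawn from the two
most recent generations; a `genotyped_fraction` (default 654/1237) of
those is retained in the genotype file, sampled uniformly at random —
the cohort design does not record how genotyped animals were chosen, so
uniform sampling is the neutral choice. Sex is not modelled: the fixed
part of the animal model contains no sex effect, so an all-female cohort
and an unsexed cohort are statistically identical here. Missing genotype
calls are injected uniformly at `missing_rate` (default 0.01).

All randomness flows through `numpy.random.SeedSequence(seed)` substreams,
so a configuration and seed reproduce every file byte for byte.

## Genotype quality control

Filters, in a fixed and reported order:

1. animals with call rate < 0.90 (sample-level missingness is removed
   before any SNP statistic is computed — the standard convention, and the
   package's inference for unexplained sample exclusions; the QC report
   header flags it as such);
2. SNPs with call rate < 0.90;
3. SNPs with minor allele frequency < 0.01, computed from observed calls;
4. SNPs with an exact Hardy-Weinberg test p-value < 1e-7.

All comparisons are strict, so a SNP exactly at a threshold survives. The
HWE test is the exact conditional test (Wigginton-style enumeration of
heterozygote counts given allele counts, two-sided by summing
probabilities no larger than the observed configuration's); a chi-square
approximation is useless at p = 1e-7 with rare alleles. The filter
cascade is idempotent, and each removal is recorded with its reason.

## Relationship matrices

* **A** by the tabular method, O(n^2) memory; diagonal 1 + F.
* **A^-1** assembled directly from Henderson's rules with
  Mendelian-sampling variances computed from Meuwissen-Luo inbreeding
  coefficients, so it is the exact inverse of the tabular A.
* **G** per VanRaden's first method. Centering frequencies default to the
  observed post-QC frequencies of the genotyped animals (base-population
  frequencies are generally unavailable); a frequency vector can be
  supplied. Residual missing calls are mean-imputed to 2p_j, which makes
  their centered contribution exactly zero.
* **Blending**: G* = (1 - omega) G + omega A22 with omega = 0.05 by
  default. Blending is required for H^-1 to exist when G is singular
  (duplicate genotypes, n_snps < n_animals); omega is configurable and
  logged. Rescaling G to A22 by the two-coefficient regression
  (matching mean diagonal and mean off-diagonal) is available behind a
  flag but off by default.
* **H^-1** = A^-1 plus the correction G*^-1 - A22^-1 on the genotyped
  block. H itself is never formed in the solvers; the explicit joint form
  appears only as a test oracle.

Everything is dense, sized for pedigrees up to a few thousand animals;
A^-1 is assembled from sparse triplets internally.

## Mixed-model solvers

Henderson's MME with lambda = sigma_e^2 / sigma_a^2, solved by dense
Cholesky. Fixed effects use reference coding (first level of each factor
dropped, intercept retained); residual rank deficiency is resolved by
dropping dependent columns found by pivoted QR, and the dropped names are
reported on the fit. Breeding values are returned for every animal in the
relationship structure, including unphenotyped ones.

Corrected phenotypes y_c = EBV + residual (= y - Xb-hat) are computed
**once**, from the full-data pedigree-BLUP fit, and reused as the fixed
response for all genomic prediction, including inside cross-validation.
Holding y_c fixed mirrors the standard two-step workflow, but it means
validation animals' phenotypes did participate in the fixed-effect
adjustment; this is a known, documented source of (mild) optimism shared
by both methods, so the GBLUP/ssGBLUP comparison remains fair.

GBLUP fits y_c = 1 mu + Zg + e with K = G* over genotyped animals only, an
overall mean being the only fixed effect — any remaining fixed-effect
signal already lives in y_c. ssGBLUP solves the identical model with
K^-1 = H^-1 over the whole pedigree, so non-genotyped phenotyped animals
join the reference population. Variance components for both prediction
methods come from the same full-data single-step AIREML fit, which keeps
the method comparison a relationship-matrix comparison rather than a
variance-component comparison.

## AIREML

Parameterised directly in (sigma_a^2, sigma_e^2). Because
V = R sigma_a^2 + I sigma_e^2 with R = ZKZ' fixed across iterations, R is
eigendecomposed once and every iteration works in the rotated basis where
V is diagonal: likelihood, score and average-information terms cost
O(n p^2). Updates are AI steps guarded by an EM-type fallback and step
halving whenever a step leaves the parameter space or decreases the
restricted likelihood, with a variance floor of 1e-8 * Var(y); accepted
iterations therefore never decrease the likelihood. Convergence is
declared at relative parameter change < 1e-8 (max 200 iterations);
initialisation splits Var(y) evenly. Standard errors come from the
inverse AI matrix at convergence; h^2 SEs use the first-order delta
method. Estimates pinned at the floor are flagged as boundary solutions
and their SE is reported as NaN. When the two components are not
separately identifiable (K = I), the AI matrix is singular; the guarded
steps still converge and the total sigma_p^2 remains correct.

## Cross-validation

Five replicates of five-fold partitions of the genotyped animals (fold
sizes differ by at most one), identical plans for both methods so the
comparison is paired. Per fold, validation y_c are removed from the
training response; GBLUP's reference is the remaining genotyped animals,
ssGBLUP's additionally includes every non-genotyped phenotyped animal.
Accuracy per replicate is sum(n_i r_i)/sum(n_i) / sqrt(h^2), reported as
mean +/- SE over the five replicate values. The sqrt(h^2) denominator is
the convention this weighted-accuracy statistic comes from; dividing by
h^2 itself is available as a sensitivity variant. The h^2 in the
denominator is the full-data single-step AIREML estimate and is logged
with every report. The bias slope (y_c on GEBV) is aggregated as the
n_i-weighted mean over all 25 fold cells with the SE taken over replicate
means — the aggregation is a package choice, since a single slope +/- SE
per trait/method admits several conventions. Folds with fewer than three
validation animals, or zero GEBV variance, are errors rather than NaNs.

## Problem sizes used in tests and the acceptance script

Tests run the same code paths at reduced scale — typically 120-500
pedigree animals for unit and property tests, 2000 phenotyped records for
REML parameter recovery, and 1200 phenotyped / ~600 genotyped for the
method-comparison runs — sizes at which the dense solvers complete in
seconds while leaving every algorithmic branch exercised. The default
configuration remains the full study-scale profile (4498 / 1237 / 654,
10k SNPs), which the CLI runs in a few minutes.

## Known limitations

* No LD, selection, overlapping generations, or non-additive effects in
  the generator; parameter-recovery results do not certify behaviour on
  real LD-structured data.
* Single-trait analyses only; no genetic-correlation estimation.
* Dense linear algebra throughout: pedigrees beyond ~5000 animals need
  sparse MME solvers this package does not provide.
* No metafounders, unknown-parent groups, or APY approximation of G^-1.
* Published variance-component tables this design emulates contain a few
  internally inconsistent rows for low-heritability sensory traits
  (component ratios that do not reproduce the printed heritability at the
  printed precision); such rows are not usable as worked-example checks
  and the package does not attempt to resolve them.
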