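# ssgblup

Single-step genomic evaluation for desk-scale animal-breeding datasets:
pedigree, genomic and combined relationship matrices; BLUP, GBLUP and
ssGBLUP breeding-value prediction; AIREML variance components and
heritability; genotype quality control; and replicated cross-validation of
prediction accuracy and bias — with a synthetic data generator so the whole
pipeline runs and is tested without any external data.

## Who this is for

Animal breeders and quantitative geneticists evaluating whether single-step
genomic prediction pays off in cohorts where only a fraction of the
phenotyped animals are genotyped — the typical situation for expensive
post-mortem traits (meat quality, sensory scores, fatty-acid composition)
measured on slaughtered animals. The package mirrors a Duroc pig evaluation
design: a pedigree of ~4500 animals, ~1200 phenotyped females, ~650
genotyped on a 60K SNP chip, and traits with heritabilities from 0.08 to
0.72.

## The model

Phenotypes follow the animal model

    y = Xb + Za + e,    a ~ N(0, K sigma_a^2),   e ~ N(0, I sigma_e^2)

with fixed effects b (herd, slaughter year, slaughter month and one
covariate) and additive genetic effects a whose covariance K is:

* **A** — the pedigree numerator relationship matrix (tabular method;
  A^-1 built directly by Henderson's rules with Meuwissen–Luo inbreeding);
* **G** — the VanRaden genomic relationship matrix,
  `G = (M - P)(M - P)' / sum_j 2 p_j (1 - p_j)`, blended as
  `(1-omega) G + omega A22` so it is invertible;
* **H** — the single-step combination, used through its inverse
  `H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]`.

Corrected phenotypes `y_c = EBV + residual` from a full-data pedigree-BLUP
fit are the response for the genomic models, which fit only an overall
mean. Variance components come from average-information REML; heritability
is `h^2 = sigma_a^2 / (sigma_a^2 + sigma_e^2)` with a delta-method SE.
Prediction is scored by five replicates of five-fold cross-validation over
the genotyped animals: accuracy is the n_i-weighted mean of
`r_i = corr(GEBV, y_c)` across folds divided by `sqrt(h^2)`, and dispersion
bias is the slope of the regression of y_c on GEBV (1 = unbiased).

## Worked example

```python
import ssgblup as ss

cfg = ss.SimConfig(n_founders=60, n_generations=2, matings_per_generation=40,
                   offspring_per_mating=2, n_snps=600, n_phenotyped=120,
                   genotyped_fraction=0.5, h2_true=0.45, sigma_p_true=9.10,
                   seed=3)
ped, _, phen, truth, geno_raw = ss.simulate_dataset(cfg)
geno, report = ss.apply_qc(geno_raw)          # call rate / MAF / exact HWE

A = ss.numerator_relationship(ped)
A_inv = ss.a_inverse(ped)
A22 = ss.a22_from_full(A, geno.ids)
G_star = ss.blend_g(ss.genomic_relationship(geno), A22, omega=0.05)
H_inv = ss.h_inverse(A_inv, A22, G_star, geno.ids)

vc = ss.aireml(phen, ss.ModelSpec(), A)
print(f"h2 = {vc.h2:.2f} +/- {vc.se_h2:.2f}")

fit = ss.solve_mme(phen, ss.ModelSpec(), A_inv, vc.sigma_a2, vc.sigma_e2)
yc = ss.corrected_phenotypes(fit)
gebv = ss.ssgblup(yc, H_inv, vc.sigma_a2, vc.sigma_e2).breeding_values
```

Running this prints `h2 = 0.65 +/- 0.20`: with only 120 records the REML
estimate of the simulated heritability (0.45) is within one SE of truth
but noisy — the default study-scale profile with 1237 phenotyped animals
brings the SE down to roughly 0.05.
`gebv` then holds single-step genomic breeding values for every pedigree
animal, genotyped or not.

The same run from the shell:

```bash
ssgblup run-all --config config.yaml --out run1 --seed 3
```

writes `variance_components.csv`, `breeding_values.csv`, `cv_report.csv`
(accuracy, bias slope and % improvement of ssGBLUP over GBLUP) and a
`manifest.json` tying every output to the config and seed.

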