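# Example pipeline configuration (ssgblup run-all --config docs/example-config.yaml
# --out run1 --seed 3).  Omitted keys take the defaults shown in docs/methods.md;
# the sim block below is a reduced-scale profile that completes in seconds.
sim:
  n_founders: 200
  n_generations: 3
  matings_per_generation: 120
  offspring_per_mating: 2
  n_snps: 2000
  founder_freq_range: [0.05, 0.95]
  h2_true: 0.45
  sigma_p_true: 9.10
  n_phenotyped: 450
  genotyped_fraction: 0.53
  missing_rate: 0.01
  seed: 3
qc:
  min_snp_call_rate: 0.90
  min_maf: 0.01
  hwe_p_min: 1.0e-7
  min_animal_call_rate: 0.90
omega: 0.05
tune_g_to_a22: false
cv_k: 5
cv_replicates: 5
accuracy_denominator: sqrt_h2
export_matrices: false
seed: 3
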