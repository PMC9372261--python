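# Example end-to-end pipeline configuration for `modmod all --config ...`.
#
# Stages run in dependency order; omit "power" (the slow stage) for a quick
# run.  Every stochastic stage derives its randomness from `seed`.

stages: [simulate, score, screen, fit, slopes]
outdir: modmod_out
seed: 1

# Positive-screen threshold on the depression total (kept if >= threshold).
screen_threshold: 5

# Confidence level for coefficient intervals.
ci_level: 0.95

# Replicates per grid point when the power stage is enabled.
power_reps: 1000

# Synthetic cohort generator.  Omitted fields fall back to the package
# defaults, which emulate the screened freshman survey the analysis targets.
generator:
  n_respondents: 2359
  noise_sd: 0.8
  female_fraction: 0.5965
  # latent correlations among (IS, PsyCap, FS)
  latent_correlations:
    - [1.000, -0.361, -0.286]
    - [-0.361, 1.000, 0.229]
    - [-0.286, 0.229, 1.000]
  # b0..b7 of the generating three-way interaction equation
  true_coefficients: [-0.058, 0.343, -0.006, -0.106, -0.033, -0.032, 0.011, 0.076]
  scale_means: {dep: 7.909, is: 14.442, psycap: 102.107, fs: 13.895}
  scale_sds: {dep: 3.147, is: 6.148, psycap: 13.064, fs: 4.833}
  # fraction of records corrupted per exclusion class
  contamination: {incomplete: 0.02, straight_line: 0.015, patterned: 0.012}
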