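# Collider scenario: 50 outcome-associated SNPs and a causal effect of the
# outcome on the later exposure (Y -> X2 = 0.5); the later exposure has no
# direct effect on the outcome.
scenario_id: collider
n_snps: 150
n_outcome_snps: 50
effect_variance_total: 0.1
effect_corr:
- [1.0, 0.25]
- [0.25, 1.0]
maf_range: [0.05, 0.5]
beta1: 0.2
beta2: 0.0
beta3: 0.0
gamma12: 0.1
gamma23: 0.0
delta_y2: 0.5
confounder_corr: 0.8
confounder_effect_x: 0.3
confounder_effect_y: 0.3
# X2's residual is smaller here because the Y -> X2 feedback already
# contributes ~0.37 of X2's unit variance
noise_sd_x: [0.935, 0.627]
noise_sd_y: 0.7
n_exposure_sample: 150000
n_outcome_sample: 150000
n_reps: 2000
seed: 2022
p_threshold: 5.0e-08
apply_steiger: true
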