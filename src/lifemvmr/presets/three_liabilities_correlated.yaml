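# Three liability periods; only X1 and X2 are included in the estimation.
# Third-period genetic effects correlated with the included periods
# (rho(L2,L3)=0.25, rho(L1,L3)=0.1).
scenario_id: three_liabilities_correlated
n_snps: 150
n_outcome_snps: 0
effect_variance_total: 0.1
effect_corr:
- [1.0, 0.25, 0.1]
- [0.25, 1.0, 0.25]
- [0.1, 0.25, 1.0]
maf_range: [0.05, 0.5]
beta1: 0.2
beta2: 0.3
beta3: 0.2
gamma12: 0.1
gamma23: 0.1
delta_y2: 0.0
confounder_corr: 0.8
confounder_effect_x: 0.3
confounder_effect_y: 0.3
noise_sd_x: [0.935, 0.912, 0.92]
noise_sd_y: 0.7
n_exposure_sample: 150000
n_outcome_sample: 150000
n_reps: 2000
seed: 2022
p_threshold: 5.0e-08
apply_steiger: false
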