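# Methods

## The liability model

The simulator implements a lifecourse exposure model in which the genetic
signal acts through period-specific *liabilities*. For `l` independent
biallelic SNPs in Hardy-Weinberg equilibrium (allele counts
`g_j ~ Binomial(2, maf_j)`, MAF drawn uniformly on [0.05, 0.5]), each
liability is an exact linear function of the genotypes, `L_k = G π_k`,
with no non-genetic component: all environmental variation enters at the
exposure level. Per-SNP liability effects are multivariate normal with
per-liability variance `v/l` (total explained-effect budget `v = 0.1`) and
a configurable cross-period correlation matrix (default ρ = 0.25 between
adjacent periods).

Structural equations (two-period default):

    X1 = L1 + c U1 + e1
    X2 = γ12 X1 + L2 + c U2 + e2
    Y  = β1 X1 + β2 X2 + d (U1 + U2) + eY

with standardised confounders U jointly normal at correlation 0.8, one per
exposure period, each also loading on the outcome. Defaults
β1 = 0.2, β2 = 0.3, γ12 = 0.1. Scenario variants:

* **one_liability** — both exposures load on a single liability, so the
  genetic associations of the two exposure measurements differ only by
  estimation noise (the conditionally-weak-instrument case);
* **collider** — the outcome has its own 50 SNPs
  (effects N(0, 0.1/50)) and feeds into the later exposure
  (`X2 += 0.5·Y`, with β2 = 0), making X2 a collider once conditioned on;
* **three_liabilities_correlated / _independent** — a third period
  (γ23 = 0.1, β3 = 0.2, chosen so the implied totals are exactly
  0.232 for X1 and 0.320 for X2) is simulated but excluded from the
  estimation, with its genetic effects either correlated with the
  included periods (ρ(L2,L3) = 0.25, ρ(L1,L3) = 0.1) or independent.

Two cohorts are simulated independently from the same population: the
*exposure sample* supplies all SNP-exposure associations (and the
instrument selection), the *outcome sample* only the SNP-outcome
associations — the standard two-sample summary-data design.

### Calibration of unstated constants

Confounder loadings are c = d = 0.3. Exposure residual SDs
(0.935, 0.912, 0.920) put each exposure's variance at ≈ 1, and the outcome
residual SD 0.7 keeps outcome-association standard errors on the scale of
published simulation reports. These constants control the absolute
instrument strength (mean univariable F ≈ 90, conditional F ≈ 50-55, and
≈ 85 of 150 SNPs genome-wide significant at n = 150,000 in the
two-liability scenario); diagnostics of that kind are therefore
calibration-dependent and the tests treat them as scale checks, not as
point targets. All constants are ordinary config fields.

## Estimators

IVW-MVMR solves the weighted least-squares problem
`Γ̂_j = Σ_k β_k π̂_kj + ε_j` without intercept, weights `w_j = 1/σ̂²_Γj`,
via an SVD-guarded QR solve; a numerically collinear design raises a
dedicated error naming the exposures. Coefficient covariances are
`φ (X'WX)^{-1}` with the multiplicative over-dispersion
`φ = max(1, Q/(k−K))` — the usual IVW convention of never deflating below
the fixed-effect variance. Confidence intervals are normal-theory
(±1.96 SE). With one exposure the fit reduces to univariable IVW and, for
a single SNP, to the Wald ratio; the univariable strength statistic is the
mean per-SNP `(π̂/se)²`.

**Conditional F.** The per-exposure conditional instrument strength is the
Q-based fixed-effect construction: regress the target exposure's
associations on the other exposures' associations and divide the weighted
residual sum of squares by its degrees of freedom, `F = Q_x/(k−K+1)`. The
weights are the inverse variance of the fitted *residual*
`π̂_t − Σ_o b_o π̂_o`, which involves the covariance of the estimation
errors across exposures; because all exposures are measured in one sample
those errors correlate (approximately at the phenotypic correlation), and
ignoring the covariance inflates the null value of the statistic well
above 1 (to ≈1.45 under this model's calibration). The coefficients and
weights are profiled by a short fixed-point iteration (5 rounds, far past
convergence). The error-correlation matrix is an optional argument; the
simulation pipeline estimates it from the exposure cohort, and the
file-driven interface defaults to independence (the information is rarely
published). No heterogeneity adjustment is applied; the function is
isolated so an adjusted variant can be swapped in.

**Q-statistic.** `Q = Σ_j w_j (Γ̂_j − Σ_k β̂_k π̂_kj)²` on `k−K` degrees of
freedom, the standard summary-data pleiotropy screen.

**Steiger filtering.** Summary-level variance explained is approximated by
`r² = z²/(z²+n)`; an instrument is dropped when it explains more variance
in the outcome than in the designated exposure. In the collider scenario
the designated exposure is the later period (the collider); univariable
fits filter against their own exposure.

## Instrument selection

Genome-wide significance `p < 5×10⁻⁸` in the exposure sample; univariable
mode selects on the single exposure, multivariable mode takes the union
over exposures. Monomorphic SNPs are flagged and excluded. Selection in
the same sample that supplies π̂ deliberately reproduces the winner's-curse
/ weak-instrument behaviour of the published simulation design.

## Truths for bias and coverage

Structural direct effects are read off the configuration. The
liability-effect estimands (what the estimators converge to, used as the
coverage reference) come from a probability-limit oracle: draw true SNP
effects, form the noiseless SNP-trait associations and exact trait
covariances implied by the structural equations (every trait is linear in
independent sources, so moments propagate in closed form), simulate the
selection step on noisy z-statistics at the configured sample size
(errors correlated across exposures within the shared sample), and solve
the weighted least-squares estimand on the selected *true* associations,
averaging over draws. In the collider scenario the outcome-SNP block is
excluded from the oracle so the truths refer to genuine liability
instruments. Where a closed-form identity exists it is used instead of
Monte Carlo: in the two-liability, one-liability and collider scenarios
the MVMR estimand equals the structural direct effects exactly
(conditioning on the other included exposure absorbs every mediated path),
independent of confounding and noise. For the excluded-liability scenarios
the MVMR truths carry the leakage term and come from the oracle.

The univariable estimand in the two-liability scenario has its own
closed form, `(β1 + γ12 β2) + β2 ρ`, which selection leaves unchanged
(selection acts on π1 alone and E[π2 π1 | sel] = ρ E[π1² | sel] under
joint normality); the oracle reproduces it to Monte-Carlo precision and is
cross-checked against brute-force large-n simulated estimation in the
tests.

## Study runner and problem sizes

One repetition = draw effects → simulate both cohorts → per-SNP simple
linear-regression GWAS → select → fit univariable MR per exposure and the
joint MVMR. For the collider preset the same data are estimated twice,
without and with Steiger filtering, and both panels are reported.
Aggregation over repetitions reports mean estimate, mean estimated SE,
simulation SE (SD across repetitions), mean absolute bias, empirical 95%
CI coverage, mean (conditional) F and mean instrument count; repetitions
with no significant instrument are skipped and counted.

Determinism: each repetition seeds its own generator from
`(master seed, rep_index)`, so replay is bit-identical and independent of
execution order or the joblib worker count (asserted in the tests).

The bundled presets carry the full published scale (2000 repetitions, two
cohorts of n = 150,000). The test suite and the acceptance script run 200
repetitions at n = 150,000: reducing only the repetition count leaves the
estimand and every per-repetition distribution untouched and inflates
Monte-Carlo error on means to ≈ 0.001-0.005, whereas reducing the cohort
size would change the object under study — instrument counts fall by half
and weak-instrument attenuation roughly triples at n = 50,000, which is
itself demonstrated in the tests as a property of the method, not used as
a reporting scale. The excluded-liability scenarios use 100 repetitions
(only orderings and leakage margins are asserted there).

## File-driven estimation

The applied interface reads the conventional tab-separated summary format
(`SNP effect_allele other_allele eaf beta se pval N`), intersects SNPs
across one outcome and K exposures, aligns alleles to the first exposure's
convention (sign-flipping swapped records), drops strand-ambiguous
palindromic SNPs (A/T, G/C with eaf in [0.42, 0.58] or missing) and keeps
per-SNP provenance. Missing eaf on a non-palindromic SNP is retained with
a warning — eaf only disambiguates palindromes. Harmonisation is
idempotent, and file round-trips preserve all numeric columns exactly
(`%.17g` formatting, round-trip float parsing). Odds-ratio output for
binary outcomes is a display transform (exponentiation of estimate and CI)
only. Inputs are assumed LD-clumped; clumping, covariate-adjusted or
logistic GWAS, and pleiotropy-robust estimators (Egger, median) are out of
scope.

## What the simulations do and do not show

The generator matches the published simulation design: independent SNPs
(no LD), continuous traits, linear effects, homogeneous effects across
individuals, exposures measured without error correlated with genotype,
and non-overlapping samples from one population. Passing tests therefore
demonstrate the estimators' behaviour under that design — consistency
with genetically distinct periods, the direction-flipping
weak-instrument bias with a shared liability, collider bias from
outcome-associated instruments and its removal by Steiger filtering,
excluded-period leakage scaling with genetic correlation. They do not
speak to LD structure, population stratification, binary traits,
sample overlap or selection bias in real GWAS data.

## Known limitations

* The conditional-F and heterogeneity statistics use fixed-effect
  weighting; heterogeneity-adjusted variants are not implemented.
* In the collider scenario, Steiger filtering removes — correctly, by its
  own rule — a handful of genuine liability SNPs per repetition whose
  later-period association happens to sit near zero (they really do
  explain more outcome than later-exposure variance through the early
  period). At this package's instrument-strength calibration that trims
  the filtered early-period mean to ≈0.183 rather than the ≈0.195 a
  stronger-instrument calibration produces; the later-period coefficient,
  the coverage restoration and the instrument-count reduction are
  unaffected. The corresponding reproduction check documents this gap
  rather than recalibrating around it.
* Absolute instrument-strength diagnostics (mean F, selected SNP counts)
  depend on the unstated residual-variance calibration; only their
  qualitative regimes (≫10 vs ≈1) are design-independent.
* The file-driven mode trusts the input's SNP identities (no strand
  inference beyond allele matching) and assumes pre-clumped variants.
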