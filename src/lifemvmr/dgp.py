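"""Liability-model data generation and probability-limit truths.

The generative model: each exposure time period has an unobserved genetic
liability ``L_k = G @ pi_k`` that is an exact linear function of the
genotypes (liabilities carry no non-genetic noise).  Per-SNP liability
effects are multivariate normal with per-liability variance
``effect_variance_total / n_snps`` and a cross-period correlation matrix.
Exposures are the liability plus confounding and residual noise, with an
effect of the earlier exposure on the later one; the outcome is a linear
function of the exposures plus shared confounding.  In the collider
scenario the outcome additionally has its own SNPs and feeds back into the
later exposure.

Because every trait is linear in independent sources (genotypes,
confounders, residuals), population moments — true per-allele SNP-trait
associations, trait variances and covariances — are available in closed
form for any drawn effect table.  :func:`plim_truth` uses those moments to
compute the probability limits of the univariable-MR and MVMR estimands
under power-consistent instrument selection, which serve as the coverage
truths for the simulation reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import (COLLIDER, ONE_LIABILITY, THREE_CORRELATED,
                     THREE_INDEPENDENT, TWO_LIABILITIES, ScenarioConfig)
from .errors import ConfigError

__all__ = [
    "SnpEffectTable", "Cohort", "TruthValues",
    "draw_snp_effects", "simulate_cohort",
    "true_associations", "trait_covariance", "total_effects", "plim_truth",
]


# ----------------------------------------------------------------------
@dataclass
class SnpEffectTable:
    """True per-SNP effects on the period-specific liabilities.

    ``pi`` has one column per liability; ``pi_y`` holds direct SNP effects
    on the outcome (collider scenario only, zero otherwise).  The first
    ``n_snps`` rows are liability SNPs, any remaining rows are the
    outcome-SNP block.
    """

    snp_ids: np.ndarray
    maf: np.ndarray
    pi: np.ndarray          # (m, n_liabilities)
    pi_y: np.ndarray        # (m,)
    is_outcome_snp: np.ndarray  # (m,) bool

    def __post_init__(self):
        m = len(self.snp_ids)
        if not (len(self.maf) == self.pi.shape[0] == len(self.pi_y)
                == len(self.is_outcome_snp) == m):
            raise ValueError("inconsistent SnpEffectTable row counts")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_liabilities(self) -> int:
        return self.pi.shape[1]

    def liability_effects(self, k: int) -> np.ndarray:
        return self.pi[:, k]

    def to_frame(self) -> pd.DataFrame:
        d = {"snp": self.snp_ids, "maf": self.maf}
        for k in range(self.n_liabilities):
            d[f"pi{k + 1}"] = self.pi[:, k]
        d["pi_y"] = self.pi_y
        d["is_outcome_snp"] = self.is_outcome_snp
        return pd.DataFrame(d)


@dataclass
class Cohort:
    """One simulated sample: genotypes plus all generated variables."""

    genotypes: np.ndarray            # (n, m) int8, allele counts 0/1/2
    traits: dict                     # name -> (n,) array (X1, X2[, X3], Y)
    liabilities: np.ndarray          # (n, n_liabilities)
    confounders: np.ndarray          # (n, n_confounders)
    snp_ids: np.ndarray
    sample_label: str
    _gf: np.ndarray | None = None    # cached float64 genotype matrix

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def genotypes_float(self) -> np.ndarray:
        if self._gf is None:
            self._gf = self.genotypes.astype(np.float64)
        return self._gf


@dataclass
class TruthValues:
    """Coverage references for one scenario.

    ``direct`` are the structural direct effects; ``mr_liability`` and
    ``mvmr_liability`` are the liability-effect probability limits of the
    univariable-MR and MVMR estimands (per estimated exposure).
    """

    exposures: tuple
    direct: dict
    mr_liability: dict
    mvmr_liability: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "exposure": list(self.exposures),
            "direct_effect": [self.direct[e] for e in self.exposures],
            "mr_liability_effect": [self.mr_liability[e] for e in self.exposures],
            "mvmr_liability_effect": [self.mvmr_liability[e] for e in self.exposures],
        })


# ----------------------------------------------------------------------
def draw_snp_effects(config: ScenarioConfig, rng: np.random.Generator) -> SnpEffectTable:
    """Draw true per-SNP liability effects and MAFs for one repetition.

    Liability effects are zero-mean multivariate normal with per-liability
    variance ``effect_variance_total / n_snps`` and correlation
    ``effect_corr``; outcome-SNP effects (collider scenario) are drawn
    independently with variance ``effect_variance_total / n_outcome_snps``.
    """
    l, m = config.n_snps, config.total_snps
    per_snp_var = config.effect_variance_total / l
    R = config.effect_corr_matrix
    try:
        chol = np.linalg.cholesky(R + 1e-12 * np.eye(len(R)))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - validate() guards
        raise ConfigError("effect_corr is not positive semi-definite") from exc

    pi = np.zeros((m, config.n_liabilities))
    z = rng.standard_normal((l, config.n_liabilities))
    pi[:l] = np.sqrt(per_snp_var) * (z @ chol.T)

    pi_y = np.zeros(m)
    if config.n_outcome_snps:
        var_y = config.effect_variance_total / config.n_outcome_snps
        pi_y[l:] = np.sqrt(var_y) * rng.standard_normal(config.n_outcome_snps)

    maf = rng.uniform(*config.maf_range, size=m)
    snp_ids = np.array([f"snp{i:04d}" for i in range(m)])
    is_outcome = np.zeros(m, dtype=bool)
    is_outcome[l:] = True
    return SnpEffectTable(snp_ids=snp_ids, maf=maf, pi=pi, pi_y=pi_y,
                          is_outcome_snp=is_outcome)


# ----------------------------------------------------------------------
def _confounder_count(config: ScenarioConfig) -> int:
    return config.n_exposures


def _confounder_chol(config: ScenarioConfig) -> np.ndarray:
    nU = _confounder_count(config)
    R = np.full((nU, nU), config.confounder_corr)
    np.fill_diagonal(R, 1.0)
    return np.linalg.cholesky(R + 1e-12 * np.eye(nU))


def simulate_cohort(effects: SnpEffectTable, config: ScenarioConfig,
                    sample_label: str, rng: np.random.Generator) -> Cohort:
    """Simulate one cohort under the scenario's structural equations.

    Genotypes are independent biallelic SNPs in Hardy-Weinberg equilibrium
    (allele counts ~ Binomial(2, maf)); liabilities are exact linear
    functions of the genotypes; confounders are standardised jointly-normal
    variables shared between each exposure and the outcome.
    """
    n = (config.n_exposure_sample if sample_label == "exposure"
         else config.n_outcome_sample)
    m = config.total_snps
    # allele count ~ Binomial(2, maf) via the HWE genotype probabilities
    # (p^2, 2p(1-p), (1-p)^2) and a single inverse-CDF uniform per entry
    u = rng.random((n, m), dtype=np.float32)
    p = effects.maf.astype(np.float32)
    thr_hom = p * p
    thr_het = thr_hom + 2.0 * p * (1.0 - p)
    G = (u < thr_hom).astype(np.int8)
    G += u < thr_het
    Gf = G.astype(np.float64)
    L = Gf @ effects.pi                      # (n, n_liabilities)

    U = rng.standard_normal((n, _confounder_count(config))) @ _confounder_chol(config).T
    c = config.confounder_effect_x
    d = config.confounder_effect_y
    sds = config.noise_sd_x

    traits: dict = {}
    X1 = L[:, 0] + c * U[:, 0] + sds[0] * rng.standard_normal(n)
    traits["X1"] = X1

    if config.scenario_id == COLLIDER:
        # outcome realised before the later exposure, which it feeds into
        Y = (config.beta1 * X1 + Gf @ effects.pi_y
             + d * U.sum(axis=1) + config.noise_sd_y * rng.standard_normal(n))
        X2 = (config.gamma12 * X1 + L[:, 1] + config.delta_y2 * Y
              + c * U[:, 1] + sds[1] * rng.standard_normal(n))
        traits["X2"] = X2
        traits["Y"] = Y
    else:
        L2 = L[:, 0] if config.scenario_id == ONE_LIABILITY else L[:, 1]
        X2 = (config.gamma12 * X1 + L2 + c * U[:, 1]
              + sds[1] * rng.standard_normal(n))
        traits["X2"] = X2
        if config.n_exposures == 3:
            X3 = (config.gamma23 * X2 + L[:, 2] + c * U[:, 2]
                  + sds[2] * rng.standard_normal(n))
            traits["X3"] = X3
        Y = d * U.sum(axis=1) + config.noise_sd_y * rng.standard_normal(n)
        for beta, name in zip(config.betas, config.exposure_names):
            Y = Y + beta * traits[name]
        traits["Y"] = Y

    return Cohort(genotypes=G, traits=traits, liabilities=L, confounders=U,
                  snp_ids=effects.snp_ids, sample_label=sample_label, _gf=Gf)


# ----------------------------------------------------------------------
# Closed-form moments: every trait is linear in independent sources
# (genotypes, confounders, per-trait residuals), so loadings propagate
# through the structural equations exactly.
@dataclass
class _Loadings:
    s: np.ndarray   # per-SNP genotype loadings (m,)
    u: np.ndarray   # confounder loadings (nU,)
    e: np.ndarray   # residual loadings, basis order (e_X1, e_X2[, e_X3], e_Y)


def _trait_loadings(effects: SnpEffectTable, config: ScenarioConfig) -> dict:
    m = config.total_snps
    nU = _confounder_count(config)
    nE = config.n_exposures + 1
    c, d = config.confounder_effect_x, config.confounder_effect_y
    sds = config.noise_sd_x

    def blank():
        return _Loadings(np.zeros(m), np.zeros(nU), np.zeros(nE))

    def add(dst: _Loadings, src: _Loadings, coef: float):
        dst.s += coef * src.s
        dst.u += coef * src.u
        dst.e += coef * src.e

    pi = effects.pi
    out: dict = {}
    X1 = blank()
    X1.s += pi[:, 0]
    X1.u[0] = c
    X1.e[0] = sds[0]
    out["X1"] = X1

    if config.scenario_id == COLLIDER:
        Y = blank()
        add(Y, X1, config.beta1)
        Y.s += effects.pi_y
        Y.u += d
        Y.e[-1] = config.noise_sd_y
        X2 = blank()
        add(X2, X1, config.gamma12)
        add(X2, Y, config.delta_y2)
        X2.s += pi[:, 1]
        X2.u[1] += c
        X2.e[1] += sds[1]
        out["X2"], out["Y"] = X2, Y
        return out

    X2 = blank()
    add(X2, X1, config.gamma12)
    X2.s += pi[:, 0] if config.scenario_id == ONE_LIABILITY else pi[:, 1]
    X2.u[1] = c
    X2.e[1] = sds[1]
    out["X2"] = X2
    if config.n_exposures == 3:
        X3 = blank()
        add(X3, X2, config.gamma23)
        X3.s += pi[:, 2]
        X3.u[2] = c
        X3.e[2] = sds[2]
        out["X3"] = X3
    Y = blank()
    for beta, name in zip(config.betas, config.exposure_names):
        add(Y, out[name], beta)
    Y.u += d
    Y.e[-1] = config.noise_sd_y
    out["Y"] = Y
    return out


def true_associations(effects: SnpEffectTable, config: ScenarioConfig) -> pd.DataFrame:
    """Noiseless per-allele SNP-trait associations implied by the model."""
    loadings = _trait_loadings(effects, config)
    return pd.DataFrame({name: ld.s for name, ld in loadings.items()},
                        index=effects.snp_ids)


def trait_covariance(effects: SnpEffectTable, config: ScenarioConfig) -> pd.DataFrame:
    """Exact population covariance matrix of the generated traits."""
    loadings = _trait_loadings(effects, config)
    names = list(loadings)
    nU = _confounder_count(config)
    RU = np.full((nU, nU), config.confounder_corr)
    np.fill_diagonal(RU, 1.0)
    gvar = 2.0 * effects.maf * (1.0 - effects.maf)
    V = np.empty((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            la, lb = loadings[a], loadings[b]
            V[i, j] = (np.sum(gvar * la.s * lb.s) + la.u @ RU @ lb.u
                       + la.e @ lb.e)
    return pd.DataFrame(V, index=names, columns=names)


def total_effects(config: ScenarioConfig) -> dict:
    """Path-tracing total effects of each measured exposure on the outcome."""
    betas = config.betas
    if config.n_exposures == 3:
        t3 = betas[2]
        t2 = betas[1] + config.gamma23 * t3
        t1 = betas[0] + config.gamma12 * t2
        return {"X1": t1, "X2": t2, "X3": t3}
    t2 = betas[1]
    t1 = betas[0] + config.gamma12 * t2
    return {"X1": t1, "X2": t2}


# ----------------------------------------------------------------------
def plim_truth(config: ScenarioConfig, n_effect_draws: int = 30,
               n_noise_draws: int = 40, seed: int | None = None) -> TruthValues:
    """Probability limits of the MR and MVMR estimands under selection.

    One oracle run: draw true per-SNP effects, form the noiseless SNP-trait
    associations and their asymptotic standard errors at the configured
    exposure sample size, simulate the instrument-selection step on noisy
    z-statistics (power-consistent selection, with estimation errors
    correlated across exposures within the shared exposure sample), and
    solve the weighted least-squares estimands exactly on the selected
    *true* associations.  Averaging over effect and selection draws gives
    the estimand probability limits.

    In the collider scenario the outcome-SNP block is excluded: the
    liability-effect truths refer to the genuine liability instruments.
    For the scenarios whose MVMR estimand is the structural direct effect
    (two distinct liabilities, one liability, collider) the closed-form
    identity is used for ``mvmr_liability`` instead of the Monte-Carlo
    oracle.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0x7E57,)))
    zcrit = stats.norm.isf(config.p_threshold / 2.0)
    exposures = list(config.estimated_exposures)
    K = len(exposures)
    n_exp = config.n_exposure_sample

    # the MVMR estimand follows the closed-form identity except in the
    # excluded-liability scenarios (and the identity case is exactly
    # collinear on true associations, so the solve is skipped there)
    need_mvmr_oracle = config.scenario_id not in (TWO_LIABILITIES,
                                                  ONE_LIABILITY, COLLIDER)
    mr_sums = {e: [] for e in exposures}
    mvmr_sums: list = []
    for _ in range(n_effect_draws):
        effects = draw_snp_effects(config, rng)
        keep = ~effects.is_outcome_snp
        A = true_associations(effects, config)
        cov = trait_covariance(effects, config)
        gvar = 2.0 * effects.maf * (1.0 - effects.maf)

        a_exp = A[exposures].to_numpy()[keep]            # (l, K)
        a_out = A["Y"].to_numpy()[keep]
        w = gvar[keep]                                   # 1/var(Gamma-hat) up to a constant

        # asymptotic SEs of the exposure associations and the correlation of
        # their estimation errors within the shared exposure sample
        var_exp = np.array([cov.loc[e, e] for e in exposures])
        se = np.sqrt(np.maximum(var_exp[None, :] - a_exp ** 2 * w[:, None], 1e-12)
                     / (n_exp * w[:, None]))
        z_true = a_exp / se
        Ce = cov.loc[exposures, exposures].to_numpy()
        Cr = Ce / np.sqrt(np.outer(np.diag(Ce), np.diag(Ce)))
        chol = np.linalg.cholesky(Cr + 1e-10 * np.eye(K))

        for _ in range(n_noise_draws):
            noise = rng.standard_normal(z_true.shape) @ chol.T
            sel = np.abs(z_true + noise) > zcrit         # (l, K)
            union = sel.any(axis=1)
            for k, e in enumerate(exposures):
                s = sel[:, k]
                if s.sum() >= 1:
                    ws = w[s]
                    mr_sums[e].append(np.sum(ws * a_exp[s, k] * a_out[s])
                                      / np.sum(ws * a_exp[s, k] ** 2))
            if need_mvmr_oracle and union.sum() >= K + 1:
                Xs = a_exp[union]
                Ws = w[union]
                XtW = Xs.T * Ws
                mvmr_sums.append(np.linalg.solve(XtW @ Xs, XtW @ a_out[union]))

    direct = dict(zip(config.exposure_names, config.betas))
    mr_liability = {e: float(np.mean(v)) if v else np.nan
                    for e, v in mr_sums.items()}
    if config.scenario_id in (TWO_LIABILITIES, ONE_LIABILITY, COLLIDER):
        # exact identity: conditioning on the other included exposure removes
        # all mediated paths, so the MVMR estimand is the structural direct
        # effect (0 for the later period in the collider scenario)
        mvmr_liability = {e: direct[e] for e in exposures}
    else:
        est = np.mean(np.array(mvmr_sums), axis=0)
        mvmr_liability = {e: float(est[k]) for k, e in enumerate(exposures)}

    return TruthValues(exposures=tuple(exposures),
                       direct={e: direct[e] for e in exposures},
                       mr_liability=mr_liability,
                       mvmr_liability=mvmr_liability)
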