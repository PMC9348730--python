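"""Data-generating process: effect draws, cohorts, moments, plim truths."""

import numpy as np
import pytest

import lifemvmr as lm
from lifemvmr.dgp import trait_covariance, true_associations


class TestDrawSnpEffects:
    def test_effect_variance_targets_total(self):
        """Sum over SNPs of per-SNP effect variance equals the total (0.1)."""
        cfg = lm.preset("two_liabilities")
        sums = []
        rng = np.random.default_rng(0)
        for _ in range(200):
            eff = lm.draw_snp_effects(cfg, rng)
            sums.append(np.sum(eff.pi[:, 0] ** 2))
        assert np.mean(sums) == pytest.approx(0.1, rel=0.02)

    def test_cross_period_effect_correlation(self):
        """Empirical corr of (pi1, pi2) matches the configured rho=0.25."""
        cfg = lm.preset("two_liabilities").scaled(n_sample=1000)
        cfg = cfg.scaled()  # no-op; keep preset rho
        rng = np.random.default_rng(1)
        p1, p2 = [], []
        for _ in range(700):  # 700 x 150 > 1e5 draws
            eff = lm.draw_snp_effects(cfg, rng)
            p1.append(eff.pi[:, 0])
            p2.append(eff.pi[:, 1])
        r = np.corrcoef(np.concatenate(p1), np.concatenate(p2))[0, 1]
        assert r == pytest.approx(0.25, abs=0.01)

    def test_independent_effects_uncorrelated(self):
        cfg = lm.preset("two_liabilities", effect_corr=((1.0, 0.0), (0.0, 1.0)))
        rng = np.random.default_rng(2)
        p = np.concatenate([lm.draw_snp_effects(cfg, rng).pi for _ in range(700)])
        r = np.corrcoef(p[:, 0], p[:, 1])[0, 1]
        assert abs(r) < 0.01

    def test_outcome_snp_block(self):
        eff = lm.draw_snp_effects(lm.preset("collider"), np.random.default_rng(3))
        assert eff.is_outcome_snp.sum() == 50
        assert np.all(eff.pi[eff.is_outcome_snp] == 0.0)
        assert np.all(eff.pi_y[~eff.is_outcome_snp] == 0.0)
        assert np.all(eff.pi_y[eff.is_outcome_snp] != 0.0)

    def test_maf_within_range(self, small_effects, small_config):
        lo, hi = small_config.maf_range
        assert np.all((small_effects.maf >= lo) & (small_effects.maf <= hi))


class TestSimulateCohort:
    def test_liabilities_exact_linear_in_genotypes(self, small_cohort,
                                                   small_effects):
        """L - G @ pi vanishes elementwise: liabilities carry no noise."""
        recon = small_cohort.genotypes_float() @ small_effects.pi
        assert np.array_equal(recon, small_cohort.liabilities)

    def test_genotype_values_and_hwe(self, small_cohort, small_effects):
        G = small_cohort.genotypes
        assert set(np.unique(G)) <= {0, 1, 2}
        n = G.shape[0]
        freq = G.mean(axis=0) / 2.0
        se = np.sqrt(small_effects.maf * (1 - small_effects.maf) / (2 * n))
        assert np.all(np.abs(freq - small_effects.maf) < 5 * se)
        # HWE: heterozygote share close to 2p(1-p)
        het = (G == 1).mean(axis=0)
        p = small_effects.maf
        assert np.all(np.abs(het - 2 * p * (1 - p)) < 6 * np.sqrt(
            2 * p * (1 - p) / n) + 1e-9)

    def test_null_model_has_no_exposure_outcome_association(self):
        """All structural coefficients zero -> X1 and Y uncorrelated."""
        cfg = lm.preset("two_liabilities").scaled(
            n_sample=20_000, beta1=0.0, beta2=0.0, gamma12=0.0,
            confounder_effect_x=0.0, confounder_effect_y=0.0)
        rng = np.random.default_rng(4)
        eff = lm.draw_snp_effects(cfg, rng)
        eff.pi[:] = 0.0
        coh = lm.simulate_cohort(eff, cfg, "exposure", rng)
        n = coh.n_individuals
        r = np.corrcoef(coh.traits["X1"], coh.traits["Y"])[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_gamma12_recovered_by_oracle_regression(self):
        """Regressing X2 on X1, L2, U2 (latents included) recovers 0.1."""
        cfg = lm.preset("two_liabilities").scaled(n_sample=200_000, seed=5)
        rng = np.random.default_rng(5)
        eff = lm.draw_snp_effects(cfg, rng)
        coh = lm.simulate_cohort(eff, cfg, "exposure", rng)
        X = np.column_stack([coh.traits["X1"], coh.liabilities[:, 1],
                             coh.confounders[:, 1],
                             np.ones(coh.n_individuals)])
        coef, *_ = np.linalg.lstsq(X, coh.traits["X2"], rcond=None)
        assert coef[0] == pytest.approx(cfg.gamma12, abs=0.01)

    def test_samples_are_independent(self):
        """Exposure- and outcome-sample association errors are uncorrelated."""
        cfg = lm.preset("two_liabilities").scaled(n_sample=3000)
        err_exp, err_out = [], []
        for rep in range(25):
            ss = np.random.SeedSequence(99, spawn_key=(rep,))
            r0, r1, r2 = [np.random.default_rng(c) for c in ss.spawn(3)]
            eff = lm.draw_snp_effects(cfg, r0)
            a = true_associations(eff, cfg)
            ce = lm.simulate_cohort(eff, cfg, "exposure", r1)
            co = lm.simulate_cohort(eff, cfg, "outcome", r2)
            se_ = lm.stats_for(lm.run_gwas(ce, ["X1"]), "X1")
            so_ = lm.stats_for(lm.run_gwas(co, ["Y"]), "Y")
            err_exp.append(se_["beta"].to_numpy() - a["X1"].to_numpy())
            err_out.append(so_["beta"].to_numpy() - a["Y"].to_numpy())
        r = np.corrcoef(np.concatenate(err_exp), np.concatenate(err_out))[0, 1]
        assert abs(r) < 0.05

    def test_collider_feedback_enters_later_exposure(self):
        """Outcome SNPs associate with X2 through the Y -> X2 path."""
        cfg = lm.preset("collider")
        eff = lm.draw_snp_effects(cfg, np.random.default_rng(6))
        a = true_associations(eff, cfg)
        outcome = eff.is_outcome_snp
        expected = cfg.delta_y2 * eff.pi_y[outcome]
        assert a["X2"].to_numpy()[outcome] == pytest.approx(expected)


class TestAnalyticMoments:
    def test_covariance_matches_simulation(self, small_config):
        """Closed-form trait covariance agrees with a simulated cohort."""
        rng = np.random.default_rng(10)
        cfg = small_config.scaled(n_sample=150_000)
        eff = lm.draw_snp_effects(cfg, rng)
        coh = lm.simulate_cohort(eff, cfg, "exposure", rng)
        V = trait_covariance(eff, cfg)
        T = np.column_stack([coh.traits[t] for t in V.index])
        emp = np.cov(T, rowvar=False)
        assert np.allclose(emp, V.to_numpy(), atol=0.02)

    def test_true_associations_match_large_sample_gwas(self):
        cfg = lm.preset("two_liabilities").scaled(n_sample=400_000)
        rng = np.random.default_rng(11)
        eff = lm.draw_snp_effects(cfg, rng)
        coh = lm.simulate_cohort(eff, cfg, "exposure", rng)
        est = lm.stats_for(lm.run_gwas(coh, ["X2"]), "X2")["beta"].to_numpy()
        a = true_associations(eff, cfg)["X2"].to_numpy()
        assert np.allclose(est, a, atol=0.012)

    def test_total_effects_path_tracing(self):
        """Composite paths: X1 total = b1 + g12*(b2 + g23*b3), X2 total = b2 + g23*b3."""
        tot = lm.total_effects(lm.preset("three_liabilities_correlated"))
        assert tot["X1"] == pytest.approx(0.232)
        assert tot["X2"] == pytest.approx(0.320)
        tot2 = lm.total_effects(lm.preset("two_liabilities"))
        assert tot2["X1"] == pytest.approx(0.23)
        assert tot2["X2"] == pytest.approx(0.30)


class TestPlimTruth:
    def test_mvmr_truth_is_structural_in_two_liability_scenario(self):
        tr = lm.plim_truth(lm.preset("two_liabilities"), n_effect_draws=5,
                           n_noise_draws=5)
        assert tr.mvmr_liability["X1"] == pytest.approx(0.2)
        assert tr.mvmr_liability["X2"] == pytest.approx(0.3)

    def test_collider_mvmr_truth_later_period_zero(self):
        tr = lm.plim_truth(lm.preset("collider"), n_effect_draws=5,
                           n_noise_draws=5)
        assert tr.mvmr_liability["X2"] == 0.0
        assert tr.mvmr_liability["X1"] == pytest.approx(0.2)

    def test_univariable_plim_matches_brute_force_large_n(self):
        """Oracle plims agree with a brute-force simulated estimation.

        At n=300,000 a single repetition's MR estimates are within a few
        simulation SEs of the estimand; the oracle value must sit inside
        that band for both exposures.
        """
        cfg = lm.preset("two_liabilities").scaled(n_sample=300_000, seed=17)
        tr = lm.plim_truth(cfg, n_effect_draws=40, n_noise_draws=40)
        reps = [lm.run_repetition(cfg, i) for i in range(3)]
        for e in ("X1", "X2"):
            est = np.mean([r.mr[e].estimate[0] for r in reps])
            assert est == pytest.approx(tr.mr_liability[e], abs=0.035)
        # and the closed-form unconditional slope for the early exposure:
        # (beta1 + gamma12*beta2) + beta2*rho, selection-invariant
        closed = (cfg.beta1 + cfg.gamma12 * cfg.beta2) + cfg.beta2 * 0.25
        assert tr.mr_liability["X1"] == pytest.approx(closed, abs=0.02)

    def test_one_liability_univariable_plims(self):
        """Shared liability: slopes are exactly (b1+g*b2+b2) and that /(1+g)."""
        cfg = lm.preset("one_liability")
        tr = lm.plim_truth(cfg, n_effect_draws=10, n_noise_draws=10)
        expect_x1 = cfg.beta1 + cfg.gamma12 * cfg.beta2 + cfg.beta2
        assert tr.mr_liability["X1"] == pytest.approx(expect_x1, abs=0.01)
        assert tr.mr_liability["X2"] == pytest.approx(
            expect_x1 / (1 + cfg.gamma12), abs=0.01)
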