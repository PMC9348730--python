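"""IVW MR/MVMR estimators and diagnostics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import lifemvmr as lm

# 5-SNP two-exposure fixture used by several oracle comparisons
PI = np.array([[0.12, 0.02], [-0.08, 0.10], [0.05, -0.06],
               [0.20, 0.07], [-0.03, -0.11]])
GAMMA = np.array([0.05, 0.02, -0.01, 0.07, -0.04])
SE_GAMMA = np.array([0.010, 0.012, 0.008, 0.015, 0.011])
SE_PI = np.full_like(PI, 0.01)


class TestIvwMvmr:
    def test_noiseless_two_regressor_identity(self):
        """Gamma = 0.23*pi1 + 0.3*pi2 with pi_X2 = 0.1*pi1 + pi2 -> (0.2, 0.3).

        The total effect 0.23 = 0.2 + 0.1*0.3 decomposes exactly into the
        direct effects once the later exposure is conditioned on.
        """
        rng = np.random.default_rng(0)
        pi1 = rng.normal(0, 0.03, 40)
        pi2 = rng.normal(0, 0.03, 40)
        gamma = 0.23 * pi1 + 0.3 * pi2
        X = np.column_stack([pi1, 0.1 * pi1 + pi2])
        fit = lm.ivw_mvmr(X, gamma, np.full(40, 0.01))
        assert fit.estimate == pytest.approx([0.2, 0.3], abs=1e-12)
        assert fit.q == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_wls(self):
        """Coefficients and (unscaled) SEs match an independent WLS solve."""
        w = 1.0 / SE_GAMMA ** 2
        fit = lm.ivw_mvmr(PI, GAMMA, SE_GAMMA, exposure_se=SE_PI)
        ref = sm.WLS(GAMMA, PI, weights=w).fit()
        assert fit.estimate == pytest.approx(ref.params, abs=1e-12)
        # explicit normal equations as a second, fully independent route
        XtW = PI.T * w
        beta = np.linalg.solve(XtW @ PI, XtW @ GAMMA)
        assert fit.estimate == pytest.approx(beta, abs=1e-12)
        q = float(np.sum(w * (GAMMA - PI @ beta) ** 2))
        cov = max(1.0, q / (5 - 2)) * np.linalg.inv(XtW @ PI)
        assert fit.se == pytest.approx(np.sqrt(np.diag(cov)), abs=1e-12)
        assert fit.q == pytest.approx(q, abs=1e-12)
        assert fit.q_df == 3

    def test_collinear_design_raises(self):
        X = np.column_stack([PI[:, 0], 2.0 * PI[:, 0]])
        with pytest.raises(lm.SingularDesignError):
            lm.ivw_mvmr(X, GAMMA, SE_GAMMA)

    def test_too_few_instruments_raises(self):
        with pytest.raises(lm.NoInstrumentsError):
            lm.ivw_mvmr(PI[:2], GAMMA[:2], SE_GAMMA[:2])

    def test_ci_is_normal_theory(self):
        fit = lm.ivw_mvmr(PI, GAMMA, SE_GAMMA)
        assert fit.ci_low == pytest.approx(fit.estimate - 1.96 * fit.se,
                                           abs=1e-4)
        assert fit.ci_high == pytest.approx(fit.estimate + 1.96 * fit.se,
                                            abs=1e-4)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_weight_rescaling_invariance(self, c):
        """Multiplying all outcome SEs by a constant leaves estimates alone."""
        fit1 = lm.ivw_mvmr(PI, GAMMA, SE_GAMMA)
        fit2 = lm.ivw_mvmr(PI, GAMMA, np.sqrt(c) * SE_GAMMA)
        assert fit2.estimate == pytest.approx(fit1.estimate, rel=1e-9)


class TestIvwMr:
    def test_single_instrument_is_wald_ratio(self):
        fit = lm.ivw_mr([0.08], [0.01], [0.024], [0.005])
        assert fit.estimate[0] == pytest.approx(0.024 / 0.08, abs=1e-15)
        assert fit.se[0] == pytest.approx(0.005 / 0.08, abs=1e-12)

    def test_three_snp_wls_oracle(self):
        x = np.array([0.10, 0.15, 0.08])
        y = np.array([0.031, 0.044, 0.022])
        ose = np.array([0.004, 0.006, 0.005])
        w = 1.0 / ose ** 2
        beta = np.sum(w * x * y) / np.sum(w * x * x)
        fit = lm.ivw_mr(x, np.full(3, 0.01), y, ose)
        assert fit.estimate[0] == pytest.approx(beta, abs=1e-12)
        assert fit.f_stat == pytest.approx(np.mean((x / 0.01) ** 2))

    def test_equal_weights_single_exposure_reduces_to_mvmr(self):
        fit_mr = lm.ivw_mr(PI[:, 0], SE_PI[:, 0], GAMMA, SE_GAMMA)
        fit_mv = lm.ivw_mvmr(PI[:, [0]], GAMMA, SE_GAMMA)
        assert fit_mr.estimate == pytest.approx(fit_mv.estimate, abs=1e-14)
        assert fit_mr.se == pytest.approx(fit_mv.se, abs=1e-14)


class TestConditionalF:
    def test_hand_computed_four_snp_fixture(self):
        """Step-by-step weighted residual sum of squares, k=4, K=2.

        With exact (zero-error) regressor associations the residual
        variance is the target's own, so the statistic reduces to the
        plainly hand-computable weighted regression form.
        """
        pi = np.array([[0.10, 0.05], [0.08, 0.01], [-0.02, 0.04],
                       [0.06, -0.03]])
        se = np.array([[0.02, 0.0], [0.01, 0.0], [0.02, 0.0],
                       [0.01, 0.0]])
        w = 1.0 / se[:, 0] ** 2
        slope = np.sum(w * pi[:, 1] * pi[:, 0]) / np.sum(w * pi[:, 1] ** 2)
        q_x = np.sum(w * (pi[:, 0] - slope * pi[:, 1]) ** 2)
        expect = q_x / (4 - 2 + 1)
        assert lm.conditional_f(pi, se, 0) == pytest.approx(expect, abs=1e-12)

    def test_near_one_when_no_conditional_signal(self):
        """Duplicate columns plus estimation noise -> F near its null value.

        Both columns measure the same underlying associations with
        independent errors; the residual-variance weighting makes the
        statistic pivot to ~1 under the null.
        """
        rng = np.random.default_rng(3)
        pi1 = rng.normal(0, 0.05, 4000)
        se = np.full((4000, 2), 0.01)
        vals = []
        for _ in range(5):
            X = np.column_stack([pi1 + rng.normal(0, 0.01, 4000),
                                 pi1 + rng.normal(0, 0.01, 4000)])
            vals.append(lm.conditional_f(X, se, 0))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_correlated_errors_handled_via_exposure_corr(self):
        """Shared-sample error correlation keeps the null statistic at ~1."""
        rng = np.random.default_rng(4)
        pi1 = rng.normal(0, 0.05, 4000)
        rho = 0.6
        se = np.full((4000, 2), 0.01)
        vals = []
        for _ in range(5):
            e1 = rng.standard_normal(4000)
            e2 = rho * e1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(4000)
            X = np.column_stack([pi1 + 0.01 * e1, pi1 + 0.01 * e2])
            vals.append(lm.conditional_f(
                X, se, 0, exposure_corr=[[1.0, rho], [rho, 1.0]]))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_requires_two_exposures_and_enough_instruments(self):
        with pytest.raises(lm.UndefinedStatisticError):
            lm.conditional_f(PI[:, [0]], SE_PI[:, [0]], 0)
        with pytest.raises(lm.UndefinedStatisticError):
            lm.conditional_f(PI[:1], SE_PI[:1], 0)


class TestQStatistic:
    def test_zero_for_perfect_fit(self):
        beta = np.array([0.2, 0.3])
        y = PI @ beta
        q, df = lm.q_statistic(beta, PI, y, SE_GAMMA)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert df == 3

    def test_permutation_invariance(self):
        beta = np.array([0.15, 0.25])
        q1, _ = lm.q_statistic(beta, PI, GAMMA, SE_GAMMA)
        perm = np.array([3, 0, 4, 2, 1])
        q2, _ = lm.q_statistic(beta, PI[perm], GAMMA[perm], SE_GAMMA[perm])
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_term_by_term_hand_computation(self):
        beta = np.array([0.1, 0.2])
        expect = sum((1.0 / SE_GAMMA[j] ** 2)
                     * (GAMMA[j] - PI[j] @ beta) ** 2 for j in range(5))
        q, df = lm.q_statistic(beta, PI, GAMMA, SE_GAMMA)
        assert q == pytest.approx(expect, rel=1e-12)


class TestSteigerFilter:
    @staticmethod
    def make_stats(z, n):
        snps = [f"snp{i:04d}" for i in range(len(z))]
        return pd.DataFrame({
            "beta": np.asarray(z, float) * 0.01, "se": 0.01,
            "pval": 0.5, "n": n,
        }, index=pd.Index(snps, name="snp"))

    def test_dominant_outcome_snp_removed(self):
        exp = self.make_stats([2.0], 1000)
        out = self.make_stats([10.0], 1000)
        inst = lm.InstrumentSet(snps=["snp0000", ], selected_for={})
        with pytest.raises(lm.NoInstrumentsError):
            lm.steiger_filter(exp, out, inst)

    def test_toy_table_matches_exhaustive_comparison(self):
        z_exp = [6.0, 2.0, 5.0, 9.0, 1.0, 4.0]
        z_out = [3.0, 4.0, 5.5, 2.0, 0.5, 4.0]
        n_exp, n_out = 2000, 1000
        exp = self.make_stats(z_exp, n_exp)
        out = self.make_stats(z_out, n_out)
        inst = lm.InstrumentSet(snps=list(exp.index), selected_for={})
        result = lm.steiger_filter(exp, out, inst)
        keep = [f"snp{i:04d}" for i in range(6)
                if z_out[i] ** 2 / (z_out[i] ** 2 + n_out)
                <= z_exp[i] ** 2 / (z_exp[i] ** 2 + n_exp)]
        removed = [s for s in exp.index if s not in keep]
        assert result.snps == keep
        assert result.removed_by_steiger == removed

    def test_missing_sample_size_raises(self):
        exp = self.make_stats([2.0], 1000)
        out = self.make_stats([1.0], 1000).assign(n=np.nan)
        inst = lm.InstrumentSet(snps=["snp0000"], selected_for={})
        with pytest.raises(lm.AlignmentError, match="sample size"):
            lm.steiger_filter(exp, out, inst)
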