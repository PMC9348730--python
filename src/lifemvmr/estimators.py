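"""Two-sample IVW MR and MVMR estimation with diagnostics.

The estimating equation regresses the SNP-outcome associations on the
SNP-exposure associations without an intercept,

    Gamma_j = beta_1 pi_1j + ... + beta_K pi_Kj + eps_j,

weighted by the inverse variance of the outcome associations.  The
coefficients are the direct effects of each exposure's liability
conditional on the others (for K = 1, the total effect; for a single SNP
the estimate reduces to the Wald ratio).  Standard errors come from the
weighted normal equations with a multiplicative over-dispersion factor
floored at 1, the usual IVW convention.

Diagnostics:

* heterogeneity Q-statistic (weighted residual sum of squares over
  instruments, df = #instruments - #exposures) against pleiotropy;
* per-exposure conditional F-statistic (Q-based fixed-effect construction)
  for conditional instrument strength, with the plain mean-chi-square
  F-statistic in the univariable case;
* Steiger filtering: drop instruments whose summary-level variance
  explained in the outcome exceeds that in the designated exposure,
  using r^2 = z^2 / (z^2 + n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (AlignmentError, NoInstrumentsError, SingularDesignError,
                     UndefinedStatisticError)
from .gwas import InstrumentSet, align_stats

__all__ = ["MvmrFit", "ivw_mr", "ivw_mvmr", "conditional_f", "q_statistic",
           "steiger_filter"]

Z95 = 1.959963984540054  # normal 97.5% point; CIs are estimate +/- 1.96*SE


@dataclass
class MvmrFit:
    """Result of one IVW (MV)MR estimation."""

    exposures: tuple
    estimate: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalue: np.ndarray
    n_snps: int
    q: float
    q_df: int
    conditional_f: np.ndarray | None = None
    f_stat: float | None = None
    snps: list | None = None

    def to_frame(self) -> pd.DataFrame:
        """One row per exposure, serialisable to a tabular report."""
        df = pd.DataFrame({
            "exposure": list(self.exposures),
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pvalue": self.pvalue,
            "n_snps": self.n_snps,
            "q": self.q,
            "q_df": self.q_df,
        })
        df["conditional_f"] = (self.conditional_f if self.conditional_f
                               is not None else np.nan)
        df["f_stat"] = self.f_stat if self.f_stat is not None else np.nan
        return df


# ----------------------------------------------------------------------
def _as_2d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _wls_no_intercept(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                      names: tuple):
    """Weighted least squares without intercept; returns (beta, cov, q, q_df)."""
    k, K = X.shape
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    svals = np.linalg.svd(Xw, compute_uv=False)
    if svals[0] == 0 or svals[-1] <= 1e-12 * svals[0]:
        raise SingularDesignError(
            f"exposure-association columns are collinear for exposures {names}")
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = y - X @ beta
    q = float(np.sum(w * resid ** 2))
    q_df = k - K
    scale = max(1.0, q / q_df) if q_df > 0 else 1.0
    cov = scale * np.linalg.inv(Xw.T @ Xw)
    return beta, cov, q, q_df


def _finish(beta, cov, q, q_df, names, k, snps, conditional_f=None,
            f_stat=None) -> MvmrFit:
    se = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(beta / se)
    return MvmrFit(
        exposures=tuple(names), estimate=beta, se=se,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
        pvalue=2.0 * sps.norm.sf(z), n_snps=k, q=q, q_df=q_df,
        conditional_f=conditional_f, f_stat=f_stat, snps=snps)


# ----------------------------------------------------------------------
def ivw_mvmr(exposure_beta, outcome_beta, outcome_se, exposure_se=None,
             exposure_names: tuple | None = None, snps: list | None = None,
             exposure_corr=None) -> MvmrFit:
    """Multivariable IVW regression of outcome on exposure associations.

    Parameters are aligned per-instrument arrays: ``exposure_beta`` is
    (k, K), ``outcome_beta``/``outcome_se`` are (k,).  When
    ``exposure_se`` is supplied and K >= 2 the per-exposure conditional
    F-statistics are attached to the fit; ``exposure_corr`` (the error
    correlation across exposures, see :func:`conditional_f`) sharpens them
    when the exposures come from one sample.
    """
    X = _as_2d(exposure_beta)
    y = np.asarray(outcome_beta, dtype=float)
    ose = np.asarray(outcome_se, dtype=float)
    k, K = X.shape
    if y.shape != (k,) or ose.shape != (k,):
        raise AlignmentError("exposure and outcome statistics have "
                             "inconsistent instrument counts")
    if k < K + 1:
        raise NoInstrumentsError(
            f"MVMR needs at least {K + 1} instruments for {K} exposures, got {k}")
    names = exposure_names or tuple(f"X{i + 1}" for i in range(K))
    w = 1.0 / ose ** 2
    beta, cov, q, q_df = _wls_no_intercept(X, y, w, names)
    cond_f = None
    if exposure_se is not None and K >= 2:
        ese = _as_2d(exposure_se)
        cond_f = np.array([conditional_f(X, ese, t, exposure_corr=exposure_corr)
                           for t in range(K)])
    return _finish(beta, cov, q, q_df, names, k, snps, conditional_f=cond_f)


def ivw_mr(exposure_beta, exposure_se, outcome_beta, outcome_se,
           exposure_name: str = "X1", snps: list | None = None) -> MvmrFit:
    """Univariable IVW MR (one-SNP case reduces to the Wald ratio).

    The reported F-statistic is the mean per-SNP (beta/se)^2 of the
    exposure associations, the conventional summary-data strength proxy.
    """
    x = np.asarray(exposure_beta, dtype=float).ravel()
    xe = np.asarray(exposure_se, dtype=float).ravel()
    y = np.asarray(outcome_beta, dtype=float).ravel()
    ose = np.asarray(outcome_se, dtype=float).ravel()
    k = x.size
    if k < 1:
        raise NoInstrumentsError("univariable MR needs at least one instrument")
    if not (y.size == ose.size == xe.size == k):
        raise AlignmentError("exposure and outcome statistics have "
                             "inconsistent instrument counts")
    w = 1.0 / ose ** 2
    beta, cov, q, q_df = _wls_no_intercept(x[:, None], y, w, (exposure_name,))
    f = float(np.mean((x / xe) ** 2))
    return _finish(beta, cov, q, q_df, (exposure_name,), k, snps, f_stat=f)


# ----------------------------------------------------------------------
def conditional_f(exposure_beta, exposure_se, target: int,
                  exposure_corr=None, n_iter: int = 5) -> float:
    """Conditional instrument strength of one exposure given the others.

    Fixed-effect Q-based construction: the target exposure's associations
    are regressed (no intercept) on the other exposures' associations, and
    the weighted residual sum of squares Q_x divided by its degrees of
    freedom (k - K + 1) is returned.  Each instrument's weight is the
    inverse variance of its fitted residual,

        var(pi_t - sum_o b_o pi_o) =
            se_t^2 + sum_{o,o'} b_o b_o' rho_{oo'} se_o se_o'
            - 2 sum_o b_o rho_{to} se_t se_o,

    so under the null (no conditional genetic signal) the statistic is
    close to 1 whatever the correlation of the estimation errors.  The
    coefficients and weights are profiled jointly by a short fixed-point
    iteration.  ``exposure_corr`` is the correlation matrix of the
    association estimation errors across exposures (approximately the
    phenotypic correlation when all exposures are measured in one sample);
    the default assumes independent errors.
    """
    X = _as_2d(exposure_beta)
    SE = _as_2d(exposure_se)
    k, K = X.shape
    if K < 2:
        raise UndefinedStatisticError(
            "conditional F requires at least two exposures")
    if k < K:
        raise UndefinedStatisticError(
            f"conditional F undefined with {k} instruments for {K} exposures")
    R = np.eye(K) if exposure_corr is None else np.asarray(exposure_corr, float)
    others = [j for j in range(K) if j != target]
    Z = X[:, others]
    se_t = SE[:, target]
    se_o = SE[:, others]
    R_oo = R[np.ix_(others, others)]
    R_to = R[target, others]

    w = 1.0 / se_t ** 2
    coef = np.zeros(len(others))
    for _ in range(n_iter):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(Z * sw[:, None], X[:, target] * sw,
                                   rcond=None)
        M = se_o * coef[None, :]
        sigma2 = (se_t ** 2 + np.einsum("ko,op,kp->k", M, R_oo, M)
                  - 2.0 * se_t * (M @ R_to))
        w = 1.0 / np.maximum(sigma2, 1e-300)
    resid = X[:, target] - Z @ coef
    q_x = float(np.sum(w * resid ** 2))
    return q_x / (k - K + 1)


def q_statistic(estimate, exposure_beta, outcome_beta, outcome_se):
    """Heterogeneity Q of a fitted model: sum_j w_j (Gamma_j - X_j beta)^2.

    Returns ``(q, df)`` with df = #instruments - #exposures.  Excess Q
    relative to a chi-square with df degrees of freedom indicates
    associations with the outcome outside the modelled exposures
    (horizontal pleiotropy).
    """
    X = _as_2d(exposure_beta)
    y = np.asarray(outcome_beta, dtype=float)
    w = 1.0 / np.asarray(outcome_se, dtype=float) ** 2
    beta = np.atleast_1d(np.asarray(estimate, dtype=float))
    resid = y - X @ beta
    return float(np.sum(w * resid ** 2)), X.shape[0] - X.shape[1]


# ----------------------------------------------------------------------
def steiger_filter(exposure_stats: pd.DataFrame, outcome_stats: pd.DataFrame,
                   instruments: InstrumentSet) -> InstrumentSet:
    """Drop instruments explaining more outcome than exposure variance.

    ``exposure_stats`` is the single designated exposure's statistics
    (indexed by snp); the summary-level variance explained is
    r^2 = z^2 / (z^2 + n).  Returns a new instrument set with removal
    provenance; raises if sample sizes are unavailable.
    """
    for df, label in ((exposure_stats, "exposure"), (outcome_stats, "outcome")):
        if "n" not in df.columns or df["n"].isna().any():
            raise AlignmentError(
                f"Steiger filtering needs per-SNP sample sizes for the {label} "
                "statistics")
    snps = list(instruments)
    (eb, es, ob, ose, en, on, _) = align_stats([exposure_stats], outcome_stats,
                                               instruments)
    z_exp = (eb[:, 0] / es[:, 0]) ** 2
    z_out = (ob / ose) ** 2
    r2_exp = z_exp / (z_exp + en[:, 0])
    r2_out = z_out / (z_out + on)
    keep = r2_out <= r2_exp
    kept = [s for s, k in zip(snps, keep) if k]
    removed = [s for s, k in zip(snps, keep) if not k]
    if not kept:
        raise NoInstrumentsError("Steiger filtering removed every instrument")
    return InstrumentSet(
        snps=kept,
        selected_for={s: instruments.selected_for.get(s, set()) for s in kept},
        removed_by_steiger=list(instruments.removed_by_steiger) + removed)
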