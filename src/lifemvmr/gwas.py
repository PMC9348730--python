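"""Per-SNP association summary statistics and instrument selection.

``run_gwas`` regresses each requested trait on each SNP's allele count with
a simple (unadjusted) linear regression, the standard GWAS model for
continuous traits, and reports per-allele effect sizes, standard errors and
normal-approximation p-values.  ``select_instruments`` applies the
genome-wide-significance rule: a SNP is an instrument if it passes the
p-value threshold for the exposure of interest (univariable mode) or for
any of the exposures (multivariable mode), always using the exposure-sample
statistics only.

Summary statistics live in a tidy DataFrame with one record per
(snp, trait, sample); ``write_summary_stats`` / ``read_summary_stats``
round-trip the conventional tab-separated GWAS format
(SNP, effect_allele, other_allele, eaf, beta, se, pval, N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dgp import Cohort
from .errors import AlignmentError, NoInstrumentsError, SummaryFileError

__all__ = [
    "InstrumentSet", "run_gwas", "select_instruments",
    "read_summary_stats", "write_summary_stats", "stats_for", "align_stats",
]

#: columns of the on-disk summary-statistics format
FILE_COLUMNS = ["SNP", "effect_allele", "other_allele", "eaf", "beta", "se",
                "pval", "N"]

#: fixed allele convention for synthetic data (non-palindromic)
SYNTHETIC_EFFECT_ALLELE = "A"
SYNTHETIC_OTHER_ALLELE = "G"


@dataclass
class InstrumentSet:
    """An ordered set of instrument SNPs with per-SNP provenance flags."""

    snps: list
    #: snp -> set of exposures for which it passed the threshold
    selected_for: dict = field(default_factory=dict)
    #: SNPs removed by Steiger filtering (populated by mr_core.steiger_filter)
    removed_by_steiger: list = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("duplicate SNP ids in instrument set")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)


# ----------------------------------------------------------------------
def run_gwas(cohort: Cohort, traits: list | None = None) -> pd.DataFrame:
    """Per-SNP simple linear regression of each trait on allele count.

    Returns a tidy frame with columns snp, trait, sample, beta, se, pval,
    n, eaf, monomorphic.  Monomorphic SNPs (zero genotype variance) are
    flagged and carry NaN statistics; selection skips them.
    """
    if traits is None:
        traits = list(cohort.traits)
    missing = [t for t in traits if t not in cohort.traits]
    if missing:
        raise KeyError(f"traits not present in cohort: {missing}")
    n = cohort.n_individuals
    if n < 30:
        raise ValueError(f"cohort too small for GWAS (n={n} < 30)")

    G = cohort.genotypes
    # genotype sums from exact integer counts: sum g = n1 + 2 n2,
    # sum g^2 = n1 + 4 n2, so Sxx = sum g^2 - (sum g)^2 / n
    n1 = (G == 1).sum(axis=0, dtype=np.int64)
    n2 = (G == 2).sum(axis=0, dtype=np.int64)
    sum_g = n1 + 2 * n2
    gbar = sum_g / n
    sxx = (n1 + 4 * n2) - sum_g * gbar
    mono = sxx == 0.0
    sxx_safe = np.where(mono, np.nan, sxx)

    T = np.column_stack([np.asarray(cohort.traits[t], dtype=np.float64)
                         for t in traits])
    Tc = T - T.mean(axis=0)
    syy = np.einsum("ij,ij->j", Tc, Tc)
    # sum_i (g - gbar)(t - tbar) = sum_i g * (t - tbar) since Tc is centred
    sxy = cohort.genotypes_float().T @ Tc            # (m, K)
    beta = sxy / sxx_safe[:, None]
    rss = np.maximum(syy[None, :] - beta * sxy, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx_safe[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(beta / se)
    pval = 2.0 * sps.norm.sf(z)

    m = G.shape[1]
    frames = []
    for k, t in enumerate(traits):
        frames.append(pd.DataFrame({
            "snp": cohort.snp_ids,
            "trait": t,
            "sample": cohort.sample_label,
            "beta": beta[:, k],
            "se": se[:, k],
            "pval": pval[:, k],
            "n": n,
            "eaf": gbar / 2.0,
            "monomorphic": mono,
        }))
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
def stats_for(stats: pd.DataFrame, trait: str,
              sample: str | None = None) -> pd.DataFrame:
    """Subset a tidy summary-statistics frame to one trait (and sample)."""
    out = stats[stats["trait"] == trait]
    if sample is not None and "sample" in stats.columns:
        out = out[out["sample"] == sample]
    if out.empty:
        raise AlignmentError(f"no summary statistics for trait {trait!r}"
                             + (f" in sample {sample!r}" if sample else ""))
    return out.set_index("snp")


def select_instruments(stats: pd.DataFrame, exposures: list, p_threshold: float,
                       sample: str | None = "exposure") -> InstrumentSet:
    """Select instruments at the p-value threshold (union over exposures).

    Univariable mode is the single-exposure case.  Selection uses the
    exposure-sample statistics only and skips monomorphic records.
    Raises :class:`NoInstrumentsError` when nothing passes.
    """
    if isinstance(exposures, str):
        exposures = [exposures]
    selected_for: dict = {}
    order: dict = {}
    for e in exposures:
        sub = stats_for(stats, e, sample)
        if "monomorphic" in sub.columns:
            sub = sub[~sub["monomorphic"].astype(bool)]
        hits = sub.index[sub["pval"] < p_threshold]
        for pos, snp in enumerate(sub.index):
            order.setdefault(snp, pos)
        for snp in hits:
            selected_for.setdefault(snp, set()).add(e)
    snps = sorted(selected_for, key=order.get)
    if not snps:
        raise NoInstrumentsError(
            f"no SNPs pass p < {p_threshold:g} for exposure(s) {list(exposures)}")
    return InstrumentSet(snps=snps, selected_for=selected_for)


def align_stats(exposure_stats: list, outcome_stats: pd.DataFrame,
                instruments: InstrumentSet | list):
    """Align exposure and outcome statistics on an instrument list.

    ``exposure_stats`` is a list of single-trait frames indexed by snp (as
    returned by :func:`stats_for`); returns
    ``(exposure_beta (k,K), exposure_se, outcome_beta (k,), outcome_se,
    exposure_n (k,K), outcome_n (k,), snps)``.
    """
    snps = list(instruments)
    eb, es, en = [], [], []
    for df in exposure_stats:
        missing = [s for s in snps if s not in df.index]
        if missing:
            raise AlignmentError(
                f"instruments missing from exposure statistics: {missing[:5]}"
                + ("..." if len(missing) > 5 else ""))
        sub = df.loc[snps]
        eb.append(sub["beta"].to_numpy())
        es.append(sub["se"].to_numpy())
        en.append(sub["n"].to_numpy())
    missing = [s for s in snps if s not in outcome_stats.index]
    if missing:
        raise AlignmentError(
            f"instruments missing from outcome statistics: {missing[:5]}"
            + ("..." if len(missing) > 5 else ""))
    osub = outcome_stats.loc[snps]
    return (np.column_stack(eb), np.column_stack(es),
            osub["beta"].to_numpy(), osub["se"].to_numpy(),
            np.column_stack(en), osub["n"].to_numpy(), snps)


# ----------------------------------------------------------------------
def write_summary_stats(stats: pd.DataFrame, path) -> None:
    """Write one trait's statistics in the tab-separated GWAS file format."""
    df = stats.reset_index() if stats.index.name == "snp" else stats.copy()
    out = pd.DataFrame({
        "SNP": df["snp"],
        "effect_allele": df.get("effect_allele", SYNTHETIC_EFFECT_ALLELE),
        "other_allele": df.get("other_allele", SYNTHETIC_OTHER_ALLELE),
        "eaf": df["eaf"] if "eaf" in df else np.nan,
        "beta": df["beta"],
        "se": df["se"],
        "pval": df["pval"] if "pval" in df else np.nan,
        "N": df["n"],
    })
    # %.17g round-trips float64 exactly
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary_stats(path) -> pd.DataFrame:
    """Read a tab-separated GWAS summary-statistics file.

    Returns a frame with internal column names (snp, effect_allele,
    other_allele, eaf, beta, se, pval, n).
    """
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise SummaryFileError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in FILE_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryFileError(
            f"{path}: missing required columns {missing} (header must contain "
            f"{FILE_COLUMNS})")
    bad = df.index[df["se"] <= 0]
    if len(bad):
        raise SummaryFileError(
            f"{path}: non-positive standard error at data line(s) "
            f"{[int(i) + 2 for i in bad[:5]]}")
    return df.rename(columns={"SNP": "snp", "N": "n"})
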