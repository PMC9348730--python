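"""File-driven MR/MVMR for real GWAS summary statistics.

Mirrors the childhood/adult body-size style of analysis: one outcome file
and K exposure files in the tab-separated summary format are harmonised to
a shared effect-allele convention (sign flips for swapped alleles,
strand-ambiguous palindromic SNPs dropped), then univariable IVW MR gives
the total effect of each exposure and IVW MVMR the direct effects
conditional on the other exposures.  Inputs are assumed LD-clumped
upstream.  No external data are bundled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, NoInstrumentsError
from .estimators import MvmrFit, ivw_mr, ivw_mvmr, steiger_filter
from .gwas import InstrumentSet, read_summary_stats

__all__ = ["HarmonisedDataset", "harmonise", "run_applied_mvmr"]

_PALINDROMIC = ({"A", "T"}, {"G", "C"})
#: ambiguous-frequency window for palindromic SNPs
EAF_AMBIGUOUS = (0.42, 0.58)


@dataclass
class HarmonisedDataset:
    """Per-SNP records aligned across one outcome and K exposures."""

    exposures: list                 # exposure trait names (file order)
    outcome: str
    beta: pd.DataFrame              # snp x trait
    se: pd.DataFrame
    pval: pd.DataFrame
    n: pd.DataFrame
    effect_allele: pd.Series
    other_allele: pd.Series
    provenance: pd.DataFrame        # snp, trait, action in {flipped, dropped-*}

    @property
    def snps(self) -> list:
        return list(self.beta.index)

    def stats_for(self, trait: str) -> pd.DataFrame:
        df = pd.DataFrame({
            "beta": self.beta[trait], "se": self.se[trait],
            "pval": self.pval[trait], "n": self.n[trait],
        })
        df.index.name = "snp"
        return df


def _load(source, name):
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = read_summary_stats(source)
    df = df.set_index("snp")
    if df.index.has_duplicates:
        df = df[~df.index.duplicated()]
    df.attrs["name"] = name
    return df


def _is_palindromic(ea: str, oa: str) -> bool:
    return {str(ea).upper(), str(oa).upper()} in _PALINDROMIC


def harmonise(exposure_sources: list, outcome_source, exposure_names=None,
              outcome_name: str = "Y") -> HarmonisedDataset:
    """Align summary sources on shared SNPs and a common allele convention.

    Sources may be file paths or DataFrames in the summary format.  The
    first exposure defines the effect-allele convention; swapped alleles
    flip the sign of beta (and eaf), mismatched alleles and ambiguous
    palindromic SNPs are dropped, with per-SNP provenance recorded.
    Missing eaf on a non-palindromic SNP is retained with a warning.
    """
    if exposure_names is None:
        exposure_names = [f"exposure{i + 1}" for i in range(len(exposure_sources))]
    traits = list(exposure_names) + [outcome_name]
    frames = [_load(src, nm) for src, nm
              in zip(list(exposure_sources) + [outcome_source], traits)]

    shared = frames[0].index
    for df in frames[1:]:
        shared = shared.intersection(df.index)
    if shared.empty:
        raise AlignmentError("no SNPs shared across all summary sources")
    shared = [s for s in frames[0].index if s in set(shared)]  # keep file order

    ref = frames[0].loc[shared]
    prov = []
    keep = pd.Series(True, index=pd.Index(shared, name="snp"))
    harmonised = {}
    for trait, df in zip(traits, frames):
        sub = df.loc[shared].copy()
        if trait != traits[0]:
            same = ((sub["effect_allele"].str.upper()
                     == ref["effect_allele"].str.upper())
                    & (sub["other_allele"].str.upper()
                       == ref["other_allele"].str.upper()))
            swapped = ((sub["effect_allele"].str.upper()
                        == ref["other_allele"].str.upper())
                       & (sub["other_allele"].str.upper()
                          == ref["effect_allele"].str.upper()))
            mismatch = ~(same | swapped)
            sub.loc[swapped, "beta"] *= -1.0
            sub.loc[swapped, "eaf"] = 1.0 - sub.loc[swapped, "eaf"]
            sub.loc[swapped, ["effect_allele", "other_allele"]] = \
                ref.loc[swapped, ["effect_allele", "other_allele"]].to_numpy()
            for s in sub.index[swapped]:
                prov.append({"snp": s, "trait": trait, "action": "flipped"})
            for s in sub.index[mismatch]:
                prov.append({"snp": s, "trait": trait,
                             "action": "dropped-allele-mismatch"})
            keep &= ~mismatch
        harmonised[trait] = sub

    # palindromic rule uses any source's eaf; missing eaf counts as ambiguous
    pal = ref.apply(lambda r: _is_palindromic(r["effect_allele"],
                                              r["other_allele"]), axis=1)
    lo, hi = EAF_AMBIGUOUS
    ambiguous = pd.Series(False, index=keep.index)
    for trait in traits:
        eaf = harmonised[trait]["eaf"]
        ambiguous |= eaf.isna() | ((eaf >= lo) & (eaf <= hi))
    drop_pal = pal & ambiguous
    for s in keep.index[drop_pal & keep]:
        prov.append({"snp": s, "trait": "*", "action": "dropped-palindromic"})
    keep &= ~drop_pal

    missing_eaf = (~pal) & harmonised[traits[0]]["eaf"].isna()
    if missing_eaf.any():
        warnings.warn(f"{int(missing_eaf.sum())} non-palindromic SNP(s) have "
                      "missing eaf; retained", stacklevel=2)

    kept = keep.index[keep]
    if kept.empty:
        raise AlignmentError("harmonisation dropped every shared SNP")

    def col(name):
        return pd.DataFrame({t: harmonised[t].loc[kept, name] for t in traits})

    return HarmonisedDataset(
        exposures=list(exposure_names), outcome=outcome_name,
        beta=col("beta"), se=col("se"), pval=col("pval"),
        n=col("n"),
        effect_allele=ref.loc[kept, "effect_allele"],
        other_allele=ref.loc[kept, "other_allele"],
        provenance=pd.DataFrame(prov, columns=["snp", "trait", "action"]))


# ----------------------------------------------------------------------
def _or_transform(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for c in ("estimate", "ci_low", "ci_high"):
        out[c] = np.exp(out[c])
    return out.rename(columns={"estimate": "odds_ratio"})


def run_applied_mvmr(dataset: HarmonisedDataset, steiger: bool = False,
                     p_threshold: float | None = None,
                     binary_outcome: bool = False, exposure_corr=None):
    """Univariable (total) and multivariable (direct) IVW estimates.

    When ``p_threshold`` is given, instruments for each univariable fit are
    the SNPs significant for that exposure and the MVMR uses their union;
    otherwise every harmonised SNP is used (inputs assumed pre-selected).
    ``steiger`` filters against the last exposure for the MVMR fit and
    against each exposure for its own univariable fit.  With
    ``binary_outcome`` the report shows exponentiated estimates (odds
    ratios); estimation itself is unchanged.

    Returns ``(report_frame, mvmr_fit)``.
    """
    exposures = dataset.exposures
    out_stats = dataset.stats_for(dataset.outcome)

    def instruments_for(traits) -> InstrumentSet:
        if p_threshold is None:
            sel = {s: set(traits) for s in dataset.snps}
            return InstrumentSet(snps=dataset.snps, selected_for=sel)
        pv = dataset.pval[traits]
        mask = (pv < p_threshold).any(axis=1)
        snps = list(pv.index[mask])
        if not snps:
            raise NoInstrumentsError(
                f"no SNPs pass p < {p_threshold:g} for {traits}")
        sel = {s: {t for t in traits if pv.loc[s, t] < p_threshold}
               for s in snps}
        return InstrumentSet(snps=snps, selected_for=sel)

    rows = []
    for e in exposures:
        inst = instruments_for([e])
        if steiger:
            inst = steiger_filter(dataset.stats_for(e), out_stats, inst)
        sub = dataset.stats_for(e).loc[list(inst)]
        osub = out_stats.loc[list(inst)]
        fit = ivw_mr(sub["beta"], sub["se"], osub["beta"], osub["se"],
                     exposure_name=e, snps=list(inst))
        row = fit.to_frame()
        row.insert(0, "method", "MR-total")
        rows.append(row)

    inst = instruments_for(exposures)
    if steiger:
        inst = steiger_filter(dataset.stats_for(exposures[-1]), out_stats, inst)
    snps = list(inst)
    eb = dataset.beta.loc[snps, exposures].to_numpy()
    es = dataset.se.loc[snps, exposures].to_numpy()
    mvmr = ivw_mvmr(eb, out_stats.loc[snps, "beta"].to_numpy(),
                    out_stats.loc[snps, "se"].to_numpy(), exposure_se=es,
                    exposure_names=tuple(exposures), snps=snps,
                    exposure_corr=exposure_corr)
    row = mvmr.to_frame()
    row.insert(0, "method", "MVMR-direct")
    rows.append(row)

    report = pd.concat(rows, ignore_index=True)
    if binary_outcome:
        report = _or_transform(report)
    return report, mvmr
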