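"""Monte-Carlo study runner: simulate -> GWAS -> select -> estimate -> aggregate.

One repetition draws a fresh set of true SNP effects, simulates two
non-overlapping cohorts (exposure sample and outcome sample) from the same
population, computes summary statistics, selects instruments at the
configured threshold, and runs univariable IVW MR for each estimated
exposure plus the joint IVW MVMR.  For the collider preset the same
simulated data are estimated twice, without and with Steiger filtering.

Aggregation across repetitions produces the simulation-report rows: the
mean effect estimate, mean estimated SE, simulation SE (SD of estimates
across repetitions), mean absolute bias against the coverage truth,
empirical 95% CI coverage, mean (conditional) F-statistic and mean
instrument count.  Repetitions where no instrument passes selection are
skipped and counted.

Repetitions are deterministic given (seed, rep_index): every repetition
seeds its own generator from the master seed and its index, so results do
not depend on execution order or worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .config import ScenarioConfig, preset
from .dgp import TruthValues, draw_snp_effects, plim_truth, simulate_cohort
from .errors import NoInstrumentsError
from .estimators import MvmrFit, ivw_mr, ivw_mvmr, steiger_filter
from .gwas import align_stats, run_gwas, select_instruments, stats_for

__all__ = ["RepResult", "StudyResult", "ScenarioReport", "run_repetition",
           "run_study", "aggregate", "reproduce_table", "per_rep_frame"]

REPORT_COLUMNS = ["scenario", "panel", "method", "exposure", "truth",
                  "mean_estimate", "mean_se", "sim_se", "mean_abs_bias",
                  "coverage", "mean_f", "mean_conditional_f", "mean_n_snps",
                  "n_reps"]


@dataclass
class RepResult:
    """All fits from one repetition (panels keyed by filtering status)."""

    rep_index: int
    mr: dict                    # exposure -> MvmrFit (unfiltered)
    mvmr: MvmrFit | None
    mr_steiger: dict = field(default_factory=dict)
    mvmr_steiger: MvmrFit | None = None
    skipped: bool = False
    skip_reason: str | None = None


@dataclass
class StudyResult:
    config: ScenarioConfig
    reps: list

    @property
    def n_completed(self) -> int:
        return sum(not r.skipped for r in self.reps)

    @property
    def n_skipped(self) -> int:
        return sum(r.skipped for r in self.reps)


@dataclass
class ScenarioReport:
    """Per-coefficient aggregates over repetitions (one table of rows)."""

    config: ScenarioConfig
    truths: TruthValues
    table: pd.DataFrame
    n_reps: int
    n_skipped: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
def _rep_rng_children(config: ScenarioConfig, rep_index: int):
    ss = np.random.SeedSequence(config.seed, spawn_key=(int(rep_index),))
    return [np.random.default_rng(c) for c in ss.spawn(3)]


def run_repetition(config: ScenarioConfig, rep_index: int) -> RepResult:
    """One full simulate -> GWAS -> select -> estimate cycle.

    Deterministic given ``(config.seed, rep_index)``.  A repetition with no
    significant instrument for some estimation records that fit as missing;
    if the joint MVMR cannot be fitted the repetition is marked skipped.
    """
    rng_eff, rng_exp, rng_out = _rep_rng_children(config, rep_index)
    effects = draw_snp_effects(config, rng_eff)
    cohort_exp = simulate_cohort(effects, config, "exposure", rng_exp)
    cohort_out = simulate_cohort(effects, config, "outcome", rng_out)

    exposures = list(config.estimated_exposures)
    stats = pd.concat([run_gwas(cohort_exp, exposures),
                       run_gwas(cohort_out, ["Y"])], ignore_index=True)
    exp_stats = {e: stats_for(stats, e, "exposure") for e in exposures}
    out_stats = stats_for(stats, "Y", "outcome")
    # estimation errors of the exposure associations are correlated within
    # the shared exposure sample (approximately the phenotypic correlation)
    exposure_corr = np.corrcoef(
        np.column_stack([cohort_exp.traits[e] for e in exposures]),
        rowvar=False)

    def fit_mr(e, instruments):
        eb, es, ob, ose, _, _, snps = align_stats([exp_stats[e]], out_stats,
                                                  instruments)
        return ivw_mr(eb[:, 0], es[:, 0], ob, ose, exposure_name=e, snps=snps)

    def fit_mvmr(instruments):
        eb, es, ob, ose, _, _, snps = align_stats(
            [exp_stats[e] for e in exposures], out_stats, instruments)
        return ivw_mvmr(eb, ob, ose, exposure_se=es,
                        exposure_names=tuple(exposures), snps=snps,
                        exposure_corr=exposure_corr)

    mr, mr_steiger = {}, {}
    mr_sets = {}
    for e in exposures:
        try:
            mr_sets[e] = select_instruments(stats, e, config.p_threshold)
            mr[e] = fit_mr(e, mr_sets[e])
        except NoInstrumentsError:
            mr[e] = None

    mvmr = mvmr_steiger = None
    skipped, reason = False, None
    try:
        union = select_instruments(stats, exposures, config.p_threshold)
        mvmr = fit_mvmr(union)
    except NoInstrumentsError as exc:
        skipped, reason = True, str(exc)
        union = None

    if config.apply_steiger:
        # same simulated data estimated a second time after Steiger filtering:
        # univariable fits filter against their own exposure, the MVMR fit
        # against the later exposure
        later = exposures[-1]
        for e in exposures:
            if mr.get(e) is None:
                continue
            try:
                filtered = steiger_filter(exp_stats[e], out_stats, mr_sets[e])
                mr_steiger[e] = fit_mr(e, filtered)
            except NoInstrumentsError:
                mr_steiger[e] = None
        if union is not None:
            try:
                filtered = steiger_filter(exp_stats[later], out_stats, union)
                mvmr_steiger = fit_mvmr(filtered)
            except NoInstrumentsError as exc:
                skipped, reason = True, str(exc)

    return RepResult(rep_index=rep_index, mr=mr, mvmr=mvmr,
                     mr_steiger=mr_steiger, mvmr_steiger=mvmr_steiger,
                     skipped=skipped, skip_reason=reason)


def run_study(config: ScenarioConfig, n_reps: int | None = None,
              n_jobs: int = 1, progress: bool = False) -> StudyResult:
    """Run ``n_reps`` repetitions (defaults to ``config.n_reps``)."""
    if n_reps is None:
        n_reps = config.n_reps
    indices = range(n_reps)
    if n_jobs == 1:
        it = indices
        if progress:
            try:
                from tqdm import tqdm
                it = tqdm(indices, desc=config.scenario_id)
            except ImportError:
                pass
        reps = [run_repetition(config, i) for i in it]
    else:
        reps = Parallel(n_jobs=n_jobs)(
            delayed(run_repetition)(config, i) for i in indices)
    return StudyResult(config=config, reps=reps)


# ----------------------------------------------------------------------
def per_rep_frame(study: StudyResult) -> pd.DataFrame:
    """Tidy per-repetition estimate log (one row per fit and exposure)."""
    rows = []
    for rep in study.reps:
        entries = [("MR", "unfiltered", rep.mr), ("MVMR", "unfiltered",
                                                  rep.mvmr),
                   ("MR", "steiger", rep.mr_steiger),
                   ("MVMR", "steiger", rep.mvmr_steiger)]
        for method, panel, obj in entries:
            fits = obj if isinstance(obj, dict) else (
                {} if obj is None else {None: obj})
            for key, fit in fits.items():
                if fit is None:
                    continue
                for k, e in enumerate(fit.exposures):
                    rows.append({
                        "rep": rep.rep_index, "method": method,
                        "panel": panel, "exposure": e,
                        "estimate": fit.estimate[k], "se": fit.se[k],
                        "n_snps": fit.n_snps, "q": fit.q, "q_df": fit.q_df,
                        "f_stat": fit.f_stat,
                        "conditional_f": (fit.conditional_f[k]
                                          if fit.conditional_f is not None
                                          else np.nan),
                        "skipped": rep.skipped,
                    })
    return pd.DataFrame(rows)


def _collect(study: StudyResult, method: str, panel: str):
    """Yield (exposure, fits) for one method/panel over completed reps."""
    attr = {("MR", "unfiltered"): "mr", ("MR", "steiger"): "mr_steiger",
            ("MVMR", "unfiltered"): "mvmr", ("MVMR", "steiger"): "mvmr_steiger"}[
        (method, panel)]
    exposures = list(study.config.estimated_exposures)
    for e in exposures:
        fits = []
        for rep in study.reps:
            if rep.skipped:
                continue
            obj = getattr(rep, attr)
            fit = obj.get(e) if isinstance(obj, dict) else obj
            if fit is not None:
                fits.append(fit)
        yield e, fits


def aggregate(study: StudyResult, truths: TruthValues | None = None
              ) -> ScenarioReport:
    """Aggregate repetitions into the simulation-report rows.

    Coverage is evaluated against the univariable-MR plim for MR rows and
    the MVMR liability-effect truth for MVMR rows (see
    :func:`lifemvmr.dgp.plim_truth`).
    """
    if study.n_completed < 2:
        raise ValueError("aggregate needs at least two completed repetitions")
    if truths is None:
        truths = plim_truth(study.config)
    cfg = study.config
    panels = ["unfiltered"] + (["steiger"] if cfg.apply_steiger else [])
    rows = []
    for panel in panels:
        for method in ("MR", "MVMR"):
            for e, fits in _collect(study, method, panel):
                if not fits:
                    continue
                truth = (truths.mr_liability[e] if method == "MR"
                         else truths.mvmr_liability[e])
                idx = 0 if method == "MR" else list(fits[0].exposures).index(e)
                est = np.array([f.estimate[idx] for f in fits])
                se = np.array([f.se[idx] for f in fits])
                lo = np.array([f.ci_low[idx] for f in fits])
                hi = np.array([f.ci_high[idx] for f in fits])
                nsnp = np.array([f.n_snps for f in fits])
                fstat = np.array([f.f_stat for f in fits], dtype=float)
                cfstat = np.array(
                    [f.conditional_f[idx] if f.conditional_f is not None
                     else np.nan for f in fits])
                rows.append({
                    "scenario": cfg.scenario_id,
                    "panel": panel,
                    "method": method,
                    "exposure": e,
                    "truth": truth,
                    "mean_estimate": est.mean(),
                    "mean_se": se.mean(),
                    "sim_se": est.std(ddof=1),
                    "mean_abs_bias": np.abs(est - truth).mean(),
                    "coverage": float(np.mean((lo <= truth) & (truth <= hi))),
                    "mean_f": fstat.mean(),
                    "mean_conditional_f": cfstat.mean(),
                    "mean_n_snps": nsnp.mean(),
                    "n_reps": len(fits),
                })
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return ScenarioReport(config=cfg, truths=truths, table=table,
                          n_reps=study.n_completed, n_skipped=study.n_skipped)


# ----------------------------------------------------------------------
_TABLE_SCENARIOS = {
    1: ["two_liabilities", "one_liability"],
    2: ["collider"],
    3: ["three_liabilities_correlated", "three_liabilities_independent"],
}


def reproduce_table(table_id: int, n_reps: int | None = None,
                    n_sample: int | None = None, seed: int | None = None,
                    n_jobs: int = 1, progress: bool = False,
                    per_rep_dir=None) -> pd.DataFrame:
    """Re-run the preset scenarios behind one simulation table.

    ``table_id`` 1 contrasts distinct vs shared liabilities, 2 the collider
    scenario without/with Steiger filtering, 3 the excluded-liability
    scenarios with correlated vs independent third-period effects.
    ``n_reps``/``n_sample`` rescale the study (the full-scale presets use
    2000 repetitions of n=150,000); ``per_rep_dir`` additionally writes one
    per-repetition estimate log per scenario.
    """
    if table_id not in _TABLE_SCENARIOS:
        raise ValueError(f"table_id must be one of {sorted(_TABLE_SCENARIOS)}")
    frames = []
    for name in _TABLE_SCENARIOS[table_id]:
        cfg = preset(name)
        overrides = {}
        if seed is not None:
            overrides["seed"] = int(seed)
        cfg = cfg.scaled(n_reps=n_reps, n_sample=n_sample, **overrides)
        study = run_study(cfg, n_jobs=n_jobs, progress=progress)
        if per_rep_dir is not None:
            import pathlib
            out = pathlib.Path(per_rep_dir)
            out.mkdir(parents=True, exist_ok=True)
            per_rep_frame(study).to_csv(out / f"{name}_reps.tsv", sep="\t",
                                        index=False)
        frames.append(aggregate(study).table)
    return pd.concat(frames, ignore_index=True)
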