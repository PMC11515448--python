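"""End-to-end iterative radial MR analysis.

The principal analysis embeds the radial IVW fit in an iterative loop: fit,
test each SNP's Cochran Q contribution against alpha_Q = 0.01, remove every
breaching outlier, refit — up to three iterations by default — then run the
full pleiotropy-robust estimator battery and the heterogeneity / MR-PRESSO
diagnostics on the final instrument set, convert estimates to odds ratios,
and Bonferroni-adjust p-values over the study's family of hypotheses.

Because exposure and outcome are binary, an odds ratio here is the average
change in outcome odds per 2.72-fold (e-fold) increase in the prevalence
(liability odds) of the exposure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .datatypes import (
    GwasSummaryStats,
    HarmonizedInstrumentSet,
    LdReference,
    MrEstimate,
    MrpipeError,
    RadialFit,
)
from . import estimators as est
from . import heterogeneity as het
from . import instruments as ins

__all__ = [
    "AnalysisConfig",
    "IterationTrace",
    "iterate_radial",
    "run_analysis",
    "run_meta",
    "bonferroni_adjust",
    "to_odds_ratio",
    "consistency_check",
    "study_grid_m",
    "STUDY_EXPOSURE_SETS",
    "STUDY_OUTCOMES",
]

log = logging.getLogger("mrpipe")

OR_SCALE_NOTE = ("ORs represent the average change in the outcome per "
                 "2.72-fold (e-fold) increase in the prevalence of the exposure")

#: the study design this package's defaults mirror: four exposure sets
#: (replicate and strict-definition datasets support plausibility or
#: meta-analysis within a set, not extra hypotheses) ...
STUDY_EXPOSURE_SETS = (
    "ankylosing_spondylitis",
    "psoriasis",
    "psoriatic_arthritis",
    "rheumatoid_arthritis",
)
#: ... crossed with eleven outcomes: three main cancer sites plus subtypes
STUDY_OUTCOMES = (
    "breast", "breast_er_positive", "breast_er_negative",
    "endometrial", "endometrial_endometrioid", "endometrial_non_endometrioid",
    "ovarian", "ovarian_low_grade_serous", "ovarian_high_grade_serous",
    "ovarian_endometrioid", "ovarian_clear_cell",
)


def study_grid_m(exposure_sets=STUDY_EXPOSURE_SETS,
                 outcomes=STUDY_OUTCOMES) -> int:
    """Size of the Bonferroni family: one hypothesis per exposure-set x
    outcome pair."""
    return len(tuple(exposure_sets)) * len(tuple(outcomes))


@dataclass
class AnalysisConfig:
    """Tunable settings of the full analysis.

    ``alpha_q`` is the per-SNP outlier level of the iterative radial loop;
    ``bonferroni_m`` the hypothesis-family size (the default 44 is the
    4 x 11 exposure-set-by-outcome grid of :func:`study_grid_m`).
    """

    alpha_q: float = 0.01
    max_iterations: int = 3
    bonferroni_m: int = 44
    p_threshold: float = ins.P_GENOME_WIDE
    clump_r2: float = ins.CLUMP_R2
    clump_window_kb: float = ins.CLUMP_WINDOW_KB
    proxy_r2: float = ins.PROXY_R2
    maf_palindromic_cutoff: float = ins.MAF_PALINDROMIC_CUTOFF
    drop_all_palindromic: bool = False
    weight_order: str = "modified_second"
    random_effects: bool = True
    remove_one_at_a_time: bool = False
    n_boot: int = 2000
    presso_n_bootstrap: int = 1000
    raps_overdispersion: bool = True
    raps_loss: str = "huber"
    mode_bandwidth_phi: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_q < 1:
            raise MrpipeError("alpha_q must be in (0, 1)")
        if self.max_iterations < 1:
            raise MrpipeError("max_iterations must be >= 1")
        if self.bonferroni_m < 1:
            raise MrpipeError("bonferroni_m must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise MrpipeError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class IterationRecord:
    """State of one pass of the iterative radial loop."""

    iteration: int
    snp_ids: list[str]
    theta_hat: float
    se: float
    q_total: float
    q_pval: float
    removed: list[tuple[str, float]]  # (snp_id, per-SNP q p-value)


@dataclass
class IterationTrace:
    """Audit trail of the iterative loop plus the first-vs-last comparison."""

    records: list[IterationRecord] = field(default_factory=list)
    floor_reached: bool = False
    delta_theta: float = 0.0
    estimate_ratio: float = 1.0
    consistent: bool = True

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    def removed_snps(self) -> list[tuple[str, float]]:
        return [rm for rec in self.records for rm in rec.removed]

    def to_dict(self) -> dict:
        return {
            "iterations": [
                {
                    "iteration": r.iteration,
                    "snp_ids": r.snp_ids,
                    "theta_hat": r.theta_hat,
                    "se": r.se,
                    "q_total": r.q_total,
                    "q_pval": r.q_pval,
                    "removed": [{"snp": s, "q_pval": p} for s, p in r.removed],
                }
                for r in self.records
            ],
            "floor_reached": self.floor_reached,
            "first_vs_last": {
                "delta_theta": self.delta_theta,
                "estimate_ratio": self.estimate_ratio,
                "consistent": self.consistent,
            },
        }


def iterate_radial(hset: HarmonizedInstrumentSet, config: AnalysisConfig
                   ) -> tuple[RadialFit, HarmonizedInstrumentSet, IterationTrace]:
    """Iterative radial IVW with per-SNP Cochran Q outlier pruning.

    Each pass fits the radial IVW (modified second-order weights by
    default), refers every SNP's Q contribution to chi2(1), and removes all
    SNPs breaching ``alpha_q`` — stopping when the global Q is unremarkable,
    no SNP breaches, the iteration cap is hit, or removal would leave fewer
    than two instruments (the previous fit is then kept and flagged).
    Returns the final fit, the surviving instrument set, and the full trace.
    """
    if hset.n_snps < 2:
        raise MrpipeError("iterative radial analysis needs >= 2 instruments")
    trace = IterationTrace()
    current = hset
    fit = None
    for it in range(1, config.max_iterations + 1):
        fit = est.radial_ivw(current, weight_order=config.weight_order,
                             random_effects=config.random_effects)
        p_j = sps.chi2.sf(fit.q_j, 1)
        breach = np.flatnonzero(p_j < config.alpha_q)
        record = IterationRecord(
            iteration=it,
            snp_ids=list(current.snp_ids),
            theta_hat=fit.theta_hat,
            se=fit.se,
            q_total=fit.q_total,
            q_pval=fit.q_pval,
            removed=[],
        )
        trace.records.append(record)
        stop = (fit.q_pval >= config.alpha_q or breach.size == 0
                or it == config.max_iterations)
        if stop:
            break
        if config.remove_one_at_a_time:
            breach = breach[[int(np.argmax(fit.q_j[breach]))]]
        if current.n_snps - breach.size < 2:
            trace.floor_reached = True
            log.warning("outlier removal would leave < 2 instruments; "
                        "keeping previous fit")
            break
        record.removed = [(current.snp_ids[i], float(p_j[i])) for i in breach]
        keep = np.setdiff1d(np.arange(current.n_snps), breach)
        current = current.subset(keep)

    first, last = trace.records[0], trace.records[-1]
    trace.delta_theta = last.theta_hat - first.theta_hat
    trace.estimate_ratio = (last.theta_hat / first.theta_hat
                            if first.theta_hat != 0 else float("nan"))
    sign_same = np.sign(last.theta_hat) == np.sign(first.theta_hat) \
        or first.theta_hat == 0 or last.theta_hat == 0
    ci_overlap = (first.theta_hat - est.Z95 * first.se
                  <= last.theta_hat + est.Z95 * last.se
                  and last.theta_hat - est.Z95 * last.se
                  <= first.theta_hat + est.Z95 * first.se)
    trace.consistent = bool(sign_same and ci_overlap)
    return fit, current, trace


def bonferroni_adjust(p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m * p)."""
    if not 0 < p <= 1:
        raise MrpipeError("p must be in (0, 1]")
    if m < 1:
        raise MrpipeError("m must be >= 1")
    return min(1.0, m * p)


def to_odds_ratio(estimate: MrEstimate) -> tuple[float, float, float]:
    """Exponentiate a log-OR estimate: (OR, ci_low, ci_high).

    For a binary exposure the OR reads as the change in outcome odds per
    e-fold (2.72-fold) increase in exposure prevalence.
    """
    return (float(np.exp(estimate.beta)),
            float(np.exp(estimate.beta - est.Z95 * estimate.se)),
            float(np.exp(estimate.beta + est.Z95 * estimate.se)))


def consistency_check(primary: MrEstimate, plausibility: MrEstimate) -> str:
    """Sign agreement between a primary and a plausibility estimate.

    Returns ``consistent`` when the point estimates share a sign (an
    exactly-zero estimate is consistent by convention), ``contradictory``
    otherwise — contradictory rows should be read as "no clear conclusion".
    """
    if primary.beta == 0 or plausibility.beta == 0:
        return "consistent"
    return ("consistent" if np.sign(primary.beta) == np.sign(plausibility.beta)
            else "contradictory")


def _estimate_row(e: MrEstimate, config: AnalysisConfig, exposure: str,
                  outcome: str, n_initial: int, trace: IterationTrace,
                  hrep: het.HeterogeneityReport | None) -> dict:
    or_, lo, hi = to_odds_ratio(e)
    return {
        "exposure": exposure,
        "outcome": outcome,
        "method": e.method,
        "beta": e.beta,
        "se": e.se,
        "OR": or_,
        "ci_low": lo,
        "ci_high": hi,
        "pval": e.pval,
        "pval_adj": bonferroni_adjust(e.pval, config.bonferroni_m),
        "n_snps_initial": n_initial,
        "n_snps_final": e.n_snps,
        "iterations_used": trace.n_iterations,
        "q_pval": hrep.q_pval if hrep else float("nan"),
        "egger_intercept_pval": hrep.intercept_pval if hrep else float("nan"),
        "first_vs_last_consistent": trace.consistent,
    }


def _method_seeds(seed: int) -> dict[str, int]:
    names = ("weighted_median", "weighted_mode", "presso")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}


def run_analysis(exposure_stats: GwasSummaryStats,
                 outcome_stats: GwasSummaryStats,
                 ld: LdReference,
                 config: AnalysisConfig | None = None,
                 exposure_label: str | None = None,
                 outcome_label: str | None = None
                 ) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: selection, clumping, harmonization, iterative radial
    IVW, the robust estimator battery, diagnostics, OR-scale reporting.

    Returns the results table (one row per method) and a JSON-serializable
    diagnostics bundle (iteration trace, drop log, heterogeneity report,
    per-iteration MR-PRESSO).  Deterministic given the config seed.
    """
    config = config or AnalysisConfig()
    exposure_label = exposure_label or exposure_stats.trait or "exposure"
    outcome_label = outcome_label or outcome_stats.trait or "outcome"
    seeds = _method_seeds(config.seed)

    selected = ins.select_genome_wide(exposure_stats, config.p_threshold)
    log.info("selection: %d/%d SNPs at P < %g", len(selected),
             len(exposure_stats), config.p_threshold)
    if len(selected) < 2:
        raise MrpipeError(
            f"only {len(selected)} genome-wide significant instruments; >= 2 needed")
    clumped = ins.clump(selected, exposure_stats, ld,
                        config.clump_r2, config.clump_window_kb)
    log.info("clumping: %d/%d SNPs kept", len(clumped), len(selected))
    opts = ins.HarmonizationOptions(
        maf_palindromic_cutoff=config.maf_palindromic_cutoff,
        drop_all_palindromic=config.drop_all_palindromic,
        proxy_r2=config.proxy_r2,
    )
    hset = ins.harmonize(exposure_stats.subset(clumped), outcome_stats, ld, opts)
    log.info("harmonization: %d/%d SNPs kept (%d dropped)", hset.n_snps,
             len(clumped), len(hset.drop_log))
    if hset.n_snps < 2:
        raise MrpipeError(
            f"only {hset.n_snps} instruments survive harmonization; >= 2 needed")
    n_initial = hset.n_snps

    final_fit, final_set, trace = iterate_radial(hset, config)

    # per-iteration MR-PRESSO on each iteration's instrument set
    presso_by_iter = []
    id_to_pos = {s: i for i, s in enumerate(hset.snp_ids)}
    for rec in trace.records:
        sub = hset.subset([id_to_pos[s] for s in rec.snp_ids])
        if sub.n_snps < 4:
            presso_by_iter.append({"iteration": rec.iteration,
                                   "skipped": "fewer than 4 instruments"})
            continue
        rep = het.presso_global(sub, config.presso_n_bootstrap, seeds["presso"])
        out_idx, p_adj = het.presso_outliers(sub, config.presso_n_bootstrap,
                                             alpha=0.05, seed=seeds["presso"])
        d = rep.to_dict()
        d.update({"iteration": rec.iteration,
                  "outlier_snps": [rec.snp_ids[i] for i in out_idx],
                  "outlier_pval_adj": [float(p) for p in p_adj]})
        if 0 < out_idx.size < sub.n_snps - 1:
            dist, dist_p = het.presso_distortion(
                sub, out_idx, config.presso_n_bootstrap, seeds["presso"])
            d.update({"distortion_coefficient": dist, "distortion_pval": dist_p})
        presso_by_iter.append(d)

    ivw_est = est.MrEstimate(
        method="ivw_radial",
        beta=final_fit.theta_hat,
        se=final_fit.se,
        ci_low=final_fit.theta_hat - est.Z95 * final_fit.se,
        ci_high=final_fit.theta_hat + est.Z95 * final_fit.se,
        pval=max(float(2.0 * sps.norm.sf(abs(final_fit.theta_hat) / final_fit.se))
                 if final_fit.se > 0 else 1.0, np.finfo(float).tiny),
        n_snps=final_fit.n_snps,
        diagnostics={"weight_order": final_fit.weight_order},
    )

    battery: list[MrEstimate] = [ivw_est]
    not_applicable: dict[str, str] = {}

    def try_method(name, func):
        try:
            battery.append(func())
        except MrpipeError as exc:
            not_applicable[name] = str(exc)
            log.info("%s not applicable: %s", name, exc)

    def egger_estimate():
        fit = est.radial_egger(final_set, weight_order=config.weight_order)
        return est.MrEstimate(
            method="egger", beta=fit.slope, se=fit.se_slope,
            ci_low=fit.slope - est.Z95 * fit.se_slope,
            ci_high=fit.slope + est.Z95 * fit.se_slope,
            pval=fit.slope_pval, n_snps=fit.n_snps,
            diagnostics={"intercept": fit.intercept,
                         "intercept_pval": fit.intercept_pval},
        )

    try_method("egger", egger_estimate)
    try_method("weighted_median",
               lambda: est.weighted_median(final_set, config.n_boot,
                                           seeds["weighted_median"]))
    try_method("weighted_mode",
               lambda: est.weighted_mode(final_set, config.mode_bandwidth_phi,
                                         config.n_boot, seeds["weighted_mode"]))
    try_method("mr_raps",
               lambda: est.mr_raps(final_set, config.raps_overdispersion,
                                   config.raps_loss))

    hrep = None
    if final_set.n_snps >= 3:
        hrep = het.heterogeneity_report(final_set, config.weight_order)

    rows = [_estimate_row(e, config, exposure_label, outcome_label,
                          n_initial, trace, hrep) for e in battery]
    table = pd.DataFrame(rows)

    diagnostics = {
        "exposure": exposure_label,
        "outcome": outcome_label,
        "config": config.to_dict(),
        "or_scale_note": OR_SCALE_NOTE,
        "n_selected": len(selected),
        "n_clumped": len(clumped),
        "drop_log": [{"snp": s, "reason": r} for s, r in hset.drop_log],
        "trace": trace.to_dict(),
        "heterogeneity": hrep.to_dict() if hrep else None,
        "presso_by_iteration": presso_by_iter,
        "not_applicable": not_applicable,
    }
    return table, diagnostics


def run_meta(analyses: list[pd.DataFrame],
             config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Fixed-effect meta-analysis of replicate-exposure analyses.

    Pools per (outcome, method) across the given results tables; methods
    missing from any replicate are skipped with a log entry.  Pooled rows
    carry method ``meta_fixed`` with the source method recorded.
    """
    config = config or AnalysisConfig()
    if len(analyses) < 2:
        raise MrpipeError("meta-analysis needs >= 2 replicate analyses")
    combined = pd.concat(analyses, ignore_index=True)
    out_rows = []
    for (outcome, method), grp in combined.groupby(["outcome", "method"],
                                                   sort=True):
        if len(grp) < len(analyses):
            log.info("meta: method %s missing for outcome %s in some "
                     "replicates; skipped", method, outcome)
            continue
        ests = [
            MrEstimate(method=method, beta=r.beta, se=r.se,
                       ci_low=r.beta - est.Z95 * r.se,
                       ci_high=r.beta + est.Z95 * r.se,
                       pval=r.pval, n_snps=int(r.n_snps_final),
                       diagnostics={"outcome": outcome})
            for r in grp.itertuples()
        ]
        pooled = est.fixed_effect_meta(ests)
        or_, lo, hi = to_odds_ratio(pooled)
        out_rows.append({
            "exposure": "+".join(sorted(grp["exposure"].unique())),
            "outcome": outcome,
            "method": "meta_fixed",
            "source_method": method,
            "beta": pooled.beta,
            "se": pooled.se,
            "OR": or_,
            "ci_low": lo,
            "ci_high": hi,
            "pval": pooled.pval,
            "pval_adj": bonferroni_adjust(pooled.pval, config.bonferroni_m),
            "k_studies": len(ests),
        })
    return pd.DataFrame(out_rows)


def write_results(table: pd.DataFrame, path) -> None:
    """Serialize a results table deterministically (fixed float format)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_diagnostics(diag: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(diag, fh, indent=2, sort_keys=True)
        fh.write("\n")
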