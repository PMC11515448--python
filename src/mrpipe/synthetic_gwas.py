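"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of consortium case-control GWAS used in
two-sample MR of binary traits: per-SNP log-odds effects with standard errors
driven by allele frequency and sample size, a handful (tens) of genome-wide
significant independent instruments, optional horizontal pleiotropy in
balanced, directional, or InSIDE-violating form, planted gross outliers, and
an LD reference with block structure, palindromic variants and allele-order /
strand re-encodings for the harmonizer to resolve.

The causal model is linear on the liability (log-odds) scale:

    Gamma_j = theta * gamma_j + alpha_j

with observed effects gamma_hat_j ~ N(gamma_j, se_x_j^2) and
Gamma_hat_j ~ N(Gamma_j, se_y_j^2), exposure and outcome noise independent
(the two-sample setting).  Standard errors follow the usual binary-trait
approximation  se ~ 1 / sqrt(2 N p (1-p) c (1-c))  with p the effect-allele
frequency and c the case fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import (
    GwasSummaryStats,
    HarmonizedInstrumentSet,
    LdReference,
    MrpipeError,
    complement,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_two_sample_dataset",
    "simulate_harmonized",
    "make_ld_reference",
]

GENOME_WIDE_P = 5e-8

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]

# named RNG sub-streams, split deterministically from the master seed so that
# draws in one stage never reshuffle another
_STAGES = ("variants", "gamma", "noise_x", "pleiotropy", "noise_y",
           "outliers", "ld", "encoding")


@dataclass
class SimulationConfig:
    """Generating parameters for one two-sample dataset.

    Parameters
    ----------
    n_snps
        Number of candidate instruments.
    theta
        True causal effect: log-OR of the outcome per unit (e-fold) increase
        in the exposure liability.
    gamma_dist_sd
        SD of the true instrument-exposure effects gamma_j.
    n_exposure, n_outcome
        GWAS sample sizes; together with the case fractions they set the
        magnitude of the standard errors.
    case_frac_exposure, case_frac_outcome
        Case proportions of the two GWAS.
    pleiotropy_mode
        One of ``none``, ``balanced``, ``directional``, ``inside_violating``.
    pleiotropy_sd, pleiotropy_mean
        SD and mean of the direct effects alpha_j (mean used only in
        directional mode).
    inside_corr
        Correlation between alpha_j and gamma_j (inside_violating mode only).
    n_outlier_snps, outlier_magnitude
        Planted gross outliers: that many SNPs get alpha_j set to
        ``outlier_magnitude`` outright, overriding the pleiotropy regime.
    maf_range
        Interval for effect-allele frequencies, a subset of (0, 0.5].
    frac_palindromic
        Fraction of variants given A/T or G/C allele pairs.
    ld_block_size, ld_r2_within
        Block-diagonal LD reference structure.
    enforce_significance
        Rescale true gamma_j until the realized exposure p-value clears the
        genome-wide threshold (flagged per SNP in the truth record).
    seed
        Master RNG seed; identical configs and seeds give identical output.
    """

    n_snps: int = 14
    theta: float = float(np.log(1.03))
    gamma_dist_sd: float = 0.35
    n_exposure: int = 270_000
    n_outcome: int = 66_000
    case_frac_exposure: float = 0.01
    case_frac_outcome: float = 0.38
    pleiotropy_mode: str = "none"
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.0
    inside_corr: float = 0.0
    n_outlier_snps: int = 0
    outlier_magnitude: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 0.2
    ld_block_size: int = 1
    ld_r2_within: float = 0.0
    enforce_significance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise MrpipeError("n_snps must be >= 2")
        if self.gamma_dist_sd < 0 or self.pleiotropy_sd < 0:
            raise MrpipeError("SDs must be >= 0")
        if abs(self.inside_corr) > 1:
            raise MrpipeError("|inside_corr| must be <= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise MrpipeError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.frac_palindromic <= 1:
            raise MrpipeError("frac_palindromic must be in [0, 1]")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise MrpipeError("sample sizes must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional",
                                        "inside_violating"):
            raise MrpipeError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if not 0 <= self.n_outlier_snps <= self.n_snps:
            raise MrpipeError("n_outlier_snps must be in [0, n_snps]")
        if self.ld_block_size < 1:
            raise MrpipeError("ld_block_size must be >= 1")
        if not 0 <= self.ld_r2_within < 1:
            raise MrpipeError("ld_r2_within must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth behind one simulated dataset (for tests and audits)."""

    theta_true: float
    gamma_true: np.ndarray
    alpha_true: np.ndarray
    outlier_indices: np.ndarray
    palindromic_indices: np.ndarray
    significance_enforced: np.ndarray
    snp_ids: list[str] = field(default_factory=list)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(c) for name, c in zip(_STAGES, children)}


def _binary_trait_se(n: int, eaf: np.ndarray, case_frac: float) -> np.ndarray:
    # log-OR sampling SD per effect allele under the standard approximation:
    # Var(beta_hat) ~ 1 / (N * 2 p (1-p) * c (1-c))
    v = case_frac * (1.0 - case_frac)
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf) * v)


def _draw_alphas(cfg: SimulationConfig, gamma: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_snps
    if cfg.pleiotropy_mode == "none":
        return np.zeros(n)
    if cfg.pleiotropy_mode == "balanced":
        return rng.normal(0.0, cfg.pleiotropy_sd, n)
    if cfg.pleiotropy_mode == "directional":
        return rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, n)
    # inside_violating: alpha correlated with gamma at inside_corr; gamma is
    # standardized by its realized moments so the target correlation holds
    # regardless of the instrument-effect distribution
    rho = cfg.inside_corr
    sd = np.std(gamma)
    z = (gamma - np.mean(gamma)) / sd if sd > 0 else np.zeros(n)
    eps = rng.normal(0.0, 1.0, n)
    return cfg.pleiotropy_sd * (rho * z
                                + np.sqrt(max(0.0, 1.0 - rho ** 2)) * eps)


def _draw_effects(cfg: SimulationConfig, rngs: dict, eaf: np.ndarray):
    """Numeric core: true and observed effects plus SEs, in model order."""
    n = cfg.n_snps
    se_x = _binary_trait_se(cfg.n_exposure, eaf, cfg.case_frac_exposure)
    se_y = _binary_trait_se(cfg.n_outcome, eaf, cfg.case_frac_outcome)

    # instruments are oriented to the exposure-increasing allele (gamma > 0),
    # as is conventional in MR simulation studies; magnitudes are half-normal
    gamma = np.abs(rngs["gamma"].normal(0.0, cfg.gamma_dist_sd, n))
    e_x = rngs["noise_x"].normal(0.0, 1.0, n) * se_x
    gamma_hat = gamma + e_x

    enforced = np.zeros(n, dtype=bool)
    if cfg.enforce_significance:
        z_crit = sps.norm.isf(GENOME_WIDE_P / 2.0)
        needed = z_crit * se_x * (1.0 + 1e-9)
        weak = np.abs(gamma_hat) < needed
        if weak.any():
            # shift the true effect so the realized estimate lands exactly at
            # the significance boundary while keeping the same noise draw
            sign = np.where(gamma[weak] >= 0, 1.0, -1.0)
            target_hat = sign * needed[weak]
            gamma[weak] = target_hat - e_x[weak]
            gamma_hat[weak] = target_hat
            enforced[weak] = True

    alpha = _draw_alphas(cfg, gamma, rngs["pleiotropy"])

    outlier_idx = np.array([], dtype=int)
    if cfg.n_outlier_snps > 0:
        outlier_idx = np.sort(rngs["outliers"].choice(n, cfg.n_outlier_snps,
                                                      replace=False))
        alpha[outlier_idx] = cfg.outlier_magnitude

    Gamma = cfg.theta * gamma + alpha
    Gamma_hat = Gamma + rngs["noise_y"].normal(0.0, 1.0, n) * se_y
    return gamma, alpha, gamma_hat, Gamma_hat, se_x, se_y, enforced, outlier_idx


def _variant_metadata(cfg: SimulationConfig, rng: np.random.Generator):
    """SNP ids, positions (block layout), EAFs and allele pairs."""
    n = cfg.n_snps
    snp_ids = [f"rs{i + 1:05d}" for i in range(n)]
    block = np.arange(n) // cfg.ld_block_size
    within = np.arange(n) % cfg.ld_block_size
    pos = 1 + block * 2_000_000 + within * 10_000
    chrom = np.full(n, "1")
    eaf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], n)

    n_pal_exact = cfg.frac_palindromic * n
    n_pal = int(round(n_pal_exact))
    if abs(n_pal_exact - n_pal) > 1e-9:
        warnings.warn(
            f"frac_palindromic * n_snps = {n_pal_exact:.3f} is not an integer; "
            f"rounding to {n_pal} palindromic variants",
            stacklevel=3,
        )
    pal_idx = np.sort(rng.choice(n, n_pal, replace=False)) if n_pal else np.array([], int)
    is_pal = np.zeros(n, dtype=bool)
    is_pal[pal_idx] = True

    ea, oa = [], []
    for j in range(n):
        pool = _PALINDROMIC_PAIRS if is_pal[j] else _NONPALINDROMIC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        ea.append(a)
        oa.append(b)
    return snp_ids, chrom, pos, eaf, ea, oa, pal_idx


def make_ld_reference(n_snps: int, block_size: int, r2_within: float,
                      positions: dict[str, tuple[str, int]],
                      seed: int = 0) -> LdReference:
    """Block-diagonal LD reference: within-block pairs share r2 ~ r2_within
    (with small jitter), across-block pairs are unlinked."""
    if block_size < 1:
        raise MrpipeError("block_size must be >= 1")
    if not 0 <= r2_within < 1:
        raise MrpipeError("r2_within must be in [0, 1)")
    snp_ids = list(positions)[:n_snps]
    rng = np.random.default_rng(seed)
    pairs = {}
    if r2_within > 0:
        for b0 in range(0, n_snps, block_size):
            members = snp_ids[b0:b0 + block_size]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    r2 = float(np.clip(r2_within + rng.normal(0.0, 0.005),
                                       0.0, 0.9999))
                    pairs[(members[i], members[j])] = r2
    return LdReference(pairs, positions)


def simulate_two_sample_dataset(
    config: SimulationConfig,
) -> tuple[GwasSummaryStats, GwasSummaryStats, LdReference, TruthRecord]:
    """Generate exposure and outcome summary statistics plus LD reference.

    The outcome table re-encodes a random subset of variants (allele order
    swapped with negated beta, or complementary-strand representation) so
    that harmonization has real work to do; the truth record carries the
    generating effects for every SNP.
    """
    cfg = config
    rngs = _stage_rngs(cfg.seed)
    snp_ids, chrom, pos, eaf, ea, oa, pal_idx = _variant_metadata(cfg, rngs["variants"])
    (gamma, alpha, gamma_hat, Gamma_hat,
     se_x, se_y, enforced, outlier_idx) = _draw_effects(cfg, rngs, eaf)

    def table(beta, se, n_total):
        p = 2.0 * sps.norm.sf(np.abs(beta) / se)
        return pd.DataFrame({
            "SNP": snp_ids, "CHR": chrom, "BP": pos,
            "EA": ea, "OA": oa, "EAF": eaf,
            "BETA": beta, "SE": se,
            "P": np.clip(p, np.finfo(float).tiny, 1.0),
            "N": n_total,
        })

    exposure = GwasSummaryStats(table(gamma_hat, se_x, cfg.n_exposure), "exposure")

    out_tab = table(Gamma_hat, se_y, cfg.n_outcome)
    enc = rngs["encoding"]
    is_pal = np.zeros(cfg.n_snps, dtype=bool)
    is_pal[pal_idx] = True
    swap = enc.random(cfg.n_snps) < 0.5
    strand = (enc.random(cfg.n_snps) < 0.3) & ~is_pal
    for j in np.flatnonzero(swap):
        out_tab.loc[j, ["EA", "OA"]] = out_tab.loc[j, ["OA", "EA"]].to_numpy()
        out_tab.loc[j, "BETA"] = -out_tab.loc[j, "BETA"]
        out_tab.loc[j, "EAF"] = 1.0 - out_tab.loc[j, "EAF"]
    for j in np.flatnonzero(strand):
        out_tab.loc[j, "EA"] = complement(out_tab.loc[j, "EA"])
        out_tab.loc[j, "OA"] = complement(out_tab.loc[j, "OA"])
    outcome = GwasSummaryStats(out_tab, "outcome")

    positions = {s: ("1", int(p)) for s, p in zip(snp_ids, pos)}
    ld = make_ld_reference(cfg.n_snps, cfg.ld_block_size, cfg.ld_r2_within,
                           positions, seed=int(rngs["ld"].integers(2 ** 31)))

    truth = TruthRecord(
        theta_true=cfg.theta,
        gamma_true=gamma,
        alpha_true=alpha,
        outlier_indices=outlier_idx,
        palindromic_indices=pal_idx,
        significance_enforced=enforced,
        snp_ids=snp_ids,
    )
    return exposure, outcome, ld, truth


def simulate_harmonized(
    config: SimulationConfig,
) -> tuple[HarmonizedInstrumentSet, TruthRecord]:
    """Fast path for estimator studies: the same effect model as
    :func:`simulate_two_sample_dataset` delivered directly as an aligned
    instrument set, skipping allele bookkeeping so the instrument count is
    exactly ``n_snps``."""
    cfg = config
    rngs = _stage_rngs(cfg.seed)
    eaf = rngs["variants"].uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_snps)
    (gamma, alpha, gamma_hat, Gamma_hat,
     se_x, se_y, enforced, outlier_idx) = _draw_effects(cfg, rngs, eaf)
    snp_ids = [f"rs{i + 1:05d}" for i in range(cfg.n_snps)]
    hset = HarmonizedInstrumentSet(
        snp_ids=snp_ids,
        gamma_hat=gamma_hat, se_x=se_x,
        Gamma_hat=Gamma_hat, se_y=se_y,
    )
    truth = TruthRecord(
        theta_true=cfg.theta,
        gamma_true=gamma,
        alpha_true=alpha,
        outlier_indices=outlier_idx,
        palindromic_indices=np.array([], dtype=int),
        significance_enforced=enforced,
        snp_ids=snp_ids,
    )
    return hset, truth
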