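"""Heterogeneity and horizontal-pleiotropy diagnostics.

Global heterogeneity of the Wald ratios is measured by Cochran's Q under the
zero-intercept radial IVW model and by Ruecker's Q' under the free-intercept
radial Egger model; their difference Q - Q' (one degree of freedom) indexes
how much of the heterogeneity the Egger intercept absorbs, and the ratio
Q'/Q is reported descriptively.  Directional pleiotropy is tested through
the Egger intercept (t test on L - 2 df) and substantial pleiotropy through
the MR-PRESSO battery: a residual-sum-of-squares global test calibrated by
parametric bootstrap, per-SNP outlier tests with Bonferroni adjustment, and
a distortion test comparing estimates before and after outlier removal.

The PRESSO residuals here are weighted by the outcome-side variances
(se_y^2), the simple variant of the published test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .datatypes import EggerFit, HarmonizedInstrumentSet, MrpipeError, RadialFit
from .estimators import radial_egger, radial_ivw

__all__ = [
    "HeterogeneityReport",
    "PressoReport",
    "cochran_q",
    "rucker_q_prime",
    "q_difference_test",
    "egger_intercept_test",
    "presso_global",
    "presso_outliers",
    "presso_distortion",
    "heterogeneity_report",
]


@dataclass
class HeterogeneityReport:
    """Bundled Q / Q' / Egger-intercept diagnostics for one instrument set."""

    q_total: float
    q_df: int
    q_pval: float
    q_prime_total: float
    q_prime_df: int
    q_prime_pval: float
    q_diff: float
    q_diff_pval: float
    q_ratio: float
    egger_intercept: float
    intercept_se: float
    intercept_pval: float
    q_j: np.ndarray = field(default_factory=lambda: np.array([]))
    q_pval_j: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        d = {
            "q_total": self.q_total, "q_df": self.q_df, "q_pval": self.q_pval,
            "q_prime_total": self.q_prime_total, "q_prime_df": self.q_prime_df,
            "q_prime_pval": self.q_prime_pval,
            "q_diff": self.q_diff, "q_diff_pval": self.q_diff_pval,
            "q_ratio": self.q_ratio,
            "egger_intercept": self.egger_intercept,
            "intercept_se": self.intercept_se,
            "intercept_pval": self.intercept_pval,
        }
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in d.items()}


@dataclass
class PressoReport:
    """MR-PRESSO global / outlier / distortion results."""

    global_rss_obs: float
    global_pval: float
    outlier_pval: np.ndarray
    outlier_indices: np.ndarray
    distortion_coefficient: float | None
    distortion_pval: float | None
    n_bootstrap: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "global_rss_obs": float(self.global_rss_obs),
            "global_pval": float(self.global_pval),
            "outlier_pval": [float(p) for p in self.outlier_pval],
            "outlier_indices": [int(i) for i in self.outlier_indices],
            "distortion_coefficient": (None if self.distortion_coefficient is None
                                       else float(self.distortion_coefficient)),
            "distortion_pval": (None if self.distortion_pval is None
                                else float(self.distortion_pval)),
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }


def cochran_q(fit: RadialFit) -> tuple[float, int, float, np.ndarray, np.ndarray]:
    """Global and per-SNP Cochran's Q from a radial IVW fit.

    Q ~ chi2(L-1) under homogeneity; each SNP's contribution q_j is referred
    to chi2(1) for an outlier p-value.
    """
    if fit.n_snps < 2:
        raise MrpipeError("Cochran's Q needs at least 2 instruments")
    p_j = sps.chi2.sf(fit.q_j, 1)
    return fit.q_total, fit.df, fit.q_pval, fit.q_j, p_j


def rucker_q_prime(fit: EggerFit) -> tuple[float, int, float]:
    """Ruecker's Q' (sum of squared radial-Egger residuals), chi2(L-2)."""
    p = float(sps.chi2.sf(fit.q_prime_total, fit.df))
    return fit.q_prime_total, fit.df, p


def q_difference_test(q: float, q_prime: float,
                      tolerance: float = 1e-8) -> tuple[float, float, float]:
    """(Q - Q', chi2(1) p, ratio Q'/Q).

    The difference tests the Egger intercept's contribution to
    heterogeneity; the ratio is descriptive (defined as 1 when Q = 0).
    """
    if q < q_prime - tolerance:
        raise MrpipeError(f"Q ({q}) < Q' ({q_prime}); models are nested")
    diff = max(0.0, q - q_prime)
    p = float(sps.chi2.sf(diff, 1))
    ratio = 1.0 if q == 0 else q_prime / q
    return diff, p, ratio


def egger_intercept_test(fit: EggerFit) -> float:
    """Two-sided t test of a zero Egger intercept (df = L - 2)."""
    return fit.intercept_pval


def _loo_ivw(gamma: np.ndarray, Gamma: np.ndarray,
             w: np.ndarray) -> np.ndarray:
    """Leave-one-out first-order IVW estimates, vectorized.

    Supports batched input of shape (..., L); returns same shape with entry
    j the estimate computed without SNP j.
    """
    ratio = Gamma / gamma
    sw = np.sum(w, axis=-1, keepdims=True)
    swr = np.sum(w * ratio, axis=-1, keepdims=True)
    return (swr - w * ratio) / (sw - w)


def _presso_core(hset: HarmonizedInstrumentSet, n_bootstrap: int, seed: int):
    """Observed weighted residuals, bootstrap residual matrix and RSS null."""
    g, G = hset.gamma_hat, hset.Gamma_hat
    sx, sy = hset.se_x, hset.se_y
    w = g ** 2 / sy ** 2
    theta_loo = _loo_ivw(g, G, w)
    resid2_obs = (G - theta_loo * g) ** 2 / sy ** 2
    rss_obs = float(np.sum(resid2_obs))

    rng = np.random.default_rng(seed)
    # parametric bootstrap under the no-pleiotropy model: expected outcome
    # effect of SNP j is its leave-one-out prediction theta_(-j) * gamma_j
    g_star = rng.normal(g, sx, size=(n_bootstrap, len(g)))
    G_star = rng.normal(theta_loo * g, sy, size=(n_bootstrap, len(g)))
    g_star = np.where(g_star == 0.0, np.finfo(float).tiny, g_star)
    w_star = g_star ** 2 / sy ** 2
    theta_loo_star = _loo_ivw(g_star, G_star, w_star)
    resid2_star = (G_star - theta_loo_star * g_star) ** 2 / sy ** 2
    rss_star = np.sum(resid2_star, axis=1)
    return resid2_obs, rss_obs, resid2_star, rss_star


def presso_global(hset: HarmonizedInstrumentSet, n_bootstrap: int = 1000,
                  seed: int = 0) -> PressoReport:
    """MR-PRESSO global test for substantial horizontal pleiotropy.

    The observed statistic is the sum over SNPs of the squared
    leave-one-out residual weighted by the outcome variance; its null
    distribution is built by parametric bootstrap under the no-pleiotropy
    model and the p-value uses the add-one rule, so it is never below
    1 / (n_bootstrap + 1).
    """
    if hset.n_snps < 4:
        raise MrpipeError("MR-PRESSO needs at least 4 instruments")
    if n_bootstrap < 1:
        raise MrpipeError("n_bootstrap must be >= 1")
    _, rss_obs, _, rss_star = _presso_core(hset, n_bootstrap, seed)
    p = (1.0 + np.sum(rss_star >= rss_obs)) / (n_bootstrap + 1.0)
    return PressoReport(
        global_rss_obs=rss_obs,
        global_pval=float(p),
        outlier_pval=np.array([]),
        outlier_indices=np.array([], dtype=int),
        distortion_coefficient=None,
        distortion_pval=None,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def presso_outliers(hset: HarmonizedInstrumentSet, n_bootstrap: int = 1000,
                    alpha: float = 0.05, seed: int = 0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP MR-PRESSO outlier test.

    Each SNP's observed weighted residual is referred to its own bootstrap
    null distribution; tail probabilities are Bonferroni-adjusted by the
    number of instruments.  Returns (outlier positional indices, adjusted
    per-SNP p-values).
    """
    if hset.n_snps < 4:
        raise MrpipeError("MR-PRESSO needs at least 4 instruments")
    resid2_obs, _, resid2_star, _ = _presso_core(hset, n_bootstrap, seed)
    tail = (1.0 + np.sum(resid2_star >= resid2_obs[None, :], axis=0)) \
        / (n_bootstrap + 1.0)
    p_adj = np.minimum(1.0, hset.n_snps * tail)
    outliers = np.flatnonzero(p_adj < alpha)
    return outliers, p_adj


def presso_distortion(hset: HarmonizedInstrumentSet,
                      outlier_indices: np.ndarray, n_bootstrap: int = 1000,
                      seed: int = 0) -> tuple[float, float]:
    """MR-PRESSO distortion test.

    Distortion (percent) compares the all-SNP IVW estimate with the
    outlier-free estimate; its p-value comes from the distribution of
    distortions obtained by removing random instrument subsets of the same
    size.
    """
    outlier_indices = np.asarray(outlier_indices, dtype=int)
    if outlier_indices.size == 0:
        raise MrpipeError("distortion test requires a nonempty outlier set")
    if outlier_indices.size >= hset.n_snps:
        raise MrpipeError("outlier set must be a strict subset of instruments")
    keep = np.setdiff1d(np.arange(hset.n_snps), outlier_indices)
    if keep.size < 2:
        raise MrpipeError("removing outliers leaves fewer than 2 instruments")

    theta_all = radial_ivw(hset, weight_order="first").theta_hat
    theta_wo = radial_ivw(hset.subset(keep), weight_order="first").theta_hat
    if theta_wo == 0.0:
        raise MrpipeError("outlier-free estimate is exactly 0; distortion undefined")
    distortion = 100.0 * (theta_all - theta_wo) / abs(theta_wo)

    rng = np.random.default_rng(seed)
    k = outlier_indices.size
    null = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        drop = rng.choice(hset.n_snps, k, replace=False)
        kb = np.setdiff1d(np.arange(hset.n_snps), drop)
        th = radial_ivw(hset.subset(kb), weight_order="first").theta_hat
        null[b] = 100.0 * (theta_all - th) / abs(th) if th != 0 else np.inf
    p = (1.0 + np.sum(np.abs(null) >= abs(distortion))) / (n_bootstrap + 1.0)
    return float(distortion), float(p)


def heterogeneity_report(hset: HarmonizedInstrumentSet,
                         weight_order: str = "modified_second"
                         ) -> HeterogeneityReport:
    """Compute the full Q / Q' / intercept diagnostic bundle."""
    ivw = radial_ivw(hset, weight_order=weight_order)
    q, q_df, q_p, q_j, q_p_j = cochran_q(ivw)
    egger = radial_egger(hset, weight_order=weight_order)
    qp, qp_df, qp_p = rucker_q_prime(egger)
    diff, diff_p, ratio = q_difference_test(q, qp)
    return HeterogeneityReport(
        q_total=q, q_df=q_df, q_pval=q_p,
        q_prime_total=qp, q_prime_df=qp_df, q_prime_pval=qp_p,
        q_diff=diff, q_diff_pval=diff_p, q_ratio=ratio,
        egger_intercept=egger.intercept,
        intercept_se=egger.se_intercept,
        intercept_pval=egger.intercept_pval,
        q_j=q_j, q_pval_j=q_p_j,
    )
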