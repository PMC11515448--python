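"""Causal-effect estimators for two-sample MR on harmonized instruments.

The principal estimator is the radial IVW fit with modified second-order
weights.  Writing theta_j = Gamma_hat_j / gamma_hat_j for the per-SNP Wald
ratio and W_j for its inverse variance, the radial parameterization regresses
y_j = sqrt(W_j) * theta_j on x_j = sqrt(W_j) through the origin, so that the
slope is the IVW estimate and each SNP's squared residual is its Cochran Q
contribution.  Modified second-order weights

    W_j(theta) = gamma_hat_j^2 / (se_y_j^2 + theta^2 * se_x_j^2)

acknowledge sampling error on both sides of the instrument and are solved by
fixed-point iteration from the first-order fit.

The pleiotropy-robust battery follows: radial MR-Egger (free intercept
indexing directional pleiotropy, consistent under the InSIDE assumption),
the weighted median (consistent when < 50% of weight is invalid), the
weighted mode (consistent when the largest homogeneous cluster of ratios is
valid), and MR-RAPS (robust adjusted profile score, tolerant of weak
instruments and balanced pleiotropy).  A fixed-effect inverse-variance
meta-analysis pools replicate estimates.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats as sps

from .datatypes import (
    EggerFit,
    HarmonizedInstrumentSet,
    MrEstimate,
    MrpipeError,
    RadialFit,
)

__all__ = [
    "wald_ratios",
    "modified_second_order_weights",
    "first_order_weights",
    "radial_ivw",
    "radial_egger",
    "weighted_median",
    "weighted_mode",
    "mr_raps",
    "fixed_effect_meta",
]

Z95 = 1.959963984540054  # Phi^-1(0.975)

FIXED_POINT_TOL = 1e-10
FIXED_POINT_MAX_ITER = 100


def _check_relevance(hset: HarmonizedInstrumentSet) -> None:
    zero = np.flatnonzero(hset.gamma_hat == 0.0)
    if zero.size:
        names = [hset.snp_ids[i] for i in zero]
        raise MrpipeError(
            f"zero exposure effect (relevance violation) for SNPs: {names}")


def wald_ratios(hset: HarmonizedInstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratio estimates and their first-order standard errors.

    ratio_j = Gamma_hat_j / gamma_hat_j;  se_j = se_y_j / |gamma_hat_j|.
    """
    _check_relevance(hset)
    ratio = hset.Gamma_hat / hset.gamma_hat
    se = hset.se_y / np.abs(hset.gamma_hat)
    return ratio, se


def first_order_weights(hset: HarmonizedInstrumentSet) -> np.ndarray:
    """Inverse-variance weights ignoring exposure-side error:
    gamma_hat^2 / se_y^2."""
    _check_relevance(hset)
    return hset.gamma_hat ** 2 / hset.se_y ** 2


def modified_second_order_weights(hset: HarmonizedInstrumentSet,
                                  theta: float) -> np.ndarray:
    """W_j(theta) = [se_y^2/gamma_hat^2 + theta^2 se_x^2/gamma_hat^2]^-1."""
    if not np.isfinite(theta):
        raise MrpipeError("theta must be finite")
    _check_relevance(hset)
    return hset.gamma_hat ** 2 / (hset.se_y ** 2 + theta ** 2 * hset.se_x ** 2)


def _radial_slope(ratio: np.ndarray, w: np.ndarray) -> float:
    # zero-intercept WLS of y = sqrt(w) ratio on x = sqrt(w):
    # slope = sum(x y) / sum(x^2) = sum(w ratio) / sum(w)
    return float(np.sum(w * ratio) / np.sum(w))


def radial_ivw(hset: HarmonizedInstrumentSet,
               weight_order: str = "modified_second",
               max_weight_iter: int = FIXED_POINT_MAX_ITER,
               tol: float = FIXED_POINT_TOL,
               random_effects: bool = True) -> RadialFit:
    """Radial IVW fit; the package's principal estimator.

    With ``modified_second`` weights the slope and the weights are mutually
    dependent and solved by fixed-point iteration starting from the
    first-order fit.  The standard error is (sum W)^-1/2, inflated by
    max(1, sqrt(Q/df)) under the multiplicative random-effects convention
    (set ``random_effects=False`` for the plain fixed-effect SE).
    """
    if hset.n_snps < 2:
        raise MrpipeError("radial IVW needs at least 2 instruments")
    if weight_order not in ("first", "modified_second"):
        raise MrpipeError(f"unknown weight_order {weight_order!r}")
    ratio, _ = wald_ratios(hset)

    w = first_order_weights(hset)
    theta = _radial_slope(ratio, w)
    n_iter = 0
    if weight_order == "modified_second":
        trail = [theta]
        for n_iter in range(1, max_weight_iter + 1):
            w = modified_second_order_weights(hset, theta)
            theta_new = _radial_slope(ratio, w)
            trail.append(theta_new)
            if abs(theta_new - theta) < tol:
                theta = theta_new
                break
            theta = theta_new
        else:
            raise MrpipeError(
                "modified-second-order weight fixed point did not converge; "
                f"iterate trail: {trail}")
        w = modified_second_order_weights(hset, theta)

    q_j = w * (ratio - theta) ** 2
    q_total = float(np.sum(q_j))
    df = hset.n_snps - 1
    q_pval = float(sps.chi2.sf(q_total, df))
    se = float(1.0 / np.sqrt(np.sum(w)))
    if random_effects:
        se *= max(1.0, np.sqrt(q_total / df))
    return RadialFit(
        snp_ids=list(hset.snp_ids),
        theta_hat=float(theta),
        se=se,
        ratio=ratio,
        weights=w,
        q_j=q_j,
        q_total=q_total,
        df=df,
        q_pval=q_pval,
        weight_order=weight_order,
        n_weight_iterations=n_iter,
    )


def radial_egger(hset: HarmonizedInstrumentSet,
                 weight_order: str = "modified_second") -> EggerFit:
    """Radial MR-Egger: weighted fit of y_j = b0 + b1 * sqrt(W_j).

    The slope b1 is the causal estimate; the intercept b0 indexes
    directional pleiotropy.  Squared residuals are the per-SNP contributions
    to Ruecker's Q'; standard errors use the regression dispersion
    sqrt(Q'/df) (no floor, so the intercept t test on df = L - 2 stays
    exactly calibrated under homogeneity).
    """
    if hset.n_snps < 3:
        raise MrpipeError("radial Egger needs at least 3 instruments")
    ratio, _ = wald_ratios(hset)
    if weight_order == "modified_second":
        w = radial_ivw(hset, weight_order="modified_second").weights
    elif weight_order == "first":
        w = first_order_weights(hset)
    else:
        raise MrpipeError(f"unknown weight_order {weight_order!r}")

    x = np.sqrt(w)
    y = x * ratio
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    b0, b1 = float(coef[0]), float(coef[1])
    resid = y - X @ coef
    q_prime_j = resid ** 2
    q_prime = float(np.sum(q_prime_j))
    df = hset.n_snps - 2
    XtX_inv = np.linalg.inv(X.T @ X)
    if q_prime < 1e-12 * (float(np.sum(y ** 2)) + 1.0):
        # numerically perfect fit: the residual scale is pure round-off and
        # the t statistics are 0/0; report a degenerate exact fit
        q_prime_j = np.zeros_like(q_prime_j)
        q_prime = 0.0
        se_b0 = se_b1 = 0.0
        p_b0 = p_b1 = 1.0
    else:
        scale = np.sqrt(q_prime / df)
        se_b0 = float(np.sqrt(XtX_inv[0, 0]) * scale)
        se_b1 = float(np.sqrt(XtX_inv[1, 1]) * scale)
        p_b0 = float(2.0 * sps.t.sf(abs(b0) / se_b0, df)) if se_b0 > 0 else 1.0
        p_b1 = float(2.0 * sps.t.sf(abs(b1) / se_b1, df)) if se_b1 > 0 else 1.0
    return EggerFit(
        snp_ids=list(hset.snp_ids),
        intercept=b0,
        slope=b1,
        se_intercept=se_b0,
        se_slope=se_b1,
        intercept_pval=p_b0,
        slope_pval=p_b1,
        weights=w,
        q_prime_j=q_prime_j,
        q_prime_total=q_prime,
        df=df,
    )


def _normal_estimate(method: str, beta: float, se: float, n_snps: int,
                     **diagnostics) -> MrEstimate:
    if se > 0:
        pval = float(2.0 * sps.norm.sf(abs(beta) / se))
    else:
        pval = 1.0
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=max(pval, np.finfo(float).tiny),
        n_snps=n_snps,
        diagnostics=dict(diagnostics),
    )


def _weighted_median_point(ratio: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(ratio, kind="stable")
    r = ratio[order]
    ww = w[order]
    s = (np.cumsum(ww) - 0.5 * ww) / np.sum(ww)
    return float(np.interp(0.5, s, r))


def _parametric_bootstrap(hset: HarmonizedInstrumentSet, n_boot: int,
                          seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample (gamma*, Gamma*) ~ Normal around the observed effects."""
    rng = np.random.default_rng(seed)
    g = rng.normal(hset.gamma_hat, hset.se_x, size=(n_boot, hset.n_snps))
    G = rng.normal(hset.Gamma_hat, hset.se_y, size=(n_boot, hset.n_snps))
    return g, G


def weighted_median(hset: HarmonizedInstrumentSet, n_boot: int = 2000,
                    seed: int = 0) -> MrEstimate:
    """Weighted median of the Wald ratios (first-order inverse-variance
    weights), SE by parametric bootstrap.

    The estimate interpolates the ordered ratios at standardized cumulative
    weight 0.5 and is consistent as long as valid instruments carry more
    than half of the total weight.
    """
    if hset.n_snps < 3:
        raise MrpipeError("weighted median needs at least 3 instruments")
    if n_boot < 200:
        raise MrpipeError("n_boot must be >= 200")
    ratio, _ = wald_ratios(hset)
    w = first_order_weights(hset)
    point = _weighted_median_point(ratio, w)

    g, G = _parametric_bootstrap(hset, n_boot, seed)
    g = np.where(g == 0.0, np.finfo(float).tiny, g)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        rb = G[b] / g[b]
        wb = g[b] ** 2 / hset.se_y ** 2
        boot[b] = _weighted_median_point(rb, wb)
    se = float(np.std(boot, ddof=1))
    return _normal_estimate("weighted_median", point, se, hset.n_snps,
                            n_boot=n_boot, seed=seed)


def _mode_bandwidth(ratio: np.ndarray, se: np.ndarray, phi: float) -> float:
    # MAD-based analogue of the normal-reference rule, scaled by phi
    n = len(ratio)
    mad = np.median(np.abs(ratio - np.median(ratio))) * 1.4826
    spread = min(np.std(ratio, ddof=1), mad) if mad > 0 else np.std(ratio, ddof=1)
    if spread == 0:
        return 0.0
    return float(phi * 0.9 * spread * n ** (-1 / 5))


def _mode_point(ratio: np.ndarray, w: np.ndarray, phi: float,
                n_grid: int = 512) -> float:
    h = _mode_bandwidth(ratio, None, phi)
    if h == 0.0:  # all ratios identical (or a single cluster with no spread)
        vals, idx = np.unique(ratio, return_inverse=True)
        if len(vals) == 1:
            return float(vals[0])
        totals = np.bincount(idx, weights=w)
        return float(vals[np.argmax(totals)])
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, n_grid)
    dens = np.sum(w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h) ** 2),
                  axis=0)
    peak = np.flatnonzero(dens == dens.max())
    if len(peak) > 1:
        warnings.warn("weighted mode: exact density tie; returning the "
                      "peak with larger local weight", stacklevel=2)
        local = [np.sum(w * (np.abs(ratio - grid[p]) <= h)) for p in peak]
        return float(grid[peak[int(np.argmax(local))]])
    return float(grid[peak[0]])


def weighted_mode(hset: HarmonizedInstrumentSet, bandwidth_phi: float = 1.0,
                  n_boot: int = 2000, seed: int = 0) -> MrEstimate:
    """Mode of the kernel-smoothed weighted density of Wald ratios.

    Consistent when the largest group of instruments sharing the same ratio
    is valid (zero modal pleiotropy).  The bandwidth follows a
    median-absolute-deviation rule scaled by ``bandwidth_phi``; the density
    is evaluated on a 512-point grid spanning the ratios +/- 3 bandwidths.
    """
    if hset.n_snps < 3:
        raise MrpipeError("weighted mode needs at least 3 instruments")
    if bandwidth_phi <= 0:
        raise MrpipeError("bandwidth_phi must be positive")
    ratio, _ = wald_ratios(hset)
    w = first_order_weights(hset)
    point = _mode_point(ratio, w, bandwidth_phi)

    g, G = _parametric_bootstrap(hset, n_boot, seed)
    g = np.where(g == 0.0, np.finfo(float).tiny, g)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        rb = G[b] / g[b]
        wb = g[b] ** 2 / hset.se_y ** 2
        boot[b] = _mode_point(rb, wb, bandwidth_phi)
    se = float(np.std(boot, ddof=1))
    return _normal_estimate("weighted_mode", point, se, hset.n_snps,
                            bandwidth_phi=bandwidth_phi, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# MR-RAPS

_HUBER_K = 1.345


def _psi(t: np.ndarray, loss: str) -> np.ndarray:
    if loss == "plain":
        return t
    return np.clip(t, -_HUBER_K, _HUBER_K)


def _psi_moments(loss: str) -> tuple[float, float]:
    """(delta, e2) = (E[psi(Z) Z], E[psi(Z)^2]) for standard normal Z."""
    if loss == "plain":
        return 1.0, 1.0
    k = _HUBER_K
    inner = 2.0 * sps.norm.cdf(k) - 1.0
    delta = inner  # E[Z^2; |Z|<k] + k E[|Z|; |Z|>k] collapses to P(|Z|<k)
    e2 = inner - 2.0 * k * sps.norm.pdf(k) + 2.0 * k ** 2 * sps.norm.sf(k)
    return delta, e2


def _raps_score(theta: float, tau2: float, hset: HarmonizedInstrumentSet,
                loss: str) -> float:
    sig2 = hset.se_y ** 2 + theta ** 2 * hset.se_x ** 2 + tau2
    sig = np.sqrt(sig2)
    t = (hset.Gamma_hat - theta * hset.gamma_hat) / sig
    # d t_j / d theta
    dt = (-hset.gamma_hat * sig - (hset.Gamma_hat - theta * hset.gamma_hat)
          * theta * hset.se_x ** 2 / sig) / sig2
    return float(np.sum(_psi(t, loss) * dt))


def _solve_theta(tau2: float, hset: HarmonizedInstrumentSet, loss: str,
                 center: float, width: float) -> float:
    lo, hi = center - width, center + width
    f_lo = _raps_score(lo, tau2, hset, loss)
    f_hi = _raps_score(hi, tau2, hset, loss)
    if f_lo * f_hi > 0:  # widen the bracket once
        lo, hi = center - 10 * width, center + 10 * width
        f_lo = _raps_score(lo, tau2, hset, loss)
        f_hi = _raps_score(hi, tau2, hset, loss)
        if f_lo * f_hi > 0:
            raise MrpipeError(
                "MR-RAPS profile score has no sign change in "
                f"[{lo:.4g}, {hi:.4g}] (tau2 = {tau2:.4g})")
    return float(optimize.brentq(
        lambda th: _raps_score(th, tau2, hset, loss), lo, hi, xtol=1e-12))


def mr_raps(hset: HarmonizedInstrumentSet, overdispersion: bool = True,
            loss: str = "huber") -> MrEstimate:
    """MR-RAPS: robust adjusted profile score estimate.

    Solves sum_j psi(t_j(theta)) dt_j/dtheta = 0 for the standardized
    residuals t_j = (Gamma_hat - theta gamma_hat) / sqrt(se_y^2 +
    theta^2 se_x^2 + tau^2), with psi the identity (``plain``) or the Huber
    function (``huber``, k = 1.345).  With ``overdispersion`` a systematic
    pleiotropy variance tau^2 >= 0 is profiled out via the second moment of
    the standardized residuals.  SE by the sandwich formula.
    """
    if hset.n_snps < 3:
        raise MrpipeError("MR-RAPS needs at least 3 instruments")
    if loss not in ("plain", "huber"):
        raise MrpipeError(f"unknown loss {loss!r}")
    _check_relevance(hset)

    ivw = radial_ivw(hset, weight_order="first")
    center, width = ivw.theta_hat, max(10.0 * ivw.se, 1e-3)
    delta, e2 = _psi_moments(loss)

    def moment_gap(tau2: float) -> float:
        th = _solve_theta(tau2, hset, loss, center, width)
        sig2 = hset.se_y ** 2 + th ** 2 * hset.se_x ** 2 + tau2
        t = (hset.Gamma_hat - th * hset.gamma_hat) / np.sqrt(sig2)
        return float(np.mean(_psi(t, loss) * t) - delta)

    tau2 = 0.0
    if overdispersion and moment_gap(0.0) > 0:
        hi = float(np.max(hset.se_y ** 2))
        for _ in range(60):
            if moment_gap(hi) < 0:
                break
            hi *= 4.0
        tau2 = float(optimize.brentq(moment_gap, 0.0, hi, xtol=1e-14))

    theta = _solve_theta(tau2, hset, loss, center, width)

    sig2 = hset.se_y ** 2 + theta ** 2 * hset.se_x ** 2 + tau2
    sig = np.sqrt(sig2)
    dt = (-hset.gamma_hat * sig - (hset.Gamma_hat - theta * hset.gamma_hat)
          * theta * hset.se_x ** 2 / sig) / sig2
    V = e2 * float(np.sum(dt ** 2))
    h = max(1e-7, 1e-6 * abs(theta))
    D = (_raps_score(theta + h, tau2, hset, loss)
         - _raps_score(theta - h, tau2, hset, loss)) / (2 * h)
    se = float(np.sqrt(V) / abs(D)) if D != 0 else float("inf")
    return _normal_estimate("mr_raps", theta, se, hset.n_snps,
                            overdispersion=overdispersion, loss=loss,
                            tau2=tau2)


def fixed_effect_meta(estimates: list[MrEstimate]) -> MrEstimate:
    """Inverse-variance fixed-effect pooling of replicate estimates.

    Requires >= 2 estimates of the same method; the pooled effect is
    sum(b_k / se_k^2) / sum(1 / se_k^2) with SE (sum 1/se_k^2)^-1/2.
    """
    if len(estimates) < 2:
        raise MrpipeError("fixed-effect meta-analysis needs >= 2 estimates")
    methods = {e.method for e in estimates}
    outcomes = {e.diagnostics.get("outcome") for e in estimates}
    if len(methods) > 1 or len(outcomes) > 1:
        raise MrpipeError(
            f"cannot pool mismatched estimates: methods={methods}, "
            f"outcomes={outcomes}")
    b = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(se <= 0):
        raise MrpipeError("non-positive SE in meta-analysis input")
    w = 1.0 / se ** 2
    beta = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    est = _normal_estimate("meta_fixed", beta, pooled_se,
                           int(sum(e.n_snps for e in estimates)),
                           pooled_from=sorted(methods)[0],
                           k_studies=len(estimates))
    out = estimates[0].diagnostics.get("outcome")
    if out is not None:
        est.diagnostics["outcome"] = out
    return est
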