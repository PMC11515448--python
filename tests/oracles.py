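"""Independent brute-force oracles used to check the estimators.

Everything here is deliberately coded by a different route than the package:
statsmodels fits, explicit loops, and dense-grid scans instead of the
package's closed forms and root-finders.
"""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm


def ivw_gls_oracle(gamma, se_x, Gamma, se_y, weight_order="modified_second",
                   n_iter=200, tol=1e-13):
    """Radial IVW via statsmodels zero-intercept WLS with the same
    fixed-point weight rule, iterated to convergence."""
    gamma, se_x = np.asarray(gamma, float), np.asarray(se_x, float)
    Gamma, se_y = np.asarray(Gamma, float), np.asarray(se_y, float)
    ratio = Gamma / gamma
    w = gamma ** 2 / se_y ** 2
    theta = sm.WLS(np.sqrt(w) * ratio, np.sqrt(w)).fit().params[0]
    if weight_order == "modified_second":
        for _ in range(n_iter):
            w = gamma ** 2 / (se_y ** 2 + theta ** 2 * se_x ** 2)
            new = sm.WLS(np.sqrt(w) * ratio, np.sqrt(w)).fit().params[0]
            if abs(new - theta) < tol:
                theta = new
                break
            theta = new
        w = gamma ** 2 / (se_y ** 2 + theta ** 2 * se_x ** 2)
    q = float(np.sum(w * (ratio - theta) ** 2))
    df = len(gamma) - 1
    se_fe = 1.0 / np.sqrt(np.sum(w))
    se = se_fe * max(1.0, np.sqrt(q / df))
    return float(theta), float(se), q


def egger_wls_oracle(gamma, se_x, Gamma, se_y, weights):
    """Radial Egger via statsmodels OLS of y = b0 + b1 sqrt(w)."""
    ratio = np.asarray(Gamma, float) / np.asarray(gamma, float)
    x = np.sqrt(np.asarray(weights, float))
    y = x * ratio
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    b0, b1 = fit.params
    q_prime = float(np.sum(fit.resid ** 2))
    return float(b0), float(b1), q_prime


def weighted_median_oracle(ratio, w):
    """Cumulative-weight interpolation coded with an explicit loop."""
    pairs = sorted(zip(ratio, w))
    total = sum(p[1] for p in pairs)
    cum = 0.0
    s = []
    for _, wi in pairs:
        s.append((cum + wi / 2.0) / total)
        cum += wi
    # find bracketing pair around 0.5 and interpolate linearly
    if s[0] >= 0.5:
        return pairs[0][0]
    for i in range(1, len(s)):
        if s[i] >= 0.5:
            r0, r1 = pairs[i - 1][0], pairs[i][0]
            frac = (0.5 - s[i - 1]) / (s[i] - s[i - 1])
            return r0 + frac * (r1 - r0)
    return pairs[-1][0]


def mode_grid_oracle(ratio, w, h, lo, hi, n_grid=200_001):
    """Dense-grid argmax of the gaussian-kernel weighted density."""
    ratio, w = np.asarray(ratio, float), np.asarray(w, float)
    grid = np.linspace(lo, hi, n_grid)
    best_x, best_d = grid[0], -np.inf
    for x in grid:
        d = float(np.sum(w * np.exp(-0.5 * ((x - ratio) / h) ** 2)))
        if d > best_d:
            best_d, best_x = d, x
    return best_x


def raps_score_scan_oracle(gamma, se_x, Gamma, se_y, lo, hi, n_grid=400_001):
    """Dense-grid sign-change scan of the plain profile score (tau2 = 0)."""
    gamma, se_x = np.asarray(gamma, float), np.asarray(se_x, float)
    Gamma, se_y = np.asarray(Gamma, float), np.asarray(se_y, float)

    def score(th):
        sig2 = se_y ** 2 + th ** 2 * se_x ** 2
        sig = np.sqrt(sig2)
        t = (Gamma - th * gamma) / sig
        dt = (-gamma * sig - (Gamma - th * gamma) * th * se_x ** 2 / sig) / sig2
        return float(np.sum(t * dt))

    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([score(th) for th in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    assert sign_change.size >= 1, "no sign change on the scan grid"
    i = sign_change[0]
    # linear interpolation of the crossing
    return grid[i] - vals[i] * (grid[i + 1] - grid[i]) / (vals[i + 1] - vals[i])


def meta_oracle(betas, ses):
    """Hand-computed inverse-variance average."""
    num = sum(b / s ** 2 for b, s in zip(betas, ses))
    den = sum(1.0 / s ** 2 for s in ses)
    return num / den, den ** -0.5


def select_scan_oracle(table, p_threshold):
    """Linear scan for genome-wide significance."""
    return [row.SNP for row in table.itertuples() if row.P < p_threshold]


def clump_greedy_oracle(candidates, pvals, positions, r2_lookup,
                        r2_cutoff, window_kb):
    """Independently coded greedy clumping (explicit removal loop)."""
    pool = list(candidates)
    kept = []
    while pool:
        pool.sort(key=lambda s: (pvals[s], s))
        index = pool[0]
        kept.append(index)
        chrom_i, pos_i = positions[index]
        nxt = []
        for s in pool[1:]:
            chrom_s, pos_s = positions[s]
            same = chrom_s == chrom_i and abs(pos_s - pos_i) <= window_kb * 1000
            if same and r2_lookup(index, s) >= r2_cutoff:
                continue
            nxt.append(s)
        pool = nxt
    return kept
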