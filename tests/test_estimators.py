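"""Estimator correctness: closed-form cases, independent oracles, and the
structural invariants (scale equivariance, order invariance, known limits)."""

import dataclasses

import numpy as np
import pytest

from mrpipe.datatypes import HarmonizedInstrumentSet, MrEstimate, MrpipeError
from mrpipe.estimators import (
    _mode_bandwidth,
    first_order_weights,
    fixed_effect_meta,
    modified_second_order_weights,
    mr_raps,
    radial_egger,
    radial_ivw,
    wald_ratios,
    weighted_median,
    weighted_mode,
)

from oracles import (
    egger_wls_oracle,
    ivw_gls_oracle,
    meta_oracle,
    mode_grid_oracle,
    raps_score_scan_oracle,
    weighted_median_oracle,
)


def _hset(gamma, se_x, Gamma, se_y):
    gamma = np.asarray(gamma, float)
    return HarmonizedInstrumentSet(
        snp_ids=[f"v{i}" for i in range(len(gamma))],
        gamma_hat=gamma,
        se_x=np.broadcast_to(np.asarray(se_x, float), gamma.shape).copy(),
        Gamma_hat=np.asarray(Gamma, float),
        se_y=np.broadcast_to(np.asarray(se_y, float), gamma.shape).copy(),
    )


def _scaled(hset, c):
    """Multiply all outcome-side quantities by c."""
    return HarmonizedInstrumentSet(
        snp_ids=list(hset.snp_ids), gamma_hat=hset.gamma_hat.copy(),
        se_x=hset.se_x.copy(), Gamma_hat=c * hset.Gamma_hat,
        se_y=c * hset.se_y)


class TestWaldRatios:
    def test_direct_arithmetic(self):
        h = _hset([0.1, 0.2], 0.01, [0.003, 0.0], [0.001, 0.001])
        ratio, se = wald_ratios(h)
        assert ratio[0] == pytest.approx(0.03)
        assert se[0] == pytest.approx(0.01)
        assert ratio[1] == 0.0

    def test_zero_gamma_is_relevance_error(self):
        h = _hset([0.1, 0.0], 0.01, [0.01, 0.01], 0.001)
        with pytest.raises(MrpipeError, match="v1"):
            wald_ratios(h)

    def test_matches_elementwise_division(self, twelve_snp_set):
        ratio, se = wald_ratios(twelve_snp_set)
        np.testing.assert_allclose(
            ratio, twelve_snp_set.Gamma_hat / twelve_snp_set.gamma_hat)
        np.testing.assert_allclose(
            se, twelve_snp_set.se_y / np.abs(twelve_snp_set.gamma_hat))


class TestWeights:
    def test_theta_zero_reduces_to_first_order(self, twelve_snp_set):
        np.testing.assert_allclose(
            modified_second_order_weights(twelve_snp_set, 0.0),
            first_order_weights(twelve_snp_set))

    def test_vanishing_exposure_se_makes_weights_theta_free(self):
        h = _hset([0.3, 0.5, 0.7], 1e-30, [0.01, 0.02, 0.03], 0.01)
        np.testing.assert_allclose(modified_second_order_weights(h, 0.0),
                                   modified_second_order_weights(h, 5.0),
                                   rtol=1e-12)

    def test_scalar_oracle(self):
        h = _hset([0.1], 0.01, [0.003], 0.001)
        w = modified_second_order_weights(h, 0.03)
        expected = 1.0 / (0.001 ** 2 / 0.1 ** 2 + 0.03 ** 2 * 0.01 ** 2 / 0.1 ** 2)
        assert w[0] == pytest.approx(expected, rel=1e-12)


class TestRadialIvw:
    def test_two_identical_snps_return_common_ratio(self):
        h = _hset([0.4, 0.4], 0.03, [0.02, 0.02], 0.01)
        fit = radial_ivw(h)
        assert fit.theta_hat == pytest.approx(0.05)
        assert fit.q_total == pytest.approx(0.0, abs=1e-20)

    def test_equal_ratios_zero_heterogeneity(self):
        h = _hset([0.2, 0.4, 0.8], 0.03, [0.01, 0.02, 0.04], 0.01)
        fit = radial_ivw(h)
        assert fit.theta_hat == pytest.approx(0.05)
        assert fit.q_total == pytest.approx(0.0, abs=1e-18)
        assert fit.q_pval == pytest.approx(1.0)

    def test_first_order_noiseless_is_exact(self):
        gamma = np.array([0.2, 0.35, 0.5, 0.65])
        theta = 0.07
        h = _hset(gamma, 0.02, theta * gamma, 0.01)
        fit = radial_ivw(h, weight_order="first")
        assert fit.theta_hat == pytest.approx(theta, abs=1e-15)

    def test_gls_oracle_five_snps(self):
        rng = np.random.default_rng(17)
        gamma = rng.uniform(0.2, 0.8, 5)
        h = _hset(gamma, rng.uniform(0.02, 0.04, 5),
                  0.05 * gamma + rng.normal(0, 0.01, 5),
                  rng.uniform(0.008, 0.015, 5))
        fit = radial_ivw(h)
        th, se, q = ivw_gls_oracle(h.gamma_hat, h.se_x, h.Gamma_hat, h.se_y)
        assert fit.theta_hat == pytest.approx(th, abs=1e-10)
        assert fit.se == pytest.approx(se, abs=1e-10)
        assert fit.q_total == pytest.approx(q, abs=1e-8)

    def test_q_decomposition(self, twelve_snp_set):
        fit = radial_ivw(twelve_snp_set)
        assert fit.q_total == pytest.approx(np.sum(fit.q_j), abs=1e-10)
        assert fit.df == fit.n_snps - 1
        assert (fit.weights > 0).all()

    def test_needs_two_snps(self):
        h = _hset([0.4], 0.03, [0.02], 0.01)
        with pytest.raises(MrpipeError):
            radial_ivw(h)


class TestRadialEgger:
    def test_noiseless_no_pleiotropy_recovers_exactly(self):
        gamma = np.array([0.2, 0.4, 0.6, 0.8])
        theta = 0.06
        h = _hset(gamma, 0.02, theta * gamma, 0.01)
        fit = radial_egger(h)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.slope == pytest.approx(theta, abs=1e-12)

    def test_shift_invariance_of_slope(self):
        rng = np.random.default_rng(23)
        gamma = rng.uniform(0.2, 0.8, 6)
        se_y = rng.uniform(0.008, 0.015, 6)
        Gamma = 0.05 * gamma + rng.normal(0, 0.01, 6)
        h = _hset(gamma, 0.02, Gamma, se_y)
        base = radial_egger(h, weight_order="first")
        # adding c to every radial response shifts the intercept only;
        # with first-order weights sqrt(W) = gamma/se_y, so Gamma -> Gamma +
        # c * se_y adds exactly c to each y_j
        c = 0.7
        shifted = radial_egger(_hset(gamma, 0.02, Gamma + c * se_y, se_y),
                               weight_order="first")
        assert shifted.intercept == pytest.approx(base.intercept + c, abs=1e-10)
        assert shifted.slope == pytest.approx(base.slope, abs=1e-10)

    def test_wls_oracle_six_snps(self):
        rng = np.random.default_rng(29)
        gamma = rng.uniform(0.2, 0.8, 6)
        h = _hset(gamma, rng.uniform(0.02, 0.04, 6),
                  0.004 + 0.05 * gamma + rng.normal(0, 0.01, 6),
                  rng.uniform(0.008, 0.015, 6))
        fit = radial_egger(h)
        b0, b1, qp = egger_wls_oracle(h.gamma_hat, h.se_x, h.Gamma_hat,
                                      h.se_y, fit.weights)
        assert fit.intercept == pytest.approx(b0, abs=1e-10)
        assert fit.slope == pytest.approx(b1, abs=1e-10)
        assert fit.q_prime_total == pytest.approx(qp, abs=1e-10)

    def test_needs_three_snps(self):
        h = _hset([0.4, 0.5], 0.03, [0.02, 0.03], 0.01)
        with pytest.raises(MrpipeError):
            radial_egger(h)


class TestWeightedMedian:
    def test_equal_weights_reduce_to_sample_median(self):
        gamma = np.array([0.1, 0.1, 0.1])
        h = _hset(gamma, 0.01, gamma * np.array([1.0, 2.0, 9.0]), 0.01)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_dominant_weight_breakdown_limit(self):
        # one SNP carries ~99.99% of the weight
        h = _hset([10.0, 0.05, 0.05], 0.001,
                  [10.0 * 0.04, 0.05 * 0.9, 0.05 * 1.1], 0.01)
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.04, abs=1e-3)

    def test_interpolation_oracle_seven_snps(self):
        rng = np.random.default_rng(31)
        gamma = rng.uniform(0.2, 0.8, 7)
        h = _hset(gamma, 0.02, 0.05 * gamma + rng.normal(0, 0.01, 7),
                  rng.uniform(0.008, 0.015, 7))
        ratio = h.Gamma_hat / h.gamma_hat
        w = h.gamma_hat ** 2 / h.se_y ** 2
        est = weighted_median(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(weighted_median_oracle(ratio, w),
                                         abs=1e-12)

    def test_bootstrap_se_stable_across_seeds(self, twelve_snp_set):
        a = weighted_median(twelve_snp_set, n_boot=2000, seed=1)
        b = weighted_median(twelve_snp_set, n_boot=2000, seed=2)
        assert a.beta == b.beta
        assert abs(a.se - b.se) / a.se < 0.10

    def test_order_invariance_and_negligible_weight_duplication(self,
                                                                twelve_snp_set):
        h = twelve_snp_set
        base = weighted_median(h, n_boot=200, seed=3).beta
        perm = np.random.default_rng(0).permutation(h.n_snps)
        shuffled = h.subset(perm.tolist())
        assert weighted_median(shuffled, n_boot=200, seed=3).beta == \
            pytest.approx(base, abs=1e-12)
        # appending a SNP with vanishing weight leaves the point unchanged
        dup = HarmonizedInstrumentSet(
            snp_ids=h.snp_ids + ["dup"],
            gamma_hat=np.append(h.gamma_hat, 1e-8),
            se_x=np.append(h.se_x, 0.03),
            Gamma_hat=np.append(h.Gamma_hat, 5.0),
            se_y=np.append(h.se_y, 10.0))
        assert weighted_median(dup, n_boot=200, seed=3).beta == \
            pytest.approx(base, abs=1e-9)


class TestWeightedMode:
    def test_dominant_cluster(self):
        gamma = np.array([0.5, 0.5, 0.5, 0.5])
        ratios = np.array([0.03, 0.03, 0.03, 0.50])
        h = _hset(gamma, 0.01, gamma * ratios, 0.01)
        est = weighted_mode(h, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.03, abs=0.01)

    def test_zero_spread_returns_common_value(self):
        gamma = np.array([0.2, 0.4, 0.6])
        h = _hset(gamma, 0.01, 0.07 * gamma, 0.01)
        for phi in (0.5, 1.0, 2.0):
            est = weighted_mode(h, bandwidth_phi=phi, n_boot=200, seed=1)
            assert est.beta == pytest.approx(0.07, abs=1e-12)

    def test_two_cluster_grid_oracle(self):
        rng = np.random.default_rng(37)
        ratios = np.concatenate([rng.normal(0.03, 0.002, 6),
                                 rng.normal(0.30, 0.002, 3)])
        gamma = rng.uniform(0.3, 0.7, 9)
        h = _hset(gamma, 0.02, gamma * ratios, 0.01)
        est = weighted_mode(h, n_boot=200, seed=1)
        r = h.Gamma_hat / h.gamma_hat
        w = h.gamma_hat ** 2 / h.se_y ** 2
        h_bw = _mode_bandwidth(r, None, 1.0)
        grid_step = (r.max() + 3 * h_bw - (r.min() - 3 * h_bw)) / 511
        oracle = mode_grid_oracle(r, w, h_bw, r.min() - 3 * h_bw,
                                  r.max() + 3 * h_bw)
        assert est.beta == pytest.approx(oracle, abs=grid_step)


class TestMrRaps:
    def test_zero_exposure_noise_plain_equals_ivw(self, twelve_snp_set):
        h = twelve_snp_set
        tiny = HarmonizedInstrumentSet(
            snp_ids=list(h.snp_ids), gamma_hat=h.gamma_hat.copy(),
            se_x=np.full(h.n_snps, 1e-12), Gamma_hat=h.Gamma_hat.copy(),
            se_y=h.se_y.copy())
        est = mr_raps(tiny, overdispersion=False, loss="plain")
        ivw = radial_ivw(tiny, weight_order="first", random_effects=False)
        assert est.beta == pytest.approx(ivw.theta_hat, abs=1e-8)

    def test_grid_scan_oracle_five_snps(self):
        rng = np.random.default_rng(41)
        gamma = rng.uniform(0.3, 0.8, 5)
        h = _hset(gamma, rng.uniform(0.02, 0.04, 5),
                  0.05 * gamma + rng.normal(0, 0.012, 5),
                  rng.uniform(0.008, 0.015, 5))
        est = mr_raps(h, overdispersion=False, loss="plain")
        oracle = raps_score_scan_oracle(h.gamma_hat, h.se_x, h.Gamma_hat,
                                        h.se_y, est.beta - 0.05,
                                        est.beta + 0.05)
        assert est.beta == pytest.approx(oracle, abs=1e-6)

    def test_balanced_pleiotropy_recovery(self):
        """Mean estimate over replicates recovers theta under balanced
        pleiotropy (the setting MR-RAPS is designed for)."""
        from mrpipe import SimulationConfig, simulate_harmonized
        theta = 0.05
        ests = []
        for child in np.random.SeedSequence(43).spawn(500):
            seed = int(child.generate_state(1)[0] % 2 ** 31)
            hset, _ = simulate_harmonized(SimulationConfig(
                n_snps=14, theta=theta, pleiotropy_mode="balanced",
                pleiotropy_sd=0.01, seed=seed))
            ests.append(mr_raps(hset).beta)
        ests = np.array(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - theta) < 3 * mc_se

    def test_records_variant_in_diagnostics(self, twelve_snp_set):
        est = mr_raps(twelve_snp_set)
        assert est.diagnostics["loss"] == "huber"
        assert est.diagnostics["overdispersion"] is True
        assert est.diagnostics["tau2"] >= 0.0


class TestFixedEffectMeta:
    def _e(self, b, se, method="ivw_radial", outcome="y"):
        return MrEstimate(method=method, beta=b, se=se, ci_low=b - 1.96 * se,
                          ci_high=b + 1.96 * se, pval=0.5, n_snps=10,
                          diagnostics={"outcome": outcome})

    def test_identical_inputs_shrink_se_by_sqrt2(self):
        pooled = fixed_effect_meta([self._e(0.03, 0.01), self._e(0.03, 0.01)])
        assert pooled.beta == pytest.approx(0.03)
        assert pooled.se == pytest.approx(0.01 / np.sqrt(2))

    def test_precise_study_dominates(self):
        pooled = fixed_effect_meta([self._e(0.10, 1e-6), self._e(-0.5, 0.5)])
        assert pooled.beta == pytest.approx(0.10, abs=1e-5)

    def test_scalar_oracle(self):
        pooled = fixed_effect_meta([self._e(0.02, 0.01), self._e(0.04, 0.02)])
        b, se = meta_oracle([0.02, 0.04], [0.01, 0.02])
        assert pooled.beta == pytest.approx(b, abs=1e-14)
        assert pooled.se == pytest.approx(se, abs=1e-14)

    def test_mismatched_methods_error(self):
        with pytest.raises(MrpipeError):
            fixed_effect_meta([self._e(0.02, 0.01),
                               self._e(0.04, 0.02, method="egger")])

    def test_mismatched_outcomes_error(self):
        with pytest.raises(MrpipeError):
            fixed_effect_meta([self._e(0.02, 0.01, outcome="a"),
                               self._e(0.04, 0.02, outcome="b")])


class TestScaleEquivariance:
    """Multiplying outcome effects and SEs by c scales every estimator's
    beta and se by c."""

    @pytest.mark.parametrize("c", [2.0, 0.5])
    def test_ivw_egger_median_mode_raps(self, twelve_snp_set, c):
        h, hs = twelve_snp_set, _scaled(twelve_snp_set, c)
        f, fs = radial_ivw(h), radial_ivw(hs)
        assert fs.theta_hat == pytest.approx(c * f.theta_hat, rel=1e-9)
        assert fs.se == pytest.approx(c * f.se, rel=1e-9)
        e, es = radial_egger(h), radial_egger(hs)
        assert es.slope == pytest.approx(c * e.slope, rel=1e-9)
        assert es.se_slope == pytest.approx(c * e.se_slope, rel=1e-9)
        m, ms = (weighted_median(x, n_boot=200, seed=5) for x in (h, hs))
        assert ms.beta == pytest.approx(c * m.beta, rel=1e-9)
        r, rs = (mr_raps(x, overdispersion=False, loss="plain") for x in (h, hs))
        assert rs.beta == pytest.approx(c * r.beta, rel=1e-6)
        assert rs.se == pytest.approx(c * r.se, rel=1e-4)
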