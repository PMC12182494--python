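"""MR estimators against closed-form and independent library oracles."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from tsmr import (
    EstimationError,
    HarmonizedPair,
    WaldRatio,
    Z95,
    ivw,
    mr_egger,
    wald_ratios,
    weighted_median,
    weighted_mode,
)


def _pair(snp, bx, sx, by, sy, status="aligned"):
    return HarmonizedPair(
        snp_id=snp, beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy, status=status
    )


def _ratio(snp, b, se):
    from scipy.stats import norm

    return WaldRatio(snp_id=snp, b=b, se=se, p=2 * norm.sf(abs(b / se)))


class TestWaldRatios:
    def test_closed_form(self):
        (r,) = wald_ratios([_pair("rs1", 0.1, 0.02, 0.05, 0.02)])
        assert r.b == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)
        assert r.p == pytest.approx(0.01242, abs=1e-4)

    def test_null_outcome_effect(self):
        (r,) = wald_ratios([_pair("rs1", 0.1, 0.02, 0.0, 0.02)])
        assert r.b == 0.0 and r.p == 1.0

    def test_zero_exposure_effect_names_the_snp(self):
        with pytest.raises(EstimationError, match="rs_bad"):
            wald_ratios([_pair("rs_bad", 0.0, 0.02, 0.05, 0.02)])

    def test_dropped_pairs_excluded(self):
        pairs = [
            _pair("rs1", 0.1, 0.02, 0.05, 0.02),
            _pair("rs2", float("nan"), float("nan"), 0.1, 0.1, status="dropped"),
        ]
        assert [r.snp_id for r in wald_ratios(pairs)] == ["rs1"]

    def test_ratio_recovers_true_effect_with_tight_errors(self):
        rng = np.random.default_rng(7)
        theta, gamma = 0.4, 0.3
        sx, sy = 1e-4, 0.01
        bx = rng.normal(gamma, sx)
        by = rng.normal(theta * gamma, sy)
        (r,) = wald_ratios([_pair("rs1", bx, sx, by, sy)])
        assert abs(r.b - theta) < 3 * r.se


class TestIVW:
    def test_matches_wls_through_origin_oracle(self):
        """IVW of Wald ratios == weighted least squares of b on 1 (no intercept)."""
        rng = np.random.default_rng(1)
        b = rng.normal(0.2, 0.3, 4)
        se = rng.uniform(0.05, 0.4, 4)
        ratios = [_ratio(f"rs{i}", b[i], se[i]) for i in range(4)]
        res = ivw(ratios, mode="fixed")
        oracle = sm.WLS(b, np.ones(4), weights=1.0 / se**2).fit()
        assert res.b == pytest.approx(oracle.params[0], abs=1e-12)
        # fixed-effect SE is the WLS SE without the residual-variance factor
        assert res.se == pytest.approx(float(np.sum(se**-2.0)) ** -0.5, abs=1e-12)

    def test_single_ratio_identity(self):
        res = ivw([_ratio("rs1", 0.5, 0.2)])
        assert res.b == pytest.approx(0.5) and res.se == pytest.approx(0.2)
        assert res.nsnp == 1

    def test_empty_input_errors(self):
        with pytest.raises(EstimationError):
            ivw([])

    def test_estimate_is_convex_combination(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = rng.integers(2, 8)
            ratios = [
                _ratio(f"rs{i}", rng.normal(0, 1), rng.uniform(0.05, 1))
                for i in range(k)
            ]
            res = ivw(ratios)
            bs = [r.b for r in ratios]
            assert min(bs) - 1e-12 <= res.b <= max(bs) + 1e-12

    def test_random_mode_reduces_to_fixed_under_homogeneity(self):
        ratios = [_ratio("rs1", 0.3, 0.1), _ratio("rs2", 0.3, 0.2),
                  _ratio("rs3", 0.3, 0.15)]
        assert ivw(ratios, mode="random").se == ivw(ratios, mode="fixed").se

    def test_random_mode_inflates_se_under_heterogeneity(self):
        ratios = [_ratio("rs1", -2.0, 0.1), _ratio("rs2", 2.0, 0.1),
                  _ratio("rs3", 0.0, 0.1)]
        assert ivw(ratios, mode="random").se > ivw(ratios, mode="fixed").se

    def test_ci_exp_transform_consistency(self):
        res = ivw([_ratio("rs1", 0.4, 0.1), _ratio("rs2", 0.1, 0.3)])
        assert res.or_ == pytest.approx(math.exp(res.b), rel=1e-15)
        assert math.log(res.or_uci95) - math.log(res.or_lci95) == pytest.approx(
            2 * Z95 * res.se, rel=1e-12
        )


class TestMREgger:
    def test_exact_collinear_fit(self):
        pairs = [
            _pair(f"rs{i}", bx, 0.01, 0.4 * bx, 0.05)
            for i, bx in enumerate([0.05, 0.1, 0.15, 0.2, 0.25])
        ]
        res = mr_egger(pairs)
        assert res.b == pytest.approx(0.4, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.1 + 0.5 * bx + rng.normal(0, 0.05, 8)
        sy = rng.uniform(0.05, 0.2, 8)
        pairs = [_pair(f"rs{i}", bx[i], 0.01, by[i], sy[i]) for i in range(8)]
        res = mr_egger(pairs)
        X = sm.add_constant(bx)
        oracle = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        assert res.b == pytest.approx(oracle.params[1], abs=1e-10)
        assert res.egger_intercept == pytest.approx(oracle.params[0], abs=1e-10)
        # dispersion here exceeds 1, so SEs and t p-values agree with WLS
        if oracle.scale >= 1:
            assert res.se == pytest.approx(oracle.bse[1], abs=1e-10)
            assert res.p == pytest.approx(oracle.pvalues[1], abs=1e-10)

    def test_orientation_invariance(self):
        """Flipping which allele is 'effect' for any SNP leaves Egger unchanged."""
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.05, 0.3, 6)
        by = 0.05 + 0.3 * bx + rng.normal(0, 0.03, 6)
        sy = rng.uniform(0.05, 0.2, 6)
        pairs = [_pair(f"rs{i}", bx[i], 0.01, by[i], sy[i]) for i in range(6)]
        flipped = [
            _pair(p.snp_id, -p.beta_exp, p.se_exp, -p.beta_out, p.se_out)
            if i % 2
            else p
            for i, p in enumerate(pairs)
        ]
        a, b = mr_egger(pairs), mr_egger(flipped)
        assert a.b == pytest.approx(b.b, abs=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, abs=1e-12)

    def test_three_pairs_minimal_case_finite(self):
        pairs = [
            _pair("rs1", 0.1, 0.01, 0.06, 0.05),
            _pair("rs2", 0.2, 0.01, 0.09, 0.05),
            _pair("rs3", 0.3, 0.01, 0.14, 0.05),
        ]
        res = mr_egger(pairs)
        assert np.isfinite(res.se) and np.isfinite(res.egger_intercept_se)

    def test_fewer_than_three_errors(self):
        with pytest.raises(EstimationError):
            mr_egger([_pair("rs1", 0.1, 0.01, 0.05, 0.05),
                      _pair("rs2", 0.2, 0.01, 0.1, 0.05)])


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        ratios = [_ratio("rs1", 1.0, 0.5), _ratio("rs2", 2.0, 0.5),
                  _ratio("rs3", 3.0, 0.5)]
        res = weighted_median(ratios, n_boot=200, seed=1)
        assert res.b == pytest.approx(2.0)

    def test_seeded_bootstrap_is_deterministic(self):
        ratios = [_ratio(f"rs{i}", b, 0.3) for i, b in enumerate([0.1, 0.4, 0.9, 1.2])]
        a = weighted_median(ratios, n_boot=300, seed=42)
        b = weighted_median(ratios, n_boot=300, seed=42)
        assert a.se == b.se and a.p == b.p

    def test_majority_valid_weight_wins(self):
        """60% of weight tightly at 0.3, 40% at 1.5 -> estimate near 0.3."""
        valid = [_ratio(f"v{i}", 0.3 + 0.01 * (i - 1), 0.1) for i in range(3)]
        w_valid = sum(1 / 0.1**2 for _ in valid)  # 300
        # two invalid SNPs carrying 40% of total weight: W_i = W_v * 0.4/0.6
        se_inv = math.sqrt(2.0 * 0.6 / (0.4 * w_valid))
        invalid = [_ratio(f"i{i}", 1.5, se_inv) for i in range(2)]
        res = weighted_median(valid + invalid, n_boot=500, seed=0)
        assert abs(res.b - 0.3) < 3 * res.se
        assert abs(res.b - 0.3) < abs(ivw(valid + invalid, mode="fixed").b - 0.3)

    def test_too_few_boot_or_ratios_error(self):
        ratios = [_ratio(f"rs{i}", 0.1 * i, 0.2) for i in range(3)]
        with pytest.raises(EstimationError):
            weighted_median(ratios, n_boot=50, seed=0)
        with pytest.raises(EstimationError):
            weighted_median(ratios[:2], n_boot=200, seed=0)


class TestWeightedMode:
    def test_degenerate_identical_ratios(self):
        ratios = [_ratio(f"rs{i}", 0.7, 0.2) for i in range(4)]
        res = weighted_mode(ratios, n_boot=200, seed=0)
        assert res.b == pytest.approx(0.7)
        assert res.se > 0  # bootstrap still produces spread

    def test_bimodal_density_prefers_heavier_cluster(self):
        """70% of weight near 0.3, 30% near 1.5 -> mode lands in the 0.3 cluster."""
        from tsmr.estimators import _weighted_mode_bandwidth

        heavy = [_ratio(f"h{i}", 0.3 + 0.02 * i, 0.1) for i in range(4)]
        w_heavy = 4 / 0.1**2
        se_light = math.sqrt(2.0 * 0.7 / (0.3 * w_heavy))
        light = [_ratio(f"l{i}", 1.5 + 0.02 * i, se_light) for i in range(2)]
        ratios = heavy + light
        res = weighted_mode(ratios, n_boot=200, seed=0)
        b = np.array([r.b for r in ratios])
        w = np.array([1 / r.se**2 for r in ratios])
        h = _weighted_mode_bandwidth(b, w, 1.0)
        assert abs(res.b - 0.3) < max(h, 0.1)

    def test_mode_matches_brute_force_grid_oracle(self):
        """Kernel-density maximizer agrees with a dense brute-force grid."""
        rng = np.random.default_rng(5)
        b = rng.normal(0.4, 0.3, 7)
        se = rng.uniform(0.1, 0.5, 7)
        ratios = [_ratio(f"rs{i}", b[i], se[i]) for i in range(7)]
        res = weighted_mode(ratios, n_boot=200, seed=0)
        from tsmr.estimators import _weighted_mode_bandwidth

        w = 1.0 / se**2
        h = _weighted_mode_bandwidth(b, w, 1.0)
        grid = np.linspace(b.min() - 3 * h, b.max() + 3 * h, 200_001)
        dens = np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2) @ w
        assert res.b == pytest.approx(grid[np.argmax(dens)], abs=1e-4)

    def test_seeded_bootstrap_is_deterministic(self):
        ratios = [_ratio(f"rs{i}", b, 0.3) for i, b in enumerate([0.1, 0.4, 0.9])]
        a = weighted_mode(ratios, n_boot=200, seed=9)
        b = weighted_mode(ratios, n_boot=200, seed=9)
        assert a.se == b.se
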