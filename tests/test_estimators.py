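import math
import subprocess

import numpy as np
import pytest
from scipy import stats

from tsmr.estimators import (
    EstimatorConfig,
    _weighted_median_point,
    egger,
    ivw,
    mode_estimate,
    run_all_methods,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
)
from tsmr.harmonize import HarmonizedDataset


def hd(gamma, Gamma, se_Gamma, se_gamma=None):
    gamma = np.asarray(gamma, float)
    if se_gamma is None:
        se_gamma = np.full_like(gamma, 0.01)
    return HarmonizedDataset.from_arrays(gamma, se_gamma, Gamma, se_Gamma)


class TestWaldRatios:
    def test_direct_arithmetic(self):
        r = wald_ratios(hd([0.1], [0.05], [0.01]))
        assert r.b[0] == pytest.approx(0.5)
        assert r.s[0] == pytest.approx(0.1)

    def test_zero_outcome_effect_gives_zero_ratio(self):
        assert wald_ratios(hd([0.1], [0.0], [0.01])).b[0] == 0.0

    def test_zero_exposure_effect_is_hard_error(self):
        with pytest.raises(ValueError, match="snp2"):
            wald_ratios(hd([0.1, 0.0], [0.05, 0.05], [0.01, 0.01]))

    def test_elementwise_against_reference(self, rng):
        gamma = rng.normal(0.05, 0.01, 10)
        Gamma = rng.normal(0.02, 0.01, 10)
        se = rng.uniform(0.005, 0.02, 10)
        r = wald_ratios(hd(gamma, Gamma, se))
        np.testing.assert_allclose(r.b, Gamma / gamma)
        np.testing.assert_allclose(r.s, se / np.abs(gamma))
        np.testing.assert_allclose(r.w, np.abs(gamma) ** 2 / se**2)


class TestIvw:
    def test_two_identical_snps_give_common_ratio(self):
        est = ivw(hd([0.1, 0.1], [0.05, 0.05], [0.01, 0.01]))
        assert est.beta == pytest.approx(0.5)

    def test_homogeneous_case_uses_fixed_effect_se(self):
        data = hd([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], [0.01, 0.01, 0.01])
        est = ivw(data)
        assert est.beta == pytest.approx(0.5)
        assert est.extras["sigma"] <= 1.0
        # exact fit ⇒ SE equals the fixed-effect closed form
        w = 1 / 0.01**2
        expected_se = (w * (0.1**2 + 0.2**2 + 0.4**2)) ** -0.5
        assert est.se == pytest.approx(expected_se)

    def test_single_snp_rejected(self):
        with pytest.raises(ValueError):
            ivw(hd([0.1], [0.05], [0.01]))

    def test_permutation_and_scale_invariance(self, rng):
        gamma = rng.normal(0.05, 0.02, 20)
        Gamma = 0.5 * gamma + rng.normal(0, 0.01, 20)
        se = rng.uniform(0.005, 0.02, 20)
        base = ivw(hd(gamma, Gamma, se))
        perm = rng.permutation(20)
        assert ivw(hd(gamma[perm], Gamma[perm], se[perm])).beta == pytest.approx(base.beta)
        # consistent rescaling of the outcome scale multiplies beta by c
        c = 3.7
        scaled = ivw(hd(gamma, c * Gamma, c * se))
        assert scaled.beta == pytest.approx(c * base.beta)
        assert scaled.se == pytest.approx(c * base.se)

    def test_matches_metafor_fixed_effect(self, tmp_path):
        """Independent route: R metafor's fixed-effect meta-analysis of the
        Wald ratios equals fixed-effect IVW."""
        rng = np.random.default_rng(77)
        gamma = rng.normal(0.05, 0.02, 8)
        gamma[np.abs(gamma) < 0.01] = 0.02
        Gamma = 0.4 * gamma + rng.normal(0, 0.005, 8)
        se = rng.uniform(0.005, 0.02, 8)
        est = ivw(hd(gamma, Gamma, se), random_effects=False)
        r = wald_ratios(hd(gamma, Gamma, se))
        yi = ",".join(repr(float(v)) for v in r.b)
        vi = ",".join(repr(float(v)) for v in r.s**2)
        script = tmp_path / "fe.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"fit <- rma(yi=c({yi}), vi=c({vi}), method='FE')\n"
            "cat(sprintf('%.12f %.12f', fit$beta, fit$se))\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        beta_r, se_r = map(float, out.stdout.split())
        assert est.beta == pytest.approx(beta_r, rel=1e-8)
        assert est.se == pytest.approx(se_r, rel=1e-8)


class TestEgger:
    def test_exact_proportional_fit(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.5])
        est = egger(hd(gamma, 0.5 * gamma, np.full(4, 0.01)))
        assert est.beta == pytest.approx(0.5)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_fit_with_intercept(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.5])
        est = egger(hd(gamma, 0.02 + 0.5 * gamma, np.full(4, 0.01)))
        assert est.beta == pytest.approx(0.5)
        assert est.extras["intercept"] == pytest.approx(0.02)

    def test_orientation_makes_fit_sign_invariant(self):
        gamma = np.array([0.1, -0.2, 0.3, -0.5])
        Gamma = 0.02 * np.sign(gamma) + 0.5 * gamma
        est = egger(hd(gamma, Gamma, np.full(4, 0.01)))
        assert est.beta == pytest.approx(0.5)
        assert est.extras["intercept"] == pytest.approx(0.02)

    def test_needs_three_snps(self):
        with pytest.raises(ValueError):
            egger(hd([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))

    def test_zero_intercept_forced_equals_ivw(self, rng):
        """Internal consistency: with the intercept constrained to zero the
        weighted regression is exactly IVW (checked via the normal equations)."""
        gamma = np.abs(rng.normal(0.05, 0.02, 15)) + 0.01
        Gamma = 0.3 * gamma + rng.normal(0, 0.01, 15)
        se = rng.uniform(0.005, 0.02, 15)
        w = 1 / se**2
        slope_through_origin = np.sum(w * gamma * Gamma) / np.sum(w * gamma**2)
        assert ivw(hd(gamma, Gamma, se)).beta == pytest.approx(slope_through_origin)


class TestWeightedMedian:
    def test_equal_weight_median(self):
        data = hd([0.1, 0.1, 0.1], [0.1, 0.2, 0.3], [0.01, 0.01, 0.01])
        est = weighted_median(data, n_boot=50, seed=1)
        assert est.beta == pytest.approx(2.0)

    def test_dominant_snp_with_symmetric_weights(self):
        # dominant middle ratio with mid-cumulative weight exactly at 0.5
        b = np.array([1.0, 2.0, 3.0])
        w = np.array([0.2, 0.6, 0.2])
        assert _weighted_median_point(b, w) == pytest.approx(2.0)

    def test_interpolation_matches_brute_force(self, rng):
        b = rng.normal(0.5, 0.3, 5)
        w = rng.uniform(0.5, 2.0, 5)
        order = np.argsort(b)
        bs, ws = b[order], w[order] / w.sum()
        p = np.cumsum(ws) - ws / 2
        k = int(np.searchsorted(p, 0.5))
        expected = bs[k - 1] + (bs[k] - bs[k - 1]) * (0.5 - p[k - 1]) / (p[k] - p[k - 1])
        assert _weighted_median_point(b, w) == pytest.approx(expected)

    def test_bootstrap_se_deterministic_under_seed(self):
        data = hd(
            np.full(5, 0.1), [0.04, 0.05, 0.06, 0.05, 0.07], np.full(5, 0.01)
        )
        a = weighted_median(data, n_boot=200, seed=9)
        b = weighted_median(data, n_boot=200, seed=9)
        assert a.se == b.se


class TestMode:
    def test_degenerate_cluster_returns_common_ratio(self):
        data = hd([0.1, 0.2, 0.4], [0.07, 0.14, 0.28], [0.01, 0.02, 0.04])
        est = mode_estimate(data, n_boot=10, seed=1)
        assert est.beta == pytest.approx(0.7) and est.se == 0.0

    def test_mode_resists_outliers(self):
        gamma = np.full(7, 0.1)
        ratios = np.array([0.48, 0.5, 0.5, 0.52, 0.5, 3.0, 3.1])
        data = hd(gamma, ratios * gamma, np.full(7, 0.01))
        est = mode_estimate(data, weighted=False, n_boot=10, seed=1, grid_points=2000)
        assert abs(est.beta - 0.5) < 0.1
        assert abs(est.beta - np.mean(ratios)) > 0.3

    def test_argmax_agrees_with_finer_grid(self, rng):
        gamma = np.abs(rng.normal(0.1, 0.02, 20)) + 0.02
        Gamma = 0.5 * gamma + rng.normal(0, 0.01, 20)
        se = rng.uniform(0.005, 0.02, 20)
        data = hd(gamma, Gamma, se)
        coarse = mode_estimate(data, n_boot=2, seed=1, grid_points=10_000)
        fine = mode_estimate(data, n_boot=2, seed=1, grid_points=100_000)
        # grid-refinement: the argmax moves by less than one coarse cell
        r = wald_ratios(data)
        h = coarse.extras["bandwidth"]
        cell = (r.b.max() - r.b.min() + 4 * h) / 10_000
        assert abs(coarse.beta - fine.beta) <= cell

    def test_weighted_and_simple_differ_under_unequal_weights(self):
        gamma = np.full(6, 0.1)
        ratios = np.array([0.2, 0.22, 0.24, 0.8, 0.82, 0.84])
        se = np.array([0.05, 0.05, 0.05, 0.004, 0.004, 0.004])
        data = hd(gamma, ratios * gamma, se)
        wm = mode_estimate(data, weighted=True, n_boot=5, seed=2, grid_points=4000)
        sm = mode_estimate(data, weighted=False, n_boot=5, seed=2, grid_points=4000)
        assert wm.beta == pytest.approx(0.82, abs=0.05)
        assert 0.1 < sm.beta < 0.9


class TestOddsRatio:
    def test_table_values(self):
        or_, lo, hi = to_odds_ratio(0.551, 0.177)
        assert or_ == pytest.approx(1.735, abs=0.002)
        assert lo == pytest.approx(1.226, abs=0.002)

    def test_null_beta_symmetric_about_one(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.2)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_huge_se_saturates_instead_of_overflowing(self):
        or_, lo, hi = to_odds_ratio(0.5, 1e5)
        assert lo == 0.0 and hi == math.inf


class TestRunAll:
    def test_five_methods_in_order_with_counts(self):
        rng = np.random.default_rng(4)
        gamma = np.abs(rng.normal(0.05, 0.01, 12)) + 0.01
        Gamma = 0.5 * gamma + rng.normal(0, 0.005, 12)
        data = hd(gamma, Gamma, np.full(12, 0.01))
        ests = run_all_methods(data, EstimatorConfig(n_boot=50, grid_points=1000, seed=5))
        assert [e.method for e in ests] == [
            "IVW", "MR-Egger", "Weighted median", "Weighted mode", "Simple mode"
        ]
        assert all(e.n_snp == 12 for e in ests)
        assert all(e.or_ == pytest.approx(math.exp(e.beta)) for e in ests)

    def test_identical_ratios_make_all_methods_agree(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.4])
        data = hd(gamma, 0.7 * gamma, np.full(4, 0.01))
        ests = run_all_methods(data, EstimatorConfig(n_boot=20, grid_points=500, seed=1))
        for e in ests:
            assert e.beta == pytest.approx(0.7, abs=1e-6)

    def test_rerun_with_same_seed_is_identical(self):
        rng = np.random.default_rng(8)
        gamma = np.abs(rng.normal(0.05, 0.01, 10)) + 0.01
        Gamma = 0.5 * gamma + rng.normal(0, 0.01, 10)
        data = hd(gamma, Gamma, np.full(10, 0.01))
        cfg = EstimatorConfig(n_boot=100, grid_points=1000, seed=13)
        a = run_all_methods(data, cfg)
        b = run_all_methods(data, cfg)
        assert [(e.beta, e.se, e.pvalue) for e in a] == [(e.beta, e.se, e.pvalue) for e in b]
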