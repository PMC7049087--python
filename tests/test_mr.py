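"""MR estimators: Wald ratios, IVW, Egger, bootstrap, scaling, Bonferroni."""

import numpy as np
import pytest
import statsmodels.api as sm

from lpamr.instruments import HarmonizedSNP
from lpamr.mr import (bonferroni_gate, bootstrap_pvalue, egger_estimate,
                      ivw_estimate, scale_per_50, wald_ratio, wald_ratios)

from conftest import make_stat_set, stat_set_from_arrays


def _snp(beta_exp, se_exp, beta_out, se_out, rsid="rs1"):
    return HarmonizedSNP(rsid, "A", "G", 0.3, beta_exp, se_exp, beta_out, se_out)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        w = wald_ratio(_snp(10.0, 0.5, 0.05, 0.01))
        assert w.theta == pytest.approx(0.005)
        assert w.se_theta == pytest.approx(0.001)

    def test_zero_outcome_effect(self):
        assert wald_ratio(_snp(7.0, 0.5, 0.0, 0.01)).theta == 0.0

    def test_zero_exposure_effect_excluded_not_error(self):
        assert wald_ratio(_snp(0.0, 0.5, 0.05, 0.01)) is None

    def test_first_order_se_close_to_second_order_oracle(self):
        """Independent Taylor-expansion SE oracle: the full second-order
        delta-method SE of beta_out/beta_exp adds the exposure-noise term
        beta_out^2 se_exp^2 / beta_exp^4.  For strong instruments
        (|beta_exp|/se_exp > 10) at the effect scales the generator produces,
        the first-order SE agrees within 5%."""
        rng = np.random.default_rng(42)
        n = 1000
        bx = rng.uniform(1.0, 16.0, n)
        maf = rng.uniform(0.05, 0.45, n)
        geno_sd = np.sqrt(2 * maf * (1 - maf))
        sx = 30.0 / (geno_sd * np.sqrt(20_000.0))
        so = 1.0 / (geno_sd * np.sqrt(139_362.0))
        by = -0.002 * bx                         # Taylor expansion at the truth
        strong = bx / sx > 10
        assert strong.mean() > 0.5
        first = (so / np.abs(bx))[strong]
        second = np.sqrt(so**2 / bx**2 + by**2 * sx**2 / bx**4)[strong]
        assert np.all(second / first < 1.05)


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        s = stat_set_from_arrays([8.0], [0.4], [0.03], [0.01])
        est = ivw_estimate(s)
        w = wald_ratios(s)[0]
        assert est.slope == pytest.approx(w.theta, rel=1e-15)
        assert est.slope_sd == pytest.approx(w.se_theta, rel=1e-15)

    def test_equal_weights_average(self):
        # equal se_theta: se_out/|beta_exp| identical across both SNPs
        s = stat_set_from_arrays([10.0, 10.0], [0.5, 0.5],
                                 [0.05, 0.01], [0.01, 0.01])
        est = ivw_estimate(s)
        assert est.slope == pytest.approx((0.005 + 0.001) / 2, rel=1e-12)

    def test_equivalence_with_weighted_regression_through_origin(self):
        """Independent route: statsmodels WLS of beta_out on beta_exp without
        intercept, weights 1/se_out^2, reproduces IVW to 1e-12 relative."""
        for seed in (0, 1, 2):
            s = make_stat_set(seed=seed, n_snps=30)
            est = ivw_estimate(s)
            df = s.snps
            fit = sm.WLS(df["beta_out"], df[["beta_exp"]],
                         weights=1.0 / df["se_out"]**2).fit()
            assert est.slope == pytest.approx(fit.params.iloc[0], rel=1e-12)

    def test_order_and_joint_sign_flip_invariance(self, default_stat_set):
        base = ivw_estimate(default_stat_set).slope
        df = default_stat_set.snps.sample(frac=1.0, random_state=0)
        permuted = stat_set_from_arrays(df["beta_exp"], df["se_exp"],
                                        df["beta_out"], df["se_out"])
        assert ivw_estimate(permuted).slope == pytest.approx(base, rel=1e-12)
        flipped = stat_set_from_arrays(-df["beta_exp"], df["se_exp"],
                                       -df["beta_out"], df["se_out"])
        assert ivw_estimate(flipped).slope == pytest.approx(base, rel=1e-12)

    def test_leave_one_out_bound(self, default_stat_set):
        """Deleting the largest-weight SNP moves the slope by no more than the
        exhaustive leave-one-out oracle's maximum deviation."""
        df = default_stat_set.snps
        full = ivw_estimate(default_stat_set).slope
        deltas = {}
        for i in range(len(df)):
            sub = df.drop(df.index[i])
            s = stat_set_from_arrays(sub["beta_exp"], sub["se_exp"],
                                     sub["beta_out"], sub["se_out"])
            deltas[i] = abs(ivw_estimate(s).slope - full)
        weights = (df["beta_exp"] / df["se_out"])**2
        heaviest = int(np.argmax(weights.to_numpy()))
        assert deltas[heaviest] <= max(deltas.values()) + 1e-18

    def test_empty_set_fails(self):
        s = stat_set_from_arrays([0.0, 0.0], [0.5, 0.5], [0.01, 0.02], [0.01, 0.01])
        with pytest.raises(ValueError, match="at least one SNP"):
            ivw_estimate(s)


class TestEgger:
    def test_constrained_intercept_reduces_to_ivw(self, default_stat_set):
        ivw = ivw_estimate(default_stat_set)
        nested = egger_estimate(default_stat_set, _constrain_intercept=True)
        assert nested.slope == pytest.approx(ivw.slope, rel=1e-12)
        assert nested.slope_sd == pytest.approx(ivw.slope_sd, rel=1e-12)

    def test_matches_weighted_least_squares_oracle(self):
        """statsmodels WLS with intercept reproduces slope and intercept
        exactly, and the known-variance SEs after removing the estimated
        dispersion factor."""
        for seed in (3, 4):
            s = make_stat_set(seed=seed, pleiotropy_mean=0.002, pleiotropy_sd=0.003)
            est = egger_estimate(s)
            df = s.snps
            X = sm.add_constant(df["beta_exp"])
            fit = sm.WLS(df["beta_out"], X, weights=1.0 / df["se_out"]**2).fit()
            assert est.slope == pytest.approx(fit.params["beta_exp"], rel=1e-10)
            assert est.intercept == pytest.approx(fit.params["const"], rel=1e-10)
            scale = np.sqrt(fit.scale)
            assert est.slope_sd == pytest.approx(fit.bse["beta_exp"] / scale, rel=1e-10)
            assert est.intercept_sd == pytest.approx(fit.bse["const"] / scale, rel=1e-10)

    def test_requires_three_snps_and_orientation(self):
        s2 = stat_set_from_arrays([8.0, 9.0], [0.4, 0.4], [0.03, 0.02], [0.01, 0.01])
        with pytest.raises(ValueError, match="3 SNPs"):
            egger_estimate(s2)
        s_bad = stat_set_from_arrays([8.0, -9.0, 10.0], [0.4] * 3,
                                     [0.03, 0.02, 0.01], [0.01] * 3)
        with pytest.raises(ValueError, match="orientation"):
            egger_estimate(s_bad)

    def test_recovers_slope_under_directional_pleiotropy(self):
        """With constant directional pleiotropy the Egger intercept absorbs
        the bias and the slope stays unbiased, while IVW is pulled away."""
        true = -0.002
        egger_slopes, ivw_slopes = [], []
        for seed in range(60):
            s = make_stat_set(seed=seed, causal_slope=true,
                              pleiotropy_mean=0.01, pleiotropy_sd=0.0)
            egger_slopes.append(egger_estimate(s).slope)
            ivw_slopes.append(ivw_estimate(s).slope)
        mc_se = np.std(egger_slopes, ddof=1) / np.sqrt(len(egger_slopes))
        assert abs(np.mean(egger_slopes) - true) < 3 * mc_se
        assert abs(np.mean(ivw_slopes) - true) > 10 * mc_se


class TestBootstrap:
    def test_determinism(self, default_stat_set):
        a = bootstrap_pvalue(default_stat_set, "IVW", n_reps=2000, seed=5)
        b = bootstrap_pvalue(default_stat_set, "IVW", n_reps=2000, seed=5)
        assert a == b

    def test_too_few_reps_rejected(self, default_stat_set):
        with pytest.raises(ValueError, match="unstable"):
            bootstrap_pvalue(default_stat_set, "IVW", n_reps=50)

    def test_agrees_with_analytic_p_when_exposure_noise_vanishes(self):
        """se_exp -> 0: the bootstrap SD converges to the analytic IVW SD, so
        the two p-values agree; checked at a moderate (non-degenerate) z."""
        rng = np.random.default_rng(7)
        n = 26
        bx = rng.uniform(1.0, 16.0, n)
        so = rng.uniform(0.003, 0.008, n)
        by = rng.normal(-0.00015 * bx, so)
        s = stat_set_from_arrays(bx, np.full(n, 1e-10), by, so)
        est = ivw_estimate(s)
        assert 0.001 < est.slope_p < 0.9   # informative regime
        p_boot = bootstrap_pvalue(s, "IVW", n_reps=20_000, seed=1)
        assert abs(p_boot - est.slope_p) < 0.01

    def test_egger_bootstrap_runs(self, default_stat_set):
        p = bootstrap_pvalue(default_stat_set, "Egger", n_reps=1000, seed=2)
        assert 0.0 <= p <= 1.0


class TestScaling:
    def test_zero_slope_unit_or_symmetric_ci(self):
        from lpamr.mr import MREstimate
        est = MREstimate("IVW", 0.0, 0.001, 1.0, 10)
        sc = scale_per_50(est)
        assert sc.odds_ratio_per_50 == 1.0
        assert sc.ci_low * sc.ci_high == pytest.approx(1.0, rel=1e-12)

    def test_closed_form_doubling(self):
        from lpamr.mr import MREstimate
        est = MREstimate("IVW", np.log(2) / 50, 0.0001, 1e-6, 10)
        assert scale_per_50(est).odds_ratio_per_50 == pytest.approx(2.0, rel=1e-12)

    def test_published_or_092_ci(self):
        """Slope -0.001668 (SD 0.000283) maps to OR 0.92 with a CI near
        (0.89, 0.94); the bounds carry the rounding of the printed values."""
        from lpamr.mr import MREstimate
        est = MREstimate("IVW", -0.001668, 0.000283, 1e-8, 26)
        sc = scale_per_50(est)
        assert round(sc.odds_ratio_per_50, 2) == 0.92
        assert abs(sc.ci_low - 0.89) <= 0.011
        assert abs(sc.ci_high - 0.94) <= 0.011


class TestBonferroni:
    def test_six_outcome_threshold(self):
        flags, thr = bonferroni_gate([0.008, 0.009], n_outcomes=6)
        assert flags == [True, False]
        assert round(thr, 4) == 0.0083

    def test_boundary_is_strict(self):
        flags, _ = bonferroni_gate([0.05], n_outcomes=1)
        assert flags == [False]

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bonferroni_gate([0.0])
        with pytest.raises(ValueError):
            bonferroni_gate([1.1])
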