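import numpy as np
import pytest
from scipy import stats

from trimr import (SimConfig, cochran_q, harmonize, ivw, ivw_both, mr_egger,
                   simulate_pair, wald_ratio, wald_ratios, weighted_median)
from trimr.instruments import HarmonizedSet


def _hs(beta_exp, se_exp, beta_out, se_out):
    k = len(beta_exp)
    return HarmonizedSet(
        snp_ids=np.array([f"rs{i}" for i in range(k)], dtype=object),
        beta_exp=np.asarray(beta_exp, float), se_exp=np.asarray(se_exp, float),
        beta_out=np.asarray(beta_out, float), se_out=np.asarray(se_out, float),
        eaf_exp=np.full(k, 0.3),
    )


def _hs_from_ratios(ratios, ratio_ses):
    """Instrument set whose Wald ratios and SEs are exactly as given (beta_exp=1)."""
    k = len(ratios)
    ones = np.ones(k)
    return _hs(ones, 0.01 * ones, np.asarray(ratios, float), np.asarray(ratio_ses, float))


class TestWaldRatio:
    def test_zero_outcome_effect(self):
        assert wald_ratio(0.5, 0.01, 0.0, 0.05) == (0.0, 0.1)

    def test_arithmetic_oracle(self):
        ratio, se = wald_ratio(0.5, 0.01, 0.1, 0.05)
        assert ratio == pytest.approx(0.2)
        assert se == pytest.approx(0.1)

    def test_sign_symmetry(self):
        r1, s1 = wald_ratio(0.5, 0.01, 0.1, 0.05)
        r2, s2 = wald_ratio(-0.5, 0.01, 0.1, 0.05)
        assert r2 == -r1 and s2 == s1

    def test_zero_exposure_beta_is_hard_error(self):
        with pytest.raises(ValueError, match="undefined ratio"):
            wald_ratio(0.0, 0.01, 0.1, 0.05)

    def test_second_order_se_larger(self):
        _, s1 = wald_ratio(0.5, 0.1, 0.2, 0.05)
        _, s2 = wald_ratio(0.5, 0.1, 0.2, 0.05, second_order=True)
        assert s2 > s1


class TestIVW:
    def test_closed_form_oracle(self):
        # weights 100, 100, 25 -> beta = (20+40+15)/225, se = 1/sqrt(225)
        hs = _hs_from_ratios([0.2, 0.4, 0.6], [0.1, 0.1, 0.2])
        est, het = ivw(hs, model="fixed")
        assert est.beta == pytest.approx(75 / 225, abs=1e-12)
        assert est.se == pytest.approx(1 / 15, abs=1e-12)

    def test_single_snp_reduces_to_wald(self):
        hs = _hs([0.5], [0.01], [0.1], [0.05])
        est, het = ivw(hs)
        assert est.beta == pytest.approx(0.2)
        assert est.method == "wald"
        assert het is None

    def test_identical_ratios_have_zero_q(self):
        hs = _hs_from_ratios([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
        fixed, random_, het = ivw_both(hs)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert fixed.beta == random_.beta == pytest.approx(0.3)
        assert fixed.se == random_.se

    def test_empty_set_is_hard_error(self):
        hs = _hs([], [], [], [])
        with pytest.raises(ValueError):
            ivw(hs)

    @pytest.mark.parametrize("seed", range(20))
    def test_fixed_ivw_equals_wls_through_origin(self, seed, harmonized_factory):
        """Algebraic identity: IVW = weighted through-origin regression of
        outcome on exposure betas with weights 1/se_out^2."""
        hs = harmonized_factory(k=int(np.random.default_rng(seed).integers(3, 20)),
                                seed=seed)
        est, _ = ivw(hs, model="fixed")
        w = 1 / hs.se_out**2
        slope = np.sum(w * hs.beta_exp * hs.beta_out) / np.sum(w * hs.beta_exp**2)
        assert est.beta == pytest.approx(slope, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_se_at_least_fixed_se(self, seed, harmonized_factory):
        hs = harmonized_factory(k=12, seed=100 + seed)
        fixed, random_, het = ivw_both(hs)
        assert random_.se >= fixed.se
        if het.q <= het.df:
            assert random_.se == fixed.se

    def test_auto_model_follows_q_rule(self):
        # homogeneous ratios -> fixed; grossly heterogeneous -> random
        hs = _hs_from_ratios([0.3, 0.3, 0.3, 0.3], [0.1] * 4)
        assert ivw(hs, model="auto")[0].method == "ivw_fixed"
        hs = _hs_from_ratios([0.0, 1.0, -1.0, 2.0], [0.01] * 4)
        est, het = ivw(hs, model="auto")
        assert het.pval < 0.05
        assert est.method == "ivw_random"


class TestCochranQ:
    def test_identical_ratios(self):
        res = cochran_q(np.array([0.3, 0.3]), np.array([0.1, 0.1]), 0.3)
        assert res.q == 0.0 and res.pval == 1.0

    def test_two_snp_oracle(self):
        res = cochran_q(np.array([0.0, 1.0]), np.array([1.0, 1.0]), 0.5)
        assert res.q == pytest.approx(0.5)
        assert res.df == 1
        assert res.pval == pytest.approx(stats.chi2.sf(0.5, 1), abs=1e-10)
        assert res.pval == pytest.approx(0.4795, abs=1e-4)

    def test_three_snp_hand_arithmetic(self):
        res = cochran_q(np.array([-1.0, 0.0, 1.0]), np.ones(3), 0.0)
        assert res.q == pytest.approx(2.0)

    def test_single_snp_rejected(self):
        with pytest.raises(ValueError):
            cochran_q(np.array([0.3]), np.array([0.1]), 0.3)


class TestMREgger:
    def test_exact_line_recovered(self):
        x = np.array([0.5, 1.0, 1.5, 2.0])
        y = 0.1 + 1.0 * x
        hs = _hs(x, 0.01 * np.ones(4), y, np.ones(4))
        egger, est = mr_egger(hs)
        assert egger.intercept == pytest.approx(0.1, abs=1e-12)
        assert egger.slope == pytest.approx(1.0, abs=1e-12)

    def test_through_origin_case_matches_ivw(self):
        x = np.array([1.0, 2.0, 3.0])
        y = 2.0 * x
        hs = _hs(x, 0.01 * np.ones(3), y, np.ones(3))
        egger, _ = mr_egger(hs)
        assert egger.intercept == pytest.approx(0.0, abs=1e-12)
        assert egger.slope == pytest.approx(2.0, abs=1e-12)
        est, _ = ivw(hs, model="fixed")
        assert egger.slope == pytest.approx(est.beta, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_normal_equations_oracle(self, seed, harmonized_factory):
        hs = harmonized_factory(k=5 + seed % 10, seed=300 + seed)
        egger, _ = mr_egger(hs)
        sign = np.where(hs.beta_exp < 0, -1.0, 1.0)
        x, y, w = hs.beta_exp * sign, hs.beta_out * sign, 1 / hs.se_out**2
        X = np.column_stack([np.ones_like(x), x])
        XtWX = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(XtWX, X.T @ (w * y))
        assert egger.intercept == pytest.approx(coef[0], abs=1e-10)
        assert egger.slope == pytest.approx(coef[1], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_wls(self, seed, harmonized_factory):
        sm = pytest.importorskip("statsmodels.api")
        hs = harmonized_factory(k=12, seed=400 + seed)
        egger, _ = mr_egger(hs)
        sign = np.where(hs.beta_exp < 0, -1.0, 1.0)
        x, y, w = hs.beta_exp * sign, hs.beta_out * sign, 1 / hs.se_out**2
        fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        assert egger.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert egger.slope == pytest.approx(fit.params[1], abs=1e-10)
        assert egger.intercept_se == pytest.approx(fit.bse[0], rel=1e-8)
        assert egger.slope_se == pytest.approx(fit.bse[1], rel=1e-8)
        assert egger.slope_pval == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_orientation_invariance(self, harmonized_factory):
        hs = harmonized_factory(k=8, seed=7)
        flipped = HarmonizedSet(
            snp_ids=hs.snp_ids, beta_exp=-hs.beta_exp, se_exp=hs.se_exp,
            beta_out=-hs.beta_out, se_out=hs.se_out, eaf_exp=hs.eaf_exp)
        e1, _ = mr_egger(hs)
        e2, _ = mr_egger(flipped)
        assert e1.slope == pytest.approx(e2.slope)
        assert e1.intercept == pytest.approx(e2.intercept)

    def test_too_few_instruments(self):
        hs = _hs([0.1, 0.2], [0.01, 0.01], [0.1, 0.2], [0.05, 0.05])
        with pytest.raises(ValueError, match="insufficient instruments"):
            mr_egger(hs)


def _brute_weighted_median(ratios, weights):
    """Independent reimplementation of the cumulative-weight interpolation."""
    order = np.argsort(ratios)
    r = np.array(ratios)[order]
    w = np.array(weights)[order]
    total = w.sum()
    cum = 0.0
    p = []
    for wi in w:
        p.append((cum + wi / 2) / total)
        cum += wi
    p = np.array(p)
    for i in range(len(r) - 1):
        if p[i] <= 0.5 <= p[i + 1]:
            frac = (0.5 - p[i]) / (p[i + 1] - p[i])
            return r[i] + frac * (r[i + 1] - r[i])
    return r[0] if 0.5 < p[0] else r[-1]


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        hs = _hs_from_ratios([1.0, 2.0, 10.0], [1.0, 1.0, 1.0])
        est = weighted_median(hs, n_boot=200, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_constant_ratios(self):
        hs = _hs_from_ratios([0.7, 0.7, 0.7], [0.1, 0.2, 0.3])
        est = weighted_median(hs, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.7)
        assert est.se < 0.3

    def test_unequal_weights_match_brute_force(self):
        ratios = [1.0, 2.0, 3.0]
        ses = 1 / np.sqrt(np.array([2.0, 1.0, 1.0]))
        hs = _hs_from_ratios(ratios, ses)
        est = weighted_median(hs, n_boot=200, seed=0)
        assert est.beta == pytest.approx(_brute_weighted_median(ratios, [2, 1, 1]), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_match_brute_force(self, seed, harmonized_factory):
        hs = harmonized_factory(k=4 + seed, seed=500 + seed)
        ratios, ses = wald_ratios(hs)
        est = weighted_median(hs, n_boot=200, seed=seed)
        assert est.beta == pytest.approx(_brute_weighted_median(ratios, 1 / ses**2),
                                         abs=1e-10)

    def test_bootstrap_se_is_seeded(self):
        hs = _hs_from_ratios([0.1, 0.4, 0.2, 0.9], [0.1, 0.2, 0.15, 0.3])
        a = weighted_median(hs, n_boot=300, seed=42)
        b = weighted_median(hs, n_boot=300, seed=42)
        assert a.se == b.se

    def test_robust_to_minority_directional_pleiotropy(self):
        """With 20% of instrument weight grossly directionally pleiotropic,
        the weighted median stays near theta (its residual finite-sample
        bias shrinks with per-SNP noise) while IVW is pulled far away."""
        wm_err, ivw_err = [], []
        theta = 0.2
        for s in range(100):
            rng = np.random.default_rng(900 + s)
            cfg = SimConfig(theta=theta, n_snps=50, n_exp=500_000, n_out=500_000,
                            seed=900 + s)
            e, o, _ = simulate_pair(cfg)
            bad = rng.choice(50, size=10, replace=False)
            o = o.copy()
            o.loc[bad, "beta"] += 0.2  # huge directional direct effects
            hs = harmonize(e, o)
            wm_err.append(weighted_median(hs, n_boot=100, seed=s).beta - theta)
            ivw_err.append(ivw(hs, model="auto")[0].beta - theta)
        assert abs(np.mean(wm_err)) < 0.01  # within 5% of theta
        assert np.mean(ivw_err) > 10 * abs(np.mean(wm_err))


class TestEstimateFields:
    def test_or_and_ci_consistency(self, harmonized_factory):
        hs = harmonized_factory(k=10, seed=3)
        est, _ = ivw(hs)
        assert est.ci_low < est.ci_high
        assert est.or_ == pytest.approx(np.exp(est.beta), rel=1e-12)
        lo, hi = est.or_ci
        assert lo == pytest.approx(np.exp(est.ci_low), rel=1e-12)
        assert 0 < est.pval <= 1
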