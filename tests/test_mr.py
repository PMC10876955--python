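"""Mendelian-randomisation estimators, diagnostics, and multivariable MR."""

import numpy as np
import pytest

import postgwas as pg
from postgwas.mr import _weighted_median, _conditional_f
from postgwas.synthetic import _rng


def make_ivs(beta_exp, beta_out, se_exp=0.01, se_out=0.02):
    k = len(beta_exp)
    se_exp = np.full(k, se_exp) if np.isscalar(se_exp) else np.asarray(se_exp)
    se_out = np.full(k, se_out) if np.isscalar(se_out) else np.asarray(se_out)
    return pg.IVSet([f"iv{i}" for i in range(k)], np.asarray(beta_exp, float),
                    se_exp, np.asarray(beta_out, float), se_out)


class TestWaldRatio:
    def test_hand_arithmetic(self):
        est = pg.wald_ratio(make_ivs([0.1], [0.05], se_out=0.01))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.ci_low == pytest.approx(0.5 - 1.959964 * 0.1, abs=1e-5)

    def test_zero_outcome_effect(self):
        assert pg.wald_ratio(make_ivs([0.1], [0.0])).beta == 0.0

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ValueError):
            pg.wald_ratio(make_ivs([0.0], [0.05]))


class TestIvw:
    def test_exact_ratio_and_oracle(self):
        ivs = make_ivs([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], se_out=0.02)
        est = pg.ivw(ivs, "fixed")
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        # normal-equations oracle for WLS through the origin
        w = ivs.se_out ** -2
        oracle = np.linalg.solve(
            np.array([[np.sum(w * ivs.beta_exp ** 2)]]),
            np.array([np.sum(w * ivs.beta_exp * ivs.beta_out)]))[0]
        assert est.beta == pytest.approx(oracle, abs=1e-12)

    def test_fe_and_mre_same_point_estimate_different_se(self):
        ivs = make_ivs([0.1, 0.15, 0.2, 0.3], [0.06, 0.07, 0.11, 0.14])
        fe, mre = pg.ivw(ivs, "fixed"), pg.ivw(ivs, "multiplicative_random")
        assert fe.beta == mre.beta
        sigma = np.sqrt(mre.extra["q_stat"] / (ivs.k - 1))
        assert mre.se == pytest.approx(fe.se * sigma, rel=1e-12)

    def test_mre_se_below_fe_when_underdispersed(self):
        # near-collinear ratios: Q/(k-1) << 1, the no-floor convention keeps it
        ivs = make_ivs([0.1, 0.2, 0.3, 0.4],
                       np.array([0.1, 0.2, 0.3, 0.4]) * 0.5 + 1e-4)
        fe, mre = pg.ivw(ivs, "fixed"), pg.ivw(ivs, "multiplicative_random")
        assert mre.se < fe.se
        floored = pg.ivw(ivs, "multiplicative_random", floor_sigma=True)
        assert floored.se == pytest.approx(fe.se)

    def test_collinear_degenerate_flagged(self):
        ivs = make_ivs([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])
        mre = pg.ivw(ivs, "multiplicative_random")
        assert mre.se == 0.0 and mre.extra.get("degenerate")
        assert pg.ivw(ivs, "fixed").se > 0

    def test_single_iv_delegates_to_wald(self):
        est = pg.ivw(make_ivs([0.1], [0.05], se_out=0.01), "fixed")
        assert est.beta == pytest.approx(0.5)

    def test_recovery_under_null_pleiotropy(self):
        reps, means = 300, []
        for i in range(reps):
            cfg = pg.SynthConfig(seed=1000 + i, n_iv=50,
                                 true_causal_effect=0.2, pleiotropy="none")
            ivs, _ = pg.gen_iv_set(cfg)
            means.append(pg.ivw(ivs).beta)
        assert abs(np.mean(means) - 0.2) < 0.02


class TestEgger:
    def test_identical_ratios_no_pleiotropy(self):
        ivs = make_ivs([0.1, 0.2, 0.3], [0.07, 0.14, 0.21])
        est, icpt, _, _ = pg.egger(ivs)
        assert est.beta == pytest.approx(0.7, abs=1e-10)
        assert icpt == pytest.approx(0.0, abs=1e-10)

    def test_directional_pleiotropy_recovered(self):
        slopes, icpts = [], []
        for i in range(300):
            cfg = pg.SynthConfig(seed=2000 + i, n_iv=30,
                                 true_causal_effect=0.15,
                                 pleiotropy="directional",
                                 pleiotropy_mean=0.05, pleiotropy_sd=0.02)
            ivs, truth = pg.gen_iv_set(cfg)
            est, icpt, _, _ = pg.egger(ivs)
            slopes.append(est.beta)
            icpts.append(icpt)
        mc_se = np.std(icpts, ddof=1) / np.sqrt(len(icpts))
        assert abs(np.mean(icpts) - 0.05) < 2 * mc_se + 5e-3
        mc_se_s = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.15) < 2 * mc_se_s + 5e-3

    def test_balanced_pleiotropy_intercept_type_I(self):
        rejections = 0
        reps = 2000
        for i in range(reps):
            cfg = pg.SynthConfig(seed=3000 + i, n_iv=30,
                                 true_causal_effect=0.15,
                                 pleiotropy="balanced", pleiotropy_sd=0.05)
            ivs, _ = pg.gen_iv_set(cfg)
            _, _, _, icpt_p = pg.egger(ivs)
            rejections += icpt_p < 0.05
        assert abs(rejections / reps - 0.05) < 0.02

    def test_too_few_ivs_raises(self):
        with pytest.raises(ValueError):
            pg.egger(make_ivs([0.1, 0.2], [0.05, 0.1]))


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        ivs = make_ivs([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        est = pg.weighted_median(ivs, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5)
        assert est.se > 0

    def test_outlier_resistant_unlike_ivw(self):
        ivs = make_ivs([0.1] * 5, [0.05, 0.05, 0.05, 0.05, 0.5])
        wm = pg.weighted_median(ivs, n_boot=0)
        assert wm.beta == pytest.approx(0.5, abs=0.05)
        assert pg.ivw(ivs).beta > 1.0

    def test_cumulative_midpoint_interpolation_oracle(self):
        ratios = np.array([1.0, 2.0, 3.0, 4.0])
        weights = np.array([0.1, 0.2, 0.3, 0.4])
        got = _weighted_median(ratios, weights)
        # independent implementation of the midpoint rule
        cum = np.cumsum(weights) - 0.5 * weights
        expected = np.interp(0.5, cum, ratios)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(3.0 + 0.05 / 0.35, abs=1e-12)

    def test_bootstrap_deterministic_under_seed(self):
        ivs = make_ivs([0.1, 0.12, 0.2, 0.25], [0.05, 0.07, 0.11, 0.12])
        a = pg.weighted_median(ivs, n_boot=300, seed=42)
        b = pg.weighted_median(ivs, n_boot=300, seed=42)
        assert a.se == b.se


class TestWeightedMode:
    def test_all_ratios_equal(self):
        ivs = make_ivs([0.1, 0.2, 0.3], [0.05, 0.10, 0.15])
        assert pg.weighted_mode(ivs, n_boot=0).beta == pytest.approx(0.5, abs=0.01)

    def test_valid_majority_cluster(self, rng):
        k = 20
        bx = rng.uniform(0.08, 0.3, k)
        ratios = np.where(np.arange(k) < 12, 0.3, 1.0)
        noise = rng.normal(0, 0.003, k)
        ivs = make_ivs(bx, bx * ratios + noise, se_out=0.005)
        est = pg.weighted_mode(ivs, n_boot=0)
        assert est.beta == pytest.approx(0.3, abs=0.06)

    def test_large_bandwidth_tends_to_weighted_mean(self):
        ivs = make_ivs([0.1, 0.2, 0.25, 0.3], [0.03, 0.09, 0.1, 0.2])
        est = pg.weighted_mode(ivs, bandwidth_factor=100.0, n_boot=0)
        r, v = ivs.ratios()
        w = 1 / v
        assert est.beta == pytest.approx(np.sum(w * r) / w.sum(), abs=0.05)


class TestLeaveOneOut:
    def test_returns_k_refits(self):
        ivs = make_ivs([0.1, 0.2, 0.3, 0.4], [0.05, 0.1, 0.16, 0.2])
        fits, _ = pg.leave_one_out(ivs)
        assert len(fits) == 4
        assert {d for d, _ in fits} == set(ivs.iv_ids)

    def test_homogeneous_strong_signal_robust(self):
        cfg = pg.SynthConfig(seed=5, n_iv=30, true_causal_effect=0.3)
        ivs, _ = pg.gen_iv_set(cfg)
        _, loo_max_p = pg.leave_one_out(ivs)
        assert loo_max_p < 0.05

    def test_single_iv_driven_signal_flagged(self):
        bx = np.full(10, 0.1)
        by = np.full(10, 0.0)
        by[0] = 0.3  # the whole signal lives in one instrument
        ivs = make_ivs(bx, by, se_out=0.05)
        _, loo_max_p = pg.leave_one_out(ivs)
        assert loo_max_p >= 0.05


class TestDiagnostics:
    def test_f_statistic_arithmetic(self):
        mean_f, f, _ = pg.instrument_diagnostics(make_ivs([0.1, 0.1], [0, 0],
                                                          se_exp=0.02))
        assert mean_f == pytest.approx(25.0)
        np.testing.assert_allclose(f, 25.0)

    def test_identical_instruments_zero_i2(self):
        _, _, i2 = pg.instrument_diagnostics(make_ivs([0.1] * 4, [0.0] * 4))
        assert i2 == 0.0

    def test_heterogeneous_strong_instruments_i2_near_one(self):
        bx = np.array([0.05, 0.1, 0.2, 0.4, 0.8])
        ivs = make_ivs(bx, bx * 0.5, se_exp=0.001)
        _, _, i2 = pg.instrument_diagnostics(ivs)
        # independent Q computation
        w = ivs.se_exp ** -2.0
        xbar = np.sum(w * bx) / w.sum()
        q = np.sum(w * (bx - xbar) ** 2)
        assert i2 == pytest.approx((q - 4) / q, abs=1e-12)
        assert i2 > 0.999


class TestEstimatorInvariances:
    @pytest.mark.parametrize("method", ["ivw", "egger", "median", "mode"])
    def test_exposure_rescaling_equivariance(self, method, rng):
        cfg = pg.SynthConfig(seed=77, n_iv=15, true_causal_effect=0.15)
        ivs, _ = pg.gen_iv_set(cfg)
        c = 3.0
        scaled = pg.IVSet(ivs.iv_ids, c * ivs.beta_exp, c * ivs.se_exp,
                          ivs.beta_out, ivs.se_out)
        est = {
            "ivw": lambda s: pg.ivw(s).beta,
            "egger": lambda s: pg.egger(s)[0].beta,
            "median": lambda s: pg.weighted_median(s, n_boot=0).beta,
            "mode": lambda s: pg.weighted_mode(s, n_boot=0).beta,
        }[method]
        assert est(scaled) == pytest.approx(est(ivs) / c, rel=1e-6)

    @pytest.mark.parametrize("method", ["ivw", "egger", "median", "mode"])
    def test_single_iv_orientation_flip_invariance(self, method):
        cfg = pg.SynthConfig(seed=78, n_iv=12, true_causal_effect=0.15)
        ivs, _ = pg.gen_iv_set(cfg)
        flip = np.ones(ivs.k)
        flip[3] = -1.0
        flipped = pg.IVSet(ivs.iv_ids, flip * ivs.beta_exp, ivs.se_exp,
                           flip * ivs.beta_out, ivs.se_out)
        est = {
            "ivw": lambda s: pg.ivw(s).beta,
            "egger": lambda s: pg.egger(s)[0].beta,
            "median": lambda s: pg.weighted_median(s, n_boot=0).beta,
            "mode": lambda s: pg.weighted_mode(s, n_boot=0).beta,
        }[method]
        assert est(flipped) == pytest.approx(est(ivs), rel=1e-9)


class TestMvmr:
    def test_single_exposure_reduces_to_ivw(self):
        cfg = pg.SynthConfig(seed=9, n_iv=20, true_causal_effect=0.15)
        ivs, _ = pg.gen_iv_set(cfg)
        res = pg.mvmr_fit(ivs.beta_exp[:, None], ivs.se_exp[:, None],
                          ivs.beta_out, ivs.se_out, "ivw")
        uni = pg.ivw(ivs)
        assert res["exposures"]["exp1"]["beta"] == pytest.approx(uni.beta, abs=1e-12)

    def test_two_exposure_normal_equations_oracle(self):
        X = np.array([[0.1, 0.02], [0.2, 0.05], [0.15, 0.2], [0.05, 0.15],
                      [0.3, 0.1], [0.25, 0.25]])
        SX = np.full_like(X, 0.01)
        y = np.array([0.06, 0.11, 0.14, 0.09, 0.17, 0.21])
        sy = np.array([0.02, 0.02, 0.03, 0.02, 0.04, 0.03])
        res = pg.mvmr_fit(X, SX, y, sy, "ivw")
        W = np.diag(sy ** -2)
        oracle = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert res["exposures"]["exp1"]["beta"] == pytest.approx(oracle[0], abs=1e-10)
        assert res["exposures"]["exp2"]["beta"] == pytest.approx(oracle[1], abs=1e-10)

    def test_conditional_f_orthogonal_exposures(self):
        rng = np.random.default_rng(13)
        ratios = []
        for _ in range(100):
            k = 40
            X = np.column_stack([
                np.concatenate([rng.uniform(0.1, 0.3, k // 2), np.zeros(k // 2)]),
                np.concatenate([np.zeros(k // 2), rng.uniform(0.1, 0.3, k // 2)]),
            ]) + rng.normal(0, 0.01, (k, 2))
            SX = np.full((k, 2), 0.01)
            f_cond = _conditional_f(X, SX, np.full(k, 0.02))
            f_uni = [np.mean((X[:, j] / SX[:, j]) ** 2) * k / (k - 1)
                     for j in range(2)]
            ratios.append(f_cond[0] / f_uni[0])
        assert abs(np.mean(ratios) - 1.0) < 0.1

    def test_too_few_instruments_raises(self):
        with pytest.raises(ValueError):
            pg.mvmr_fit(np.ones((2, 2)), np.full((2, 2), 0.01),
                        np.ones(2), np.full(2, 0.02), "ivw")

    def test_rank_deficient_raises(self):
        X = np.column_stack([np.arange(1, 7, dtype=float)] * 2)
        with pytest.raises(ValueError):
            pg.mvmr_fit(X, np.full((6, 2), 0.01), np.ones(6),
                        np.full(6, 0.02), "ivw")

    def test_lasso_downweights_invalid_instruments(self):
        rng = np.random.default_rng(21)
        k = 30
        bx = rng.uniform(0.1, 0.3, k)
        by = 0.2 * bx + rng.normal(0, 0.01, k)
        by[:5] += 0.25  # five blatantly pleiotropic instruments
        res = pg.mvmr_fit(bx[:, None], np.full((k, 1), 0.01), by,
                          np.full(k, 0.01), "lasso")
        assert res["n_valid_iv"] <= k - 5
        assert res["exposures"]["exp1"]["beta"] == pytest.approx(0.2, abs=0.03)
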