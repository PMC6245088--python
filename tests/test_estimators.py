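"""Wald ratios, IVW/ML combining, MR-Egger, weighted median, heterogeneity,
leave-one-out and unit rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrinfer import estimators as est
from mrinfer.simulate import Pleiotropy, SimulationConfig, simulate_summary_stats
from conftest import hsnp


class TestWaldRatio:
    def test_first_order(self):
        r = est.wald_ratio(hsnp(bx=0.1, sx=0.01, by=0.02, sy=0.01))
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1)
        assert r.weight == pytest.approx(100.0)

    def test_null_outcome(self):
        r = est.wald_ratio(hsnp(bx=0.1, by=0.0, sy=0.03))
        assert r.beta == 0.0
        assert r.se == pytest.approx(0.3)

    def test_second_order(self):
        # closed-form oracle: sqrt(0.01 + 0.01)
        r = est.wald_ratio(hsnp(bx=0.1, sx=0.05, by=0.02, sy=0.01),
                           order="second")
        assert r.se == pytest.approx(math.sqrt(0.02), abs=1e-9)

    def test_zero_exposure_refused(self):
        bad = hsnp(bx=0.0)
        with pytest.raises(ZeroDivisionError, match="rs1"):
            est.wald_ratio(bad)


class TestCombineIvw:
    def test_single_ratio_passthrough(self):
        r = est.RatioEstimate("rs1", beta=0.2, se=0.1)
        res = est.combine_ivw([r], "fixed")
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)
        assert res.df == 0
        assert math.isnan(res.pvalue)
        assert math.isnan(res.ci_low)

    def test_two_equal_ratios(self):
        rs = [est.RatioEstimate(f"rs{i}", beta=0.3, se=0.2) for i in range(2)]
        res = est.combine_ivw(rs, "fixed")
        assert res.beta == pytest.approx(0.3)
        assert res.se == pytest.approx(0.2 / math.sqrt(2))

    def test_empty_refused(self):
        with pytest.raises(ValueError):
            est.combine_ivw([])

    def test_reorder_invariance(self):
        rs = [est.RatioEstimate(f"rs{i}", beta=b, se=s)
              for i, (b, s) in enumerate([(0.1, 0.2), (-0.3, 0.5), (0.2, 0.1)])]
        a = est.combine_ivw(rs, "fixed")
        b = est.combine_ivw(rs[::-1], "fixed")
        assert a.beta == pytest.approx(b.beta, abs=1e-15)
        assert a.se == pytest.approx(b.se, abs=1e-15)

    def test_joint_sign_flip_invariance(self):
        # flipping (beta_exposure, beta_outcome) together leaves the Wald
        # ratio — hence the IVW estimate — unchanged: (-by)/(-bx) = by/bx
        # and se = sy/|bx| either way
        bx, by, sy = 0.2, -0.03, 0.2
        r = est.wald_ratio(hsnp("rs2", bx=bx, by=by, sy=sy))
        assert r.beta == pytest.approx((-by) / (-bx))
        assert r.se == pytest.approx(sy / abs(-bx))

    def test_auto_picks_fixed_when_homogeneous(self):
        rs = [est.RatioEstimate(f"rs{i}", beta=0.1, se=0.2) for i in range(4)]
        res = est.combine_ivw(rs, "auto")
        assert res.effects_model == "fixed"

    def test_random_scales_se_by_dispersion(self):
        rs = [est.RatioEstimate("rs1", 0.0, 0.1),
              est.RatioEstimate("rs2", 1.0, 0.1),
              est.RatioEstimate("rs3", 2.0, 0.1)]
        fixed = est.combine_ivw(rs, "fixed")
        rand = est.combine_ivw(rs, "random")
        het = est.heterogeneity_stats(rs)
        assert rand.se == pytest.approx(fixed.se * math.sqrt(het.q / 2))


class TestMaxLikelihood:
    def test_vanishing_exposure_noise_equals_ivw(self):
        rng = np.random.default_rng(3)
        snps = [hsnp(f"rs{i}", bx=float(rng.uniform(0.02, 0.1)), sx=1e-8,
                     by=float(rng.normal(0, 0.05)),
                     sy=float(rng.uniform(0.05, 0.2))) for i in range(8)]
        ml = est.combine_max_likelihood(snps, "fixed")
        ivw = est.combine_ivw(est.ratio_estimates(snps), "fixed")
        assert ml.beta == pytest.approx(ivw.beta, abs=1e-6)
        assert ml.se == pytest.approx(ivw.se, rel=1e-4)

    def test_recovers_simulated_effect(self):
        cfg = SimulationConfig(n_snps=50, theta=0.3,
                               se_exposure_dist=(0.001, 0.002),
                               se_outcome_dist=(0.01, 0.02), seed=11)
        ml = est.combine_max_likelihood(simulate_summary_stats(cfg), "fixed")
        assert abs(ml.beta - 0.3) < 3 * ml.se

    def test_needs_two_snps(self):
        with pytest.raises(ValueError):
            est.combine_max_likelihood([hsnp()])

    def test_convergence_error_carries_fallback(self):
        snps = [hsnp(f"rs{i}", bx=0.05 + 0.01 * i, by=0.01 * i)
                for i in range(4)]
        with pytest.raises(est.MlConvergenceError) as exc:
            est.combine_max_likelihood(snps, "fixed", max_iter=1)
        assert exc.value.ivw_fallback.method == "ivw"


class TestEgger:
    def _line_snps(self, theta, c, L=6, seed=5):
        rng = np.random.default_rng(seed)
        bx = rng.uniform(0.02, 0.12, L)
        sy = rng.uniform(0.05, 0.2, L)
        return [hsnp(f"rs{i}", bx=float(bx[i]), sx=0.01,
                     by=float(theta * bx[i] + c), sy=float(sy[i]))
                for i in range(L)]

    def test_exact_recovery_on_noiseless_line(self):
        e = est.egger_regression(self._line_snps(theta=0.4, c=0.03))
        assert e.slope.beta == pytest.approx(0.4, abs=1e-10)
        assert e.intercept == pytest.approx(0.03, abs=1e-10)

    def test_zero_intercept_line(self):
        e = est.egger_regression(self._line_snps(theta=-0.2, c=0.0))
        assert e.intercept == pytest.approx(0.0, abs=1e-12)
        assert e.slope.beta == pytest.approx(-0.2, abs=1e-10)

    def test_through_origin_equals_ivw(self):
        rng = np.random.default_rng(9)
        snps = [hsnp(f"rs{i}", bx=float(rng.uniform(0.02, 0.1)),
                     by=float(rng.normal(0, 0.1)),
                     sy=float(rng.uniform(0.05, 0.2))) for i in range(7)]
        constrained = est.egger_regression(snps, _force_zero_intercept=True)
        ivw = est.combine_ivw(est.ratio_estimates(snps), "fixed")
        assert constrained.slope.beta == pytest.approx(ivw.beta, abs=1e-10)

    def test_rank_deficiency(self):
        snps = [hsnp(f"rs{i}", bx=0.05, by=0.01 * i) for i in range(4)]
        with pytest.raises(ValueError, match="rank"):
            est.egger_regression(snps)

    def test_needs_three_snps(self):
        with pytest.raises(ValueError):
            est.egger_regression([hsnp("rs1"), hsnp("rs2", bx=0.2)])

    def test_unoriented_exposure_rejected(self):
        bad = [hsnp("rs1"), hsnp("rs2", bx=0.2),
               hsnp("rs3", bx=0.3, by=-0.01)]
        object.__setattr__(bad[2], "beta_exposure", -0.3)
        with pytest.raises(ValueError, match="orient"):
            est.egger_regression(bad)

    def test_df_is_n_minus_two(self):
        e = est.egger_regression(self._line_snps(0.1, 0.01, L=5))
        assert e.slope.df == 3


class TestWeightedMedian:
    def _snps_from_ratios(self, betas, weights):
        # encode desired ratio betas/weights as bx=1, by=beta, sy=1/sqrt(w)
        return [hsnp(f"rs{i}", bx=1.0, sx=1e-8, by=float(b),
                     sy=float(1 / math.sqrt(w)))
                for i, (b, w) in enumerate(zip(betas, weights))]

    def test_equal_weights_middle_value(self):
        res = est.weighted_median(self._snps_from_ratios([1, 2, 3], [1, 1, 1]),
                                  n_boot=100, seed=1)
        assert res.beta == pytest.approx(2.0)

    def test_hand_interpolation_oracle(self):
        # weights (0.7, 0.15, 0.15), betas (-0.2, 1, 2): positions s =
        # (0.35, 0.775, 0.925); interp at 0.5 -> -0.2 + (0.15/0.425)*1.2
        res = est.weighted_median(
            self._snps_from_ratios([-0.2, 1, 2], [0.7, 0.15, 0.15]),
            n_boot=100, seed=1)
        assert res.beta == pytest.approx(0.223529, abs=1e-5)

    def test_equal_weights_matches_interpolated_median(self):
        betas = [-0.4, -0.1, 0.2, 0.5, 0.9, 1.3]
        res = est.weighted_median(self._snps_from_ratios(betas, [1] * 6),
                                  n_boot=100, seed=1)
        b = np.array(betas)
        s = (np.cumsum(np.full(6, 1 / 6)) - 1 / 12)
        assert res.beta == pytest.approx(float(np.interp(0.5, s, b)))

    def test_bootstrap_reproducible(self):
        snps = self._snps_from_ratios([-0.2, 1, 2], [0.7, 0.15, 0.15])
        a = est.weighted_median(snps, n_boot=500, seed=42)
        b = est.weighted_median(snps, n_boot=500, seed=42)
        assert a.se == b.se
        c = est.weighted_median(snps, n_boot=500, seed=43)
        assert a.se != c.se

    def test_small_bootstrap_refused(self):
        with pytest.raises(ValueError, match="n_boot"):
            est.weighted_median(self._snps_from_ratios([1, 2, 3], [1, 1, 1]),
                                n_boot=50)

    def test_needs_three_snps(self):
        with pytest.raises(ValueError):
            est.weighted_median(self._snps_from_ratios([1, 2], [1, 1]),
                                n_boot=100)


class TestHeterogeneity:
    def test_identical_ratios(self):
        rs = [est.RatioEstimate(f"rs{i}", 0.2, 0.1) for i in range(4)]
        het = est.heterogeneity_stats(rs)
        assert het.q == pytest.approx(0.0, abs=1e-20)
        assert het.i2 == 0.0
        assert het.pvalue == 1.0

    @given(shift=st.floats(-5, 5))
    def test_translation_invariance(self, shift):
        rs = [est.RatioEstimate("rs1", 0.1, 0.2),
              est.RatioEstimate("rs2", -0.4, 0.5),
              est.RatioEstimate("rs3", 0.8, 0.3)]
        shifted = [est.RatioEstimate(r.rsid, r.beta + shift, r.se) for r in rs]
        q0 = est.heterogeneity_stats(rs).q
        q1 = est.heterogeneity_stats(shifted).q
        assert q1 == pytest.approx(q0, rel=1e-9, abs=1e-9)

    def test_i2_clamped_nonnegative(self):
        rs = [est.RatioEstimate("rs1", 0.1, 1.0),
              est.RatioEstimate("rs2", 0.11, 1.0)]
        het = est.heterogeneity_stats(rs)
        assert het.i2 == 0.0
        assert het.q < het.df


class TestLeaveOneOut:
    def _ivw(self, snps):
        return est.combine_ivw(est.ratio_estimates(snps), "fixed")

    def test_cardinality(self, overall_snps):
        out = est.leave_one_out(overall_snps, self._ivw)
        assert len(out) == 5
        assert {rsid for rsid, _ in out} == {s.rsid for s in overall_snps}

    def test_two_snps_each_equals_other_ratio(self):
        snps = [hsnp("rs1", bx=0.1, by=0.02, sy=0.05),
                hsnp("rs2", bx=0.2, by=-0.03, sy=0.08)]
        out = dict(est.leave_one_out(snps, self._ivw))
        r1 = est.wald_ratio(snps[0])
        r2 = est.wald_ratio(snps[1])
        assert out["rs1"].beta == pytest.approx(r2.beta)
        assert out["rs2"].beta == pytest.approx(r1.beta)

    def test_zero_weight_snp_is_inert(self):
        snps = [hsnp("rs1", bx=0.1, by=0.02, sy=0.05),
                hsnp("rs2", bx=0.2, by=-0.03, sy=0.08),
                hsnp("rs3", bx=0.1, by=5.0, sy=1e8)]  # weight ~ 0
        full = self._ivw(snps)
        out = dict(est.leave_one_out(snps, self._ivw))
        assert out["rs3"].beta == pytest.approx(full.beta, abs=1e-10)

    def test_estimator_failure_labelled(self):
        snps = [hsnp("rs1"), hsnp("rs2", bx=0.2), hsnp("rs3", bx=0.3)]

        def fragile(subset):
            raise ValueError("boom")

        with pytest.raises(RuntimeError, match="rs1"):
            est.leave_one_out(snps, fragile)


class TestScaleEstimate:
    def _res(self):
        rs = [est.RatioEstimate(f"rs{i}", b, s) for i, (b, s) in
              enumerate([(0.1, 0.2), (0.3, 0.25), (-0.2, 0.4)])]
        return est.combine_ivw(rs, "fixed")

    def test_identity(self):
        res = self._res()
        assert est.scale_estimate(res, 1.0) is res

    def test_factor_two_preserves_p(self):
        res = self._res()
        doubled = est.scale_estimate(res, 2.0)
        assert doubled.beta == pytest.approx(2 * res.beta)
        assert doubled.se == pytest.approx(2 * res.se)
        assert doubled.pvalue == pytest.approx(res.pvalue, rel=1e-12)

    def test_round_trip(self):
        res = self._res()
        back = est.scale_estimate(est.scale_estimate(res, 0.5), 2.0)
        assert back.beta == pytest.approx(res.beta, rel=1e-12)
        assert back.ci_low == pytest.approx(res.ci_low, rel=1e-12)

    def test_nonpositive_factor_refused(self):
        with pytest.raises(ValueError):
            est.scale_estimate(self._res(), 0.0)
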