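"""Closed-form stationary moments: exact values, reductions, monotonicity."""

import math

import numpy as np
import pytest

from shsize import (
    MultiStepParams,
    SingleStepParams,
    adder_cv2_approx,
    adder_cv2_exact,
    adder_moment_closed_form,
    adder_moments,
    adder_skewness,
    make_partition_law,
    mean_log_beta,
    multistep_cv2_limit,
    multistep_equal_rates,
    multistep_moments,
    multistep_second_moment_pair_sum,
    newborn_cv2,
    powerlaw_closure,
    powerlaw_exact_rational,
    powerlaw_y_moments,
)

LOG4M1 = math.log(4.0) - 1.0


class TestAdder:
    def test_perfect_halving_values(self, det_law):
        s = adder_moments(SingleStepParams(1.0, 1.0, 1.0), det_law, max_order=3)
        assert s.cv2 == pytest.approx(LOG4M1, rel=1e-12)
        assert s.mean_size == pytest.approx(1.0 / math.log(2.0), rel=1e-12)
        assert s.second_moment == pytest.approx(2.0 / math.log(2.0), rel=1e-12)
        assert s.exact

    def test_noise_invariant_under_rate_rescaling(self, noisy_law):
        a = adder_moments(SingleStepParams(1.0, 1.0, 1.0), noisy_law)
        b = adder_moments(SingleStepParams(10.0, 10.0, 1.0), noisy_law)
        assert a.cv2 == pytest.approx(b.cv2, rel=1e-12)
        assert a.skewness == pytest.approx(b.skewness, rel=1e-12)

    def test_mean_scales_with_mu_over_k(self, det_law):
        a = adder_moments(SingleStepParams(2.0, 1.0, 1.0), det_law)
        b = adder_moments(SingleStepParams(1.0, 1.0, 1.0), det_law)
        assert a.mean_size == pytest.approx(2.0 * b.mean_size, rel=1e-12)

    @pytest.mark.parametrize("cv2_beta", [0.0, 0.05, 0.1, 0.3])
    def test_closed_product_form_equals_recursion(self, cv2_beta):
        law = make_partition_law(0.5, cv2_beta)
        params = SingleStepParams(1.3, 0.7, 1.0)
        s = adder_moments(params, law, max_order=6)
        for order in range(1, 7):
            assert adder_moment_closed_form(params, law, order) == pytest.approx(
                s.moments[order - 1], rel=1e-10
            )

    def test_rejects_non_adder_exponent(self, det_law):
        with pytest.raises(ValueError, match="alpha = 1"):
            adder_moments(SingleStepParams(1.0, 1.0, 2.0), det_law)


class TestAdderApproximation:
    def test_zero_noise_reduces_to_exact(self, det_law):
        assert adder_cv2_approx(det_law) == pytest.approx(LOG4M1, rel=1e-12)

    def test_close_to_exact_digamma_value(self):
        law = make_partition_law(0.5, 0.1)
        assert abs(adder_cv2_approx(law) - adder_cv2_exact(law)) < 0.02

    def test_monotone_increasing_in_partition_noise(self):
        vals = [adder_cv2_approx(make_partition_law(0.5, v)) for v in
                np.linspace(0.0, 0.5, 11)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_exact_also_monotone_in_partition_noise(self):
        vals = [adder_cv2_exact(make_partition_law(0.5, v)) for v in
                np.linspace(0.0, 0.8, 17)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestSkewnessAndNewborn:
    def test_skewness_perfect_halving(self, det_law):
        assert adder_skewness(det_law) == pytest.approx(1.68, abs=0.005)

    def test_skewness_roughly_flat_at_low_noise(self):
        vals = [adder_skewness(make_partition_law(0.5, v)) for v in (0.0, 0.05, 0.09)]
        assert max(vals) - min(vals) < 0.12

    def test_newborn_noise_floor(self, det_law):
        assert newborn_cv2(det_law, cv2_added=1.0) == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("m_stages", [1, 2, 5, 10])
    def test_newborn_floor_scales_with_stage_count(self, det_law, m_stages):
        assert newborn_cv2(det_law, cv2_added=1.0 / m_stages) == pytest.approx(
            1.0 / (3.0 * m_stages)
        )

    def test_newborn_formula_single_step(self):
        law = make_partition_law(0.5, 0.2)
        assert newborn_cv2(law) == pytest.approx((1 + 5 * 0.2) / (3 - 0.2))


class TestSensitivities:
    def test_size_noise_slope_in_partition_noise_is_one(self):
        h = 1e-6
        up = adder_cv2_exact(make_partition_law(0.5, h))
        lo = adder_cv2_exact(make_partition_law(0.5, 0.0))
        assert (up - lo) / h == pytest.approx(1.0, abs=1e-3)

    def test_newborn_noise_slope_is_sixteen_ninths(self):
        h = 1e-6
        up = newborn_cv2(make_partition_law(0.5, h))
        lo = newborn_cv2(make_partition_law(0.5, 0.0))
        assert (up - lo) / h == pytest.approx(16.0 / 9.0, abs=1e-3)


class TestPowerLaw:
    def test_identity_transform_matches_adder(self, noisy_law):
        p = SingleStepParams(1.0, 1.0, 1.0)
        y = powerlaw_y_moments(p, noisy_law, max_order=3)
        s = adder_moments(p, noisy_law, max_order=3)
        assert y.mean_size == pytest.approx(s.mean_size, rel=1e-12)
        assert y.second_moment == pytest.approx(s.second_moment, rel=1e-12)

    @pytest.mark.parametrize("alpha", [0.5, 2.0, 3.0])
    def test_mean_of_transform_independent_of_alpha(self, det_law, alpha):
        y = powerlaw_y_moments(SingleStepParams(1.0, 1.0, alpha), det_law)
        assert y.mean_size == pytest.approx(-1.0 / mean_log_beta(det_law), rel=1e-12)

    def test_recursion_against_brute_force(self, det_law):
        """Independent evaluation of the transformed-moment recursion."""
        alpha, mu, k = 3.0, 1.0, 1.0
        y = powerlaw_y_moments(SingleStepParams(mu, k, alpha), det_law, max_order=6)
        expected = [-mu / (k * mean_log_beta(det_law))]
        for p in range(1, 6):
            expected.append(
                p * alpha * mu * expected[-1] / (k * (1.0 - 0.5 ** (alpha * p)))
            )
        np.testing.assert_allclose(y.moments, expected, rtol=1e-12)

    def test_rational_exponent_exact_moments(self, det_law):
        p = SingleStepParams(1.0, 1.0, 1.0 / 3.0)
        y = powerlaw_y_moments(p, det_law, max_order=6)
        s = powerlaw_exact_rational(p, det_law)
        assert s.mean_size == pytest.approx(y.moments[2], rel=1e-12)
        assert s.second_moment == pytest.approx(y.moments[5], rel=1e-12)

    def test_rational_q1_reduces_to_adder(self, det_law):
        p = SingleStepParams(1.0, 1.0, 1.0)
        s = powerlaw_exact_rational(p, det_law)
        a = adder_moments(p, det_law)
        assert s.mean_size == pytest.approx(a.mean_size, rel=1e-12)
        assert s.second_moment == pytest.approx(a.second_moment, rel=1e-12)

    def test_rational_rejects_other_exponents(self, det_law):
        with pytest.raises(ValueError, match="1/q"):
            powerlaw_exact_rational(SingleStepParams(1.0, 1.0, 0.4), det_law)


class TestClosure:
    def test_exact_at_adder_boundary(self, noisy_law):
        c = powerlaw_closure(SingleStepParams(1.0, 1.0, 1.0), noisy_law)
        a = adder_moments(SingleStepParams(1.0, 1.0, 1.0), noisy_law)
        assert c.cv2 == pytest.approx(a.cv2, rel=1e-12)
        assert c.mean_size == pytest.approx(a.mean_size, rel=1e-12)
        assert c.exact

    def test_sizer_alpha2_value(self, det_law):
        c = powerlaw_closure(SingleStepParams(1.0, 1.0, 2.0), det_law)
        assert c.cv2 == pytest.approx(math.sqrt(math.log(4.0)) - 1.0, rel=1e-12)
        assert not c.exact

    def test_noise_decreasing_in_alpha(self, det_law):
        cv2s = [
            powerlaw_closure(SingleStepParams(1.0, 1.0, a), det_law).cv2
            for a in (1.0, 2.0, 4.0, 8.0)
        ]
        assert all(x > y for x, y in zip(cv2s, cv2s[1:]))
        assert all(v > 0 for v in cv2s)

    def test_mean_scale_equivariance(self, det_law):
        """Mean carries the (mu/k)^(1/alpha) scale; noise does not."""
        a = powerlaw_closure(SingleStepParams(8.0, 1.0, 3.0), det_law)
        b = powerlaw_closure(SingleStepParams(1.0, 1.0, 3.0), det_law)
        assert a.mean_size == pytest.approx(2.0 * b.mean_size, rel=1e-12)
        assert a.cv2 == pytest.approx(b.cv2, rel=1e-12)


class TestMultiStep:
    def test_single_stage_reduces_to_adder(self, noisy_law):
        m = multistep_moments(MultiStepParams(mu=1.0, rates=(1.0,)), noisy_law)
        a = adder_moments(SingleStepParams(1.0, 1.0, 1.0), noisy_law)
        assert m.mean_size == pytest.approx(a.mean_size, rel=1e-12)
        assert m.second_moment == pytest.approx(a.second_moment, rel=1e-12)

    @pytest.mark.parametrize("M", [2, 5, 10])
    @pytest.mark.parametrize("cv2_beta", [0.0, 0.05])
    def test_recursion_matches_equal_rate_closed_form(self, M, cv2_beta):
        law = make_partition_law(0.5, cv2_beta)
        rec = multistep_moments(MultiStepParams.equal_rates(1.0, 1.0, M), law)
        closed = multistep_equal_rates(1.0, 1.0, M, law)
        assert rec.mean_size == pytest.approx(closed.mean_size, rel=1e-12)
        assert rec.cv2 == pytest.approx(closed.cv2, rel=1e-12)

    @pytest.mark.parametrize(
        "rates", [(1.0, 3.0), (2.0, 0.5, 4.0), (1.0, 1.0, 5.0, 0.3)]
    )
    def test_pair_sum_form_matches_recursion_unequal_rates(self, noisy_law, rates):
        params = MultiStepParams(mu=1.0, rates=rates)
        rec = multistep_moments(params, noisy_law)
        assert multistep_second_moment_pair_sum(params, noisy_law) == pytest.approx(
            rec.second_moment, rel=1e-10
        )

    def test_fast_late_stages_reduce_to_single_step(self, det_law):
        """With k_2..k_M huge the model collapses onto the one-step adder."""
        fast = 1e6
        m = multistep_moments(
            MultiStepParams(mu=1.0, rates=(1.0, fast, fast, fast)), det_law
        )
        a = adder_moments(SingleStepParams(1.0, 1.0, 1.0), det_law)
        assert m.second_moment == pytest.approx(a.second_moment, rel=1e-4)

    def test_equal_rate_printed_values(self, det_law):
        assert multistep_equal_rates(1.0, 1.0, 1, det_law).cv2 == pytest.approx(
            LOG4M1, rel=1e-12
        )
        assert multistep_equal_rates(1.0, 1.0, 10, det_law).cv2 == pytest.approx(
            -1.0 + (15.5 / 20.0) * 2.0 * math.log(2.0), rel=1e-12
        )

    def test_mean_independent_of_stage_count(self, noisy_law):
        means = [
            multistep_equal_rates(1.0, 1.0, M, noisy_law).mean_size
            for M in (1, 3, 17)
        ]
        assert np.ptp(means) < 1e-12 * means[0]

    def test_noise_decreasing_in_stage_count(self, noisy_law):
        cv2s = [
            multistep_equal_rates(1.0, 1.0, M, noisy_law).cv2
            for M in (1, 2, 5, 10, 50, 200)
        ]
        assert all(x > y for x, y in zip(cv2s, cv2s[1:]))

    def test_limit_formula(self, det_law):
        lim = multistep_cv2_limit(det_law)
        assert lim == pytest.approx(1.5 * math.log(2.0) - 1.0, rel=1e-12)
        at_huge_m = multistep_equal_rates(1.0, 1.0, 10**6, det_law).cv2
        assert abs(at_huge_m - lim) < 1e-6

    def test_limit_small_noise_decomposition(self):
        """Exact limit tracks 0.04 + 3 cv2_beta / 4 at small partitioning noise."""
        law = make_partition_law(0.5, 0.04)
        approx = (1.5 * math.log(2.0) - 1.0) + 3.0 * 0.04 / 4.0
        assert abs(multistep_cv2_limit(law) - approx) < 5e-3

    def test_partition_noise_attenuation_ratio(self):
        """Slope of CV2_s in cv2_beta at 0: M -> inf is 3/4 of M = 1."""
        h = 1e-6
        slope_m1 = (
            multistep_equal_rates(1.0, 1.0, 1, make_partition_law(0.5, h)).cv2
            - multistep_equal_rates(1.0, 1.0, 1, make_partition_law(0.5, 0.0)).cv2
        ) / h
        slope_inf = (
            multistep_cv2_limit(make_partition_law(0.5, h))
            - multistep_cv2_limit(make_partition_law(0.5, 0.0))
        ) / h
        assert slope_inf / slope_m1 == pytest.approx(0.75, abs=1e-3)

    def test_noise_positive_everywhere(self):
        for mean in (0.3, 0.5, 0.7):
            for cv2 in (0.0, 0.1):
                if cv2 >= (1 - mean) / mean:
                    continue
                law = make_partition_law(mean, cv2)
                for M in (1, 4, 20):
                    assert multistep_equal_rates(1.0, 1.0, M, law).cv2 > 0
                assert multistep_cv2_limit(law) > 0
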