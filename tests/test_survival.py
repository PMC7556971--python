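"""Survival curves, fitting, and per-cycle transition probabilities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fruqcea import (
    ExponentialDuration,
    KMCurve,
    WeibullSurvival,
    cycle_death_prob,
    discontinuation_prob,
    fit_weibull_km,
    generate_pseudo_ipd,
    km_from_ipd,
    weibull_from_median,
)
from fruqcea.survival import cycle_length_months

DELTA = cycle_length_months()  # 28/30.4375 months

positive = st.floats(min_value=0.05, max_value=50.0, allow_nan=False)
shapes = st.floats(min_value=0.3, max_value=4.0, allow_nan=False)


class TestWeibullSurvival:
    def test_exponential_median(self):
        curve = WeibullSurvival(shape=1.0, scale=9.522)
        assert curve.survival(6.6) == pytest.approx(0.5, abs=1e-4)

    def test_survival_at_zero_is_one(self):
        assert WeibullSurvival(1.7, 8.0).survival(0.0) == 1.0

    def test_survival_at_scale_is_inverse_e(self):
        assert WeibullSurvival(2.0, 10.0).survival(10.0) == pytest.approx(np.exp(-1))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            WeibullSurvival(1.0, 10.0).survival(-0.1)

    @pytest.mark.parametrize("median, expected_scale", [(6.6, 9.5218), (9.3, 13.417)])
    def test_from_median_exponential_scales(self, median, expected_scale):
        curve = weibull_from_median(median, 1.0)
        assert curve.scale == pytest.approx(expected_scale, rel=1e-4)

    @given(median=positive, shape=shapes)
    @settings(derandomize=True, max_examples=50)
    def test_median_is_defining_property(self, median, shape):
        curve = weibull_from_median(median, shape)
        assert curve.survival(median) == pytest.approx(0.5, abs=1e-12)
        assert curve.median == pytest.approx(median, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            weibull_from_median(0.0, 1.0)
        with pytest.raises(ValueError):
            weibull_from_median(5.0, -1.0)


class TestCycleProbabilities:
    def test_exponential_per_cycle_death_closed_form(self):
        curve = weibull_from_median(6.6, 1.0)
        expected = 1.0 - np.exp(-np.log(2) / 6.6 * DELTA)
        for t in (0, 1, 10, 100):
            assert cycle_death_prob(curve, t) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0922, abs=5e-4)

    def test_exponential_memorylessness_across_500_cycles(self):
        curve = weibull_from_median(9.3, 1.0)
        p = curve.cycle_death_prob(np.arange(501))
        assert np.allclose(p, p[0], rtol=1e-10)

    def test_increasing_hazard_gives_increasing_cycle_probability(self):
        curve = WeibullSurvival(1.8, 12.0)
        p = curve.cycle_death_prob(np.arange(60))
        assert np.all(np.diff(p) > 0)

    def test_first_cycle_probability_equals_one_minus_survival(self):
        curve = WeibullSurvival(1.3, 10.0)
        assert cycle_death_prob(curve, 0) == pytest.approx(1.0 - curve.survival(DELTA))

    @given(shape=st.floats(0.8, 2.5), median=st.floats(2.0, 20.0))
    @settings(derandomize=True, max_examples=50)
    def test_telescoping_reconstructs_survival(self, shape, median):
        """Prod(1 - P(t)) over cycles equals S(t*Delta) to 1e-12, over the
        calibration search box (outside it the tail underflows to zero and the
        relative comparison is vacuous)."""
        curve = weibull_from_median(median, shape)
        t = np.arange(200)
        p = curve.cycle_death_prob(t)
        assert np.all(p >= 0) and np.all(p <= 1)
        reconstructed = np.cumprod(1.0 - p)
        direct = curve.survival((t + 1) * DELTA)
        live = direct > 1e-200  # below that the tail underflows to exact zero
        assert np.allclose(reconstructed[live], direct[live], rtol=1e-12)
        assert np.all(reconstructed[~live] <= 1e-200)

    def test_discontinuation_probability_from_trial_median(self):
        p = discontinuation_prob(ExponentialDuration(3.7))
        assert p == pytest.approx(1 - np.exp(-np.log(2) / 3.7 * DELTA), rel=1e-12)
        assert p == pytest.approx(0.1583, abs=5e-4)

    def test_median_of_one_cycle_gives_half(self):
        assert discontinuation_prob(ExponentialDuration(DELTA)) == pytest.approx(0.5)

    def test_infinite_median_limit_is_zero(self):
        assert discontinuation_prob(ExponentialDuration(1e12)) == pytest.approx(0.0, abs=1e-9)


class TestWeibullFitting:
    def test_exact_curve_recovery(self):
        truth = WeibullSurvival(1.3, 10.0)
        t = np.arange(1.0, 25.0)
        km = KMCurve(t, truth.survival(t))
        fit = fit_weibull_km(km)
        assert fit.shape == pytest.approx(1.3, rel=1e-6)
        assert fit.scale == pytest.approx(10.0, rel=1e-6)

    def test_recovery_from_pseudo_ipd(self):
        ipd = generate_pseudo_ipd(1.3, 10.0, n=5000, admin_censor_time=40.0, seed=0)
        fit = fit_weibull_km(km_from_ipd(ipd))
        assert fit.shape == pytest.approx(1.3, rel=0.05)
        assert fit.scale == pytest.approx(10.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_weibull_km(KMCurve([1.0, 2.0], [0.8, 0.6]))

    def test_degenerate_survival_values_excluded(self):
        truth = WeibullSurvival(1.5, 8.0)
        t = np.arange(1.0, 15.0)
        s = truth.survival(t)
        km = KMCurve(np.concatenate([[0.5], t]), np.concatenate([[1.0], s]))
        fit = fit_weibull_km(km)  # the S=1 point must be dropped, not crash the fit
        assert fit.shape == pytest.approx(1.5, rel=1e-6)


class TestKMCurve:
    def test_invalid_orderings_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            KMCurve([2.0, 1.0], [0.9, 0.8])
        with pytest.raises(ValueError, match="non-increasing"):
            KMCurve([1.0, 2.0], [0.8, 0.9])

    def test_csv_round_trip(self, tmp_path):
        km = KMCurve([1.0, 2.0, 3.0], [0.9, 0.5, 0.25])
        path = tmp_path / "km.csv"
        km.to_csv(path)
        back = KMCurve.from_csv(path)
        assert np.allclose(back.times, km.times)
        assert np.allclose(back.survival, km.survival)
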