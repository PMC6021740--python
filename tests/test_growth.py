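"""Baranyi growth kinetics: adjustment function, closed form vs ODE oracle,
square-root secondary model, fluctuating-temperature recursion, recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldchain import (BaranyiParams, TemperatureProfile, adjustment_F,
                       baranyi_log_count, fit_baranyi, mu_from_temperature,
                       simulate_fluctuating)

LN10 = math.log(10.0)


def baranyi_ode_oracle(t_end, p, dt=1e-4):
    """Fixed-step RK4 integration of the Baranyi differential system
    dy/dt = mu (q/(1+q)) (1 - e^{y - ymax}), dq/dt = v q, q(0) = 1/(e^h0 - 1),
    in natural-log units.  Independent of the closed form under test."""
    mu = p.mu_max
    v = p.v if p.v is not None else mu
    y = p.y0 * LN10
    ymax = p.nmax * LN10
    q = math.inf if p.h0 == 0 else 1.0 / math.expm1(p.h0)

    def rhs(y, q):
        alpha = 1.0 if math.isinf(q) else q / (1.0 + q)
        return mu * alpha * (1.0 - math.exp(y - ymax))

    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = rhs(y, q)
        q_mid = q if math.isinf(q) else q * math.exp(v * dt / 2)
        k2 = rhs(y + dt / 2 * k1, q_mid)
        k3 = rhs(y + dt / 2 * k2, q_mid)
        q_end = q if math.isinf(q) else q * math.exp(v * dt)
        k4 = rhs(y + dt * k3, q_end)
        y += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        q = q_end
    return y / LN10


class TestAdjustmentFunction:
    @pytest.mark.parametrize("v,h0", [(0.1, 0.5), (0.5, 2.0), (2.0, 0.0), (1.0, 5.0)])
    def test_zero_at_zero(self, v, h0):
        assert adjustment_F(0.0, v, h0) == 0.0

    @pytest.mark.parametrize("t", [0.0, 0.5, 3.0, 50.0])
    def test_no_lag_collapses_to_identity(self, t):
        assert adjustment_F(t, 0.7, 0.0) == t

    def test_reference_value_and_asymptote(self):
        # direct high-precision evaluation: v=0.5, h0=2, t=10
        v, h0, t = 0.5, 2.0, 10.0
        direct = t + math.log(math.exp(-v * t) + math.exp(-h0)
                              - math.exp(-v * t - h0)) / v
        assert adjustment_F(t, v, h0) == pytest.approx(direct, abs=1e-12)
        assert adjustment_F(t, v, h0) == pytest.approx(6.084, abs=1e-3)
        # late-time asymptote t - h0/v
        assert adjustment_F(100.0, v, h0) == pytest.approx(100.0 - h0 / v, abs=1e-9)

    @given(st.floats(0.0, 50.0), st.floats(0.05, 3.0), st.floats(0.0, 8.0))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, t, v, h0):
        f = adjustment_F(t, v, h0)
        assert -1e-12 <= f <= t + 1e-12
        assert adjustment_F(t + 0.5, v, h0) >= f - 1e-12

    def test_invalid_v_rejected(self):
        with pytest.raises(ValueError, match="v must be"):
            adjustment_F(1.0, 0.0, 1.0)


class TestConstantTemperature:
    def test_starts_at_y0(self, baranyi_params):
        assert baranyi_log_count(0.0, baranyi_params) == baranyi_params.y0

    def test_saturates_at_nmax(self, baranyi_params):
        assert baranyi_log_count(1e3, baranyi_params) == \
            pytest.approx(baranyi_params.nmax, abs=1e-6)

    @pytest.mark.parametrize("mu,h0,t", [
        (0.8, 1.0, 5.0), (0.4, 0.0, 3.0), (1.5, 3.0, 2.0), (0.2, 2.0, 20.0),
    ])
    def test_matches_ode_oracle(self, mu, h0, t):
        p = BaranyiParams(y0=3.0, nmax=9.0, mu_max=mu, v=mu, h0=h0)
        assert baranyi_log_count(t, p) == \
            pytest.approx(baranyi_ode_oracle(t, p), abs=1e-4)

    def test_monotone_and_bounded(self, baranyi_params):
        t = np.linspace(0, 40, 400)
        y = baranyi_log_count(t, baranyi_params)
        assert np.all(np.diff(y) >= -1e-12)
        assert np.all(y >= baranyi_params.y0 - 1e-12)
        assert np.all(y <= baranyi_params.nmax + 1e-9)

    def test_lag_time_equals_h0_over_mu(self):
        """With v = mu, the late-time tangent hits y0 at lag = h0/mu."""
        mu, h0 = 0.8, 2.0
        p = BaranyiParams(y0=2.0, nmax=12.0, mu_max=mu, v=mu, h0=h0)
        t = np.array([15.0, 16.0])  # deep exponential phase, far below nmax
        y = np.asarray(baranyi_log_count(t, p)) * LN10
        slope = (y[1] - y[0]) / (t[1] - t[0])
        lag = t[0] - (y[0] - p.y0 * LN10) / slope
        assert slope == pytest.approx(mu, rel=1e-3)
        assert lag == pytest.approx(h0 / mu, rel=1e-2)

    def test_as_printed_sign_is_not_a_growth_model(self, baranyi_params):
        """The uncorrected saturation sign drives the count below y0."""
        y = baranyi_log_count(5.0, baranyi_params, sign="as-printed")
        assert y < baranyi_params.y0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="nmax"):
            BaranyiParams(y0=9.0, nmax=3.0, mu_max=0.5)
        with pytest.raises(ValueError, match="h0"):
            BaranyiParams(y0=3.0, nmax=9.0, mu_max=0.5, h0=-1)


class TestSecondaryModel:
    def test_zero_rate_at_tmin(self):
        assert mu_from_temperature(-5.0, 0.03, -5.0) == 0.0

    def test_square_of_hand_arithmetic(self):
        assert mu_from_temperature(5.0, 0.03, -5.0) == pytest.approx(0.09)

    def test_below_tmin_clamps_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert mu_from_temperature(-10.0, 0.03, -5.0) == 0.0

    def test_strictly_increasing_above_tmin(self):
        T = np.linspace(-4.9, 25, 50)
        mu = mu_from_temperature(T, 0.03, -5.0)
        assert np.all(np.diff(mu) > 0)

    def test_literal_linear_form_available(self):
        assert mu_from_temperature(5.0, 0.03, -5.0, form="linear") == \
            pytest.approx(0.3)


class TestFluctuatingTemperature:
    def test_single_segment_equals_constant_closed_form(self):
        p = BaranyiParams(y0=3.0, nmax=9.0, b=0.03, t_min=-5.0, h0=1.0)
        profile = TemperatureProfile.from_segments([(5.0, 4.0)])
        curve = simulate_fluctuating(profile, p)
        mu = mu_from_temperature(5.0, 0.03, -5.0)
        const = BaranyiParams(y0=3.0, nmax=9.0, mu_max=mu, v=mu, h0=1.0)
        assert curve.log_counts[-1] == pytest.approx(
            baranyi_log_count(4.0, const), abs=1e-12)

    @given(st.lists(st.floats(0.05, 2.0), min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_lag_free_recursion_is_split_invariant(self, durations):
        """With h0 = 0 the per-segment recursion at constant temperature is a
        semigroup: any segmentation gives the unsplit answer to 1e-10."""
        p = BaranyiParams(y0=3.0, nmax=9.0, b=0.03, t_min=-5.0, h0=0.0)
        total = sum(durations)
        split = simulate_fluctuating(
            TemperatureProfile.from_segments([(5.0, d) for d in durations]), p)
        unsplit = simulate_fluctuating(
            TemperatureProfile.from_segments([(5.0, total)]), p)
        assert split.log_counts[-1] == pytest.approx(
            unsplit.log_counts[-1], abs=1e-10)

    def test_two_segment_hand_rolled_oracle(self):
        """Independent step-by-step evaluation of the recursion with plain
        scalar arithmetic."""
        y0, nmax, b, tmin, h0 = 3.0, 9.0, 0.03, -5.0, 1.0
        y_ln, ymax_ln = y0 * LN10, nmax * LN10
        for T, dt in [(5.0, 2.0), (10.0, 2.0)]:
            mu = (b * (T - tmin)) ** 2
            f = dt + math.log(math.exp(-mu * dt) + math.exp(-h0)
                              - math.exp(-mu * dt - h0)) / mu
            a = mu * f
            y_ln = y_ln + a - math.log(1 + (math.exp(a) - 1)
                                       * math.exp(-(ymax_ln - y_ln)))
        expected = y_ln / LN10

        p = BaranyiParams(y0=y0, nmax=nmax, b=b, t_min=tmin, h0=h0)
        profile = TemperatureProfile.from_segments([(5.0, 2.0), (10.0, 2.0)])
        curve = simulate_fluctuating(profile, p)
        assert curve.log_counts[-1] == pytest.approx(expected, abs=1e-12)
        assert curve.mu_values == pytest.approx((0.09, 0.2025))

    def test_bounded_and_warmer_grows_more(self):
        p = BaranyiParams(y0=3.0, nmax=9.0, b=0.03, t_min=-5.0, h0=1.0)
        cold = simulate_fluctuating(
            TemperatureProfile.from_segments([(2.0, 3.0), (4.0, 3.0)]), p)
        warm = simulate_fluctuating(
            TemperatureProfile.from_segments([(2.0, 3.0), (8.0, 3.0)]), p)
        for curve in (cold, warm):
            y = np.asarray(curve.log_counts)
            assert np.all(np.diff(y) >= -1e-12)
            assert y.min() >= 3.0 - 1e-12 and y.max() <= 9.0 + 1e-9
        assert warm.log_counts[-1] > cold.log_counts[-1]

    def test_continuity_at_breakpoints(self):
        """Halving a segment leaves the shared breakpoint's count unchanged."""
        p = BaranyiParams(y0=3.0, nmax=9.0, b=0.03, t_min=-5.0, h0=0.0)
        coarse = simulate_fluctuating(
            TemperatureProfile.from_segments([(5.0, 2.0), (10.0, 2.0)]), p)
        fine = simulate_fluctuating(
            TemperatureProfile.from_segments([(5.0, 2.0), (10.0, 1.0), (10.0, 1.0)]), p)
        assert fine.log_counts[1] == pytest.approx(coarse.log_counts[1], abs=1e-12)

    def test_empty_profile_rejected(self):
        p = BaranyiParams(y0=3.0, nmax=9.0, mu_max=0.5)
        with pytest.raises(ValueError):
            TemperatureProfile.from_segments([])


class TestParameterRecovery:
    @pytest.mark.parametrize("mu,h0", [(0.8, 1.0), (0.3, 2.5)])
    def test_noise_free_refit_recovers_inputs_to_1_percent(self, mu, h0):
        truth = BaranyiParams(y0=3.0, nmax=9.0, mu_max=mu, h0=h0)
        t = np.linspace(0, 40, 80)
        y = baranyi_log_count(t, truth)
        est = fit_baranyi(t, y)
        assert est.y0 == pytest.approx(truth.y0, rel=0.01)
        assert est.nmax == pytest.approx(truth.nmax, rel=0.01)
        assert est.mu_max == pytest.approx(mu, rel=0.01)
        assert est.h0 == pytest.approx(h0, rel=0.01)
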