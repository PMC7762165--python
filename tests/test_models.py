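"""Closed-form model core: growth law, boundary integral, release series,
concentration profiles and the phase release-rate statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from swellrelease import (
    OnePhaseParams,
    SeriesConfig,
    SwellingParams,
    TimeSeries,
    TwoPhaseParams,
    concentration_profile,
    inverse_square_integral,
    logistic_radius,
    phase_release_rate,
    relative_growth_rate,
    release_one_phase,
    release_two_phase,
)

swelling_st = st.builds(
    SwellingParams,
    L=st.floats(0.5, 20.0),
    m=st.floats(1.0, 3.0),
    g=st.floats(0.0, 5e-4),
)

# device-scale geometry for release-value properties: keeps D*t/L^2 small
# enough that 1 - R stays resolvable in double precision (R < 1 strictly)
device_st = st.builds(
    SwellingParams,
    L=st.floats(4.0, 20.0),
    m=st.floats(1.0, 3.0),
    g=st.floats(0.0, 5e-4),
)


class TestLogisticRadius:
    def test_starts_at_initial_length(self):
        sw = SwellingParams(L=5.0, m=2.0, g=1.49918e-4)
        assert logistic_radius(0.0, sw) == 5.0

    def test_saturates_at_asymptote(self):
        sw = SwellingParams(L=5.0, m=2.0, g=1.49918e-4)
        assert logistic_radius(1e9, sw) == pytest.approx(10.0, rel=1e-9)

    def test_closed_form_midpoint(self):
        # e^{gt} = 3 gives X = L*3/(1 + (3-1)/2) = 1.5 L
        sw = SwellingParams(L=5.0, m=2.0, g=1.49918e-4)
        t = np.log(3.0) / sw.g
        assert logistic_radius(t, sw) == pytest.approx(7.5, rel=1e-12)

    def test_negative_time_rejected(self):
        sw = SwellingParams(L=5.0, m=2.0, g=1e-4)
        with pytest.raises(ValueError):
            logistic_radius(-1.0, sw)

    def test_stationary_when_m_is_one_or_g_zero(self):
        t = np.linspace(0, 1e6, 7)
        for sw in (SwellingParams(L=3.0, m=1.0, g=1e-4),
                   SwellingParams(L=3.0, m=2.0, g=0.0)):
            assert np.all(logistic_radius(t, sw) == 3.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(sw=swelling_st)
    def test_monotone_and_bounded(self, sw):
        t = np.linspace(0.0, 2e5, 64)
        x = logistic_radius(t, sw)
        assert np.all(np.diff(x) >= 0)
        assert np.all((x >= sw.L - 1e-12) & (x <= sw.m * sw.L + 1e-12))

    def test_relative_growth_rate_matches_log_derivative(self):
        sw = SwellingParams(L=5.0, m=2.0, g=1.17298e-4)
        t, eps = 5000.0, 0.5
        numeric = (np.log(logistic_radius(t + eps, sw)) -
                   np.log(logistic_radius(t - eps, sw))) / (2 * eps)
        assert relative_growth_rate(t, sw) == pytest.approx(numeric, rel=1e-7)


class TestInverseSquareIntegral:
    def test_empty_interval_is_zero(self, sw):
        assert inverse_square_integral(1234.0, 1234.0, sw) == 0.0

    def test_stationary_boundary_closed_form(self):
        sw = SwellingParams(L=2.0, m=1.0, g=7e-5)
        assert inverse_square_integral(0.0, 100.0, sw) == pytest.approx(25.0, rel=1e-14)

    def test_matches_adaptive_quadrature(self):
        sw = SwellingParams(L=5.0, m=2.0, g=1.17298e-4)
        val = inverse_square_integral(0.0, 7200.0, sw)
        ref, _ = quad(lambda t: float(logistic_radius(t, sw)) ** -2, 0.0, 7200.0,
                      epsabs=1e-14, epsrel=1e-14)
        assert val == pytest.approx(ref, rel=1e-10)

    def test_reversed_interval_rejected(self, sw):
        with pytest.raises(ValueError):
            inverse_square_integral(10.0, 5.0, sw)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(sw=swelling_st, a=st.floats(0.0, 4e4), b=st.floats(0.0, 4e4))
    def test_interval_additivity(self, sw, a, b):
        a, b = min(a, b), max(a, b)
        whole = inverse_square_integral(0.0, b, sw)
        split = inverse_square_integral(0.0, a, sw) + inverse_square_integral(a, b, sw)
        assert split == pytest.approx(whole, rel=1e-12, abs=1e-18)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(sw=swelling_st, t=st.floats(10.0, 5e4))
    def test_quadrature_agreement_randomized(self, sw, t):
        val = inverse_square_integral(0.0, t, sw)
        ref, _ = quad(lambda u: float(logistic_radius(u, sw)) ** -2, 0.0, t,
                      epsabs=1e-13, epsrel=1e-13, limit=200)
        assert val == pytest.approx(ref, rel=1e-9)


class TestReleaseSeries:
    def test_zero_at_time_zero(self, sw, one_phase, two_phase):
        assert release_one_phase(0.0, sw, one_phase) == 0.0
        assert release_two_phase(0.0, sw, two_phase) == 0.0

    def test_stationary_limit_matches_plane_sheet(self):
        # classical slab: R = 1 - sum 8/((2n+1)^2 pi^2) exp(-D (2n+1)^2 pi^2 t/(4 L^2))
        sw = SwellingParams(L=1.0, m=1.0, g=0.0)
        r = release_one_phase(0.2, sw, OnePhaseParams(D=1.0))
        n = np.arange(4000)
        k = 2 * n + 1
        classical = 1.0 - np.sum(8.0 / (k * np.pi) ** 2 * np.exp(-k**2 * np.pi**2 * 0.2 / 4.0))
        assert r == pytest.approx(classical, abs=1e-13)
        assert r == pytest.approx(0.5040878, abs=1e-6)

    def test_reference_two_phase_value(self, sw, two_phase):
        # golden value cross-checked against the finite-difference oracle
        assert release_two_phase(14400.0, sw, two_phase) == pytest.approx(0.558051, abs=1e-5)

    def test_two_phase_reduces_to_one_phase_when_coefficients_equal(self, sw):
        t = np.linspace(0.0, 43200.0, 49)
        one = release_one_phase(t, sw, OnePhaseParams(D=4e-4))
        two = release_two_phase(t, sw, TwoPhaseParams(D0=4e-4, D1=4e-4, tc=7200.0))
        np.testing.assert_allclose(two, one, rtol=0, atol=1e-12)

    def test_branches_agree_at_critical_time(self, sw, two_phase):
        at_tc = release_two_phase(two_phase.tc, sw, two_phase)
        first_branch = release_one_phase(two_phase.tc, sw, OnePhaseParams(D=two_phase.D0))
        assert at_tc == pytest.approx(first_branch, rel=1e-14)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(sw=device_st, D=st.floats(1e-5, 5e-3))
    def test_bounds_and_strict_monotonicity(self, sw, D):
        t = np.linspace(0.0, 43200.0, 33)
        r = release_one_phase(t, sw, OnePhaseParams(D=D))
        assert np.all((r >= 0.0) & (r < 1.0))
        assert np.all(np.diff(r) > 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(sw=device_st, D=st.floats(1e-5, 1e-3), factor=st.floats(1.1, 10.0))
    def test_increasing_in_diffusion_coefficient(self, sw, D, factor):
        t = 14400.0
        assert (release_one_phase(t, sw, OnePhaseParams(D=D * factor))
                > release_one_phase(t, sw, OnePhaseParams(D=D)))

    def test_negative_time_rejected(self, sw, one_phase):
        with pytest.raises(ValueError):
            release_one_phase(-5.0, sw, one_phase)


class TestConcentrationProfile:
    def test_sink_boundary_is_zero(self, sw, two_phase):
        assert abs(concentration_profile(1.0, 3600.0, sw, two_phase)) < 1e-12

    def test_initial_condition_reconstructed_interior(self, sw, two_phase):
        cfg = SeriesConfig(max_terms=20000)
        c = concentration_profile(0.3, 0.0, sw, two_phase, c0=1.0, cfg=cfg)
        assert c == pytest.approx(1.0, abs=0.01)

    def test_mass_balance_against_release(self, sw, two_phase):
        # 1 - X/(L c0) * int_0^1 c dzeta must equal the direct release series
        for t in (3600.0, 14400.0):
            integral, _ = quad(lambda z: float(concentration_profile(z, t, sw, two_phase)),
                               0.0, 1.0, epsabs=1e-12, epsrel=1e-12, limit=400)
            x = float(logistic_radius(t, sw))
            via_profile = 1.0 - x / sw.L * integral
            direct = float(release_two_phase(t, sw, two_phase))
            assert via_profile == pytest.approx(direct, abs=1e-6)

    def test_zeta_out_of_range_rejected(self, sw, one_phase):
        with pytest.raises(ValueError):
            concentration_profile(1.2, 100.0, sw, one_phase)


class TestPhaseReleaseRate:
    def test_secant_convention(self):
        ts = TimeSeries(times=[0.0, 3600.0, 7200.0, 10800.0],
                        values=[0.0, 0.3, 0.5, 0.6], kind="release")
        rate1, rate2 = phase_release_rate(ts, tc=7200.0)
        assert rate1 == pytest.approx(0.5 / 7200.0)
        assert rate2 == pytest.approx(0.1 / 3600.0)

    def test_flat_second_phase_gives_zero_rate(self):
        ts = TimeSeries(times=[0.0, 3600.0, 7200.0, 10800.0],
                        values=[0.0, 0.3, 0.5, 0.5], kind="release")
        assert phase_release_rate(ts, tc=7200.0)[1] == 0.0

    def test_requires_two_points_per_phase(self):
        ts = TimeSeries(times=[0.0, 3600.0, 7200.0], values=[0.0, 0.3, 0.5], kind="release")
        with pytest.raises(ValueError):
            phase_release_rate(ts, tc=100.0)

    def test_slow_then_fast_diffusion_raises_second_phase_rate(self, sw):
        from swellrelease import generate_release_series
        p = TwoPhaseParams(D0=5e-5, D1=2e-3, tc=7200.0)
        ts = generate_release_series(sw, p)
        rate1, rate2 = phase_release_rate(ts, tc=p.tc)
        assert rate1 < rate2
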