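"""Analytic permeation models: closed forms, stationary solves, and limits."""

import math

import numpy as np
import pytest

from cngperm import kinetics as kn
from cngperm import profiles as pf
from cngperm import synthetic as sy


class TestArrhenius:
    @pytest.mark.parametrize(
        "barrier, expected",
        [(0.0, 1.0), (15.0, math.exp(-15.0)), (7.5, math.exp(-7.5))],
    )
    def test_rate(self, barrier, expected):
        assert kn.arrhenius_rate(barrier) == pytest.approx(expected, rel=1e-12)

    def test_default_rates_are_barrier_estimates(self, default_rates):
        assert default_rates.kplus == pytest.approx(math.exp(-0.5))
        assert default_rates.kminus == pytest.approx(math.exp(-1.5))
        assert default_rates.kR == pytest.approx(math.exp(-15.0))
        assert default_rates.kRtilde == pytest.approx(math.exp(-7.5))
        assert default_rates.kL == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            kn.TwoSiteRates(kR=-1.0)


class TestSingleSite:
    def test_zero_concentration(self):
        assert kn.single_site_flux(1.0, 0.5, 0.0) == 0.0

    def test_saturation(self):
        assert kn.single_site_flux(1.0, 0.5, 1e9) == pytest.approx(0.5, rel=1e-6)

    def test_half_saturation_at_kr_over_kl(self):
        kR = math.exp(-15.0)
        assert kn.single_site_flux(1.0, kR, kR) == pytest.approx(kR / 2, rel=1e-12)

    def test_absorbing_site(self):
        assert kn.single_site_flux(1.0, 0.0, 0.1) == 0.0


class TestTwoSiteStationary:
    def test_empty_at_zero_concentration(self, default_rates):
        st = kn.two_site_stationary(default_rates, 0.0)
        assert st.pE == 1.0
        assert st.flux == 0.0

    def test_closed_form_matches_linear_solve_defaults(self, default_rates):
        X = np.logspace(-6, 0, 40)
        closed = kn.two_site_flux(default_rates, X)
        solved = np.array([kn.two_site_stationary(default_rates, float(x)).flux for x in X])
        assert solved == pytest.approx(closed, rel=1e-12)

    def test_closed_form_matches_linear_solve_random_rates(self):
        rng = np.random.default_rng(42)
        X = np.logspace(-6, 0, 20)
        for _ in range(100):
            vals = np.exp(rng.uniform(-20, 0, size=5))
            rates = kn.TwoSiteRates(
                kL=vals[0], kR=vals[1], kplus=vals[2], kminus=vals[3], kRtilde=vals[4]
            )
            closed = kn.two_site_flux(rates, X)
            solved = np.array([kn.two_site_stationary(rates, float(x)).flux for x in X])
            # extreme rate ratios (up to e^20) condition the linear system badly
            assert solved == pytest.approx(closed, rel=1e-8, abs=1e-300)

    def test_balance_equations_satisfied(self, default_rates):
        for X in (1e-5, 1e-3, 1e-1):
            st = kn.two_site_stationary(default_rates, X)
            kLX = default_rates.kL * X
            r = default_rates
            assert abs(r.kR * st.pR - kLX * st.pE) < 1e-10
            assert abs(kLX * st.pE + r.kminus * st.pR + r.kRtilde * st.pD - r.kplus * st.pL) < 1e-10
            assert abs(r.kplus * st.pL - (r.kminus + r.kR + kLX) * st.pR) < 1e-10
            assert abs(kLX * st.pR - r.kRtilde * st.pD) < 1e-10
            assert st.pE + st.pL + st.pR + st.pD == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_model_raises(self):
        rates = kn.TwoSiteRates(kL=1.0, kR=0.0, kplus=0.0, kminus=0.0, kRtilde=0.0)
        with pytest.raises(ValueError, match="degenerate"):
            kn.two_site_stationary(rates, 0.1)

    def test_flux_monotone_and_bounded(self, default_rates):
        X = np.logspace(-8, 1, 200)
        J = kn.two_site_flux(default_rates, X)
        assert np.all(J >= 0)
        assert np.all(np.diff(J) >= -1e-18)
        assert np.all(J <= max(default_rates.kR, default_rates.kRtilde) + 1e-15)

    def test_flux_bounded_random_rates(self):
        """J >= 0 and J <= max(kR, k~R) for arbitrary rates; J additionally
        monotone in X whenever double occupancy does not slow the exit
        (k~R >= kR).  When k~R < kR the model genuinely predicts self-block:
        flux peaks and then falls as the second ion throttles the fast
        single-ion exit, so monotonicity is only asserted in the repulsive
        regime the defaults live in."""
        rng = np.random.default_rng(5)
        X = np.logspace(-6, 0, 15)
        for _ in range(50):
            vals = np.exp(rng.uniform(-20, 0, size=5))
            rates = kn.TwoSiteRates(
                kL=vals[0], kR=vals[1], kplus=vals[2], kminus=vals[3], kRtilde=vals[4]
            )
            J = kn.two_site_flux(rates, X)
            assert np.all(J >= 0)
            assert np.all(J <= max(rates.kR, rates.kRtilde) * (1 + 1e-12))
            if rates.kRtilde >= rates.kR:
                assert np.all(np.diff(J) >= -1e-9 * np.abs(J[:-1]) - 1e-300)


class TestKrNeglectedLimit:
    def test_limit_recovers_closed_form_as_kr_shrinks(self, default_rates):
        X = np.logspace(-5, -1, 30)
        prev = None
        for log_kr in (-15.0, -18.0, -21.0, -24.0):
            rates = default_rates.replace(kR=math.exp(log_kr))
            dev = np.max(
                np.abs(kn.two_site_flux(rates, X) - kn.two_site_flux_limit(rates, X))
                / kn.two_site_flux(rates, X)
            )
            if prev is not None:
                assert dev < prev
            prev = dev
        assert prev < 1e-5

    def test_asymptote(self, default_rates):
        r = default_rates
        expected = r.kplus * r.kRtilde / (r.kplus + r.kRtilde)
        assert kn.two_site_flux_limit(r, 1e9) == pytest.approx(expected, rel=1e-6)

    def test_michaelis_menten_functional_form(self, default_rates):
        """The limit is exactly of MM form: a X/(b X + 1) reproduces it."""
        X = np.logspace(-6, 0, 30)
        J = kn.two_site_flux_limit(default_rates, X)
        jmax = default_rates.kplus * default_rates.kRtilde / (
            default_rates.kplus + default_rates.kRtilde
        )
        xh = kn.half_activation(default_rates)
        assert J == pytest.approx(jmax * X / (X + xh), rel=1e-12)


class TestHalfActivation:
    def test_default_rates_value(self, default_rates):
        assert kn.half_activation(default_rates) == pytest.approx(7.5586e-4, abs=1e-6)

    def test_defining_property(self, default_rates):
        xh = kn.half_activation(default_rates)
        jmax = kn.two_site_flux_limit(default_rates, 1e12)
        assert kn.two_site_flux_limit(default_rates, xh) == pytest.approx(jmax / 2, rel=1e-6)

    def test_fast_double_exit_limit(self, default_rates):
        r = default_rates.replace(kRtilde=1e9)
        expected = (r.kminus + r.kplus) / r.kL
        assert kn.half_activation(r) == pytest.approx(expected, rel=1e-6)

    def test_one_site_half_activation_is_kd(self):
        """In the single-site model X1/2 = kR/kL exactly."""
        kL, kR = 2.0, math.exp(-15.0)
        xh = kR / kL
        jmax = kR
        assert kn.single_site_flux(kL, kR, xh) == pytest.approx(jmax / 2, rel=1e-12)

    def test_domain_errors(self, default_rates):
        with pytest.raises(ValueError):
            kn.half_activation(default_rates.replace(kL=0.0))
        with pytest.raises(ValueError):
            kn.half_activation(default_rates.replace(kRtilde=0.0))


class TestOccupancyRatio:
    def test_exit_enhancement(self, default_rates):
        rep = kn.occupancy_ratio_check(default_rates)
        assert rep.exit_enhancement == pytest.approx(math.exp(7.5), rel=1e-12)
        assert rep.exit_enhancement == pytest.approx(1808, rel=1e-3)

    def test_half_activation_vs_one_site_kd(self, default_rates):
        rep = kn.occupancy_ratio_check(default_rates)
        assert rep.x_half_over_kd == pytest.approx(2.47e3, rel=1e-2)

    def test_no_repulsion_limit(self, default_rates):
        r = default_rates.replace(kRtilde=default_rates.kR)
        rep = kn.occupancy_ratio_check(r)
        expected = (r.kminus + r.kplus) / (r.kplus + r.kR)
        assert rep.x_half_over_kd == pytest.approx(expected, rel=1e-12)


class TestRatesFromProfiles:
    def test_default_profile_pair(self, single_profile, double_profile):
        minima = pf.find_minima(single_profile, 1.0, labels=sy.DEFAULT_SINGLE_LABELS)
        s3, s4 = minima[0], minima[1]
        rates = kn.rates_from_profiles(single_profile, double_profile, site_L=s4, site_R=s3)
        # the two-ion well is 25 kJ/mol shallower, so the exit rate rises by
        # exp(25/kT); oracle is direct barrier subtraction
        d_single = pf.barrier_height(single_profile, s3, "increasing")
        d_double = pf.barrier_height(
            double_profile, pf.global_minimum(double_profile), "increasing"
        )
        expected = math.exp((d_single - d_double) / single_profile.kT)
        assert rates.kRtilde / rates.kR == pytest.approx(expected, rel=1e-9)
        assert d_single - d_double == pytest.approx(25.0, abs=0.2)

    def test_identical_profiles_give_equal_exit_rates(self, single_profile):
        minima = pf.find_minima(single_profile, 1.0)
        rates = kn.rates_from_profiles(
            single_profile, single_profile, site_L=minima[1], site_R=minima[0]
        )
        assert rates.kRtilde == pytest.approx(rates.kR, rel=1e-12)

    def test_detailed_balance_identity(self, single_profile, double_profile):
        minima = pf.find_minima(single_profile, 1.0)
        s3, s4 = minima[0], minima[1]
        rates = kn.rates_from_profiles(single_profile, double_profile, site_L=s4, site_R=s3)
        dG = s4.G_min - s3.G_min
        assert rates.kplus / rates.kminus == pytest.approx(
            math.exp(dG / single_profile.kT), rel=1e-12
        )

    def test_missing_minimum_rejected(self, single_profile, double_profile):
        bad = pf.Minimum("x", z_min=99.0, G_min=0.0, depth=0, prominence=0, index=-1)
        with pytest.raises(ValueError):
            kn.rates_from_profiles(single_profile, double_profile, bad, bad)
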