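"""Exponential, mechanism, isotherm and drift fits: exactness, rules, recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from facdis import (
    IdentifiabilityError,
    KappProfile,
    ValidationError,
    bound_fraction,
    discriminate_mechanism,
    fit_baseline_drift,
    fit_competition_timecourse,
    fit_double_exponential,
    fit_isotherm,
    fit_kapp_hyperbolic,
    fit_kapp_linear,
    fit_single_exponential,
    generate_fp_titration,
    generate_kapp_profile,
    polarization,
    subtract_drift,
)
from facdis.synthetic import NoiseSpec


class TestSingleExponential:
    def test_exact_decay_recovery(self):
        t = np.linspace(0.0, 200.0, 60)
        s = 2.0 + 3.0 * np.exp(-0.05 * t)
        r = fit_single_exponential(t, s, mode="decay")
        assert r.s0 == pytest.approx(2.0, abs=1e-9)
        assert r.s1 == pytest.approx(3.0, abs=1e-9)
        assert r.k1 == pytest.approx(0.05, rel=1e-9)

    def test_exact_rise_recovery(self):
        t = np.linspace(0.0, 500.0, 80)
        s = 10.0 + 40.0 * (1.0 - np.exp(-0.01 * t))
        r = fit_single_exponential(t, s, mode="rise")
        assert r.k1 == pytest.approx(0.01, rel=1e-9)
        assert r.s1 == pytest.approx(40.0, rel=1e-9)

    def test_constant_signal_flagged(self):
        t = np.linspace(0, 10, 10)
        r = fit_single_exponential(t, np.full_like(t, 5.0))
        assert r.s1 == 0.0
        assert any("unidentifiable" in f for f in r.flags)

    def test_noisy_rise_recovery_median(self):
        """2% noise, 20 seeds: median recovered rate within 5%."""
        t = np.linspace(0.0, 600.0, 120)
        clean = 5.0 + 20.0 * (1.0 - np.exp(-0.01 * t))
        ks = []
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            s = clean + rng.normal(0, 0.02 * clean.max(), t.shape)
            ks.append(fit_single_exponential(t, s, mode="rise").k1)
        assert abs(np.median(ks) / 0.01 - 1.0) < 0.05

    def test_non_finite_rejected(self):
        t = np.linspace(0, 10, 6)
        s = np.array([1.0, 2.0, np.nan, 1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            fit_single_exponential(t, s)


class TestDoubleExponential:
    T = np.arange(0.0, 601.0, 1.0)  # 1 s sampling resolves the fast phase

    def test_reporting_rule_fast_high_amplitude(self):
        s = 1.0 + 0.7 * np.exp(-0.1 * self.T) + 0.3 * np.exp(-0.001 * self.T)
        r = fit_double_exponential(self.T, s)
        assert r.n_components == 2
        assert r.k1 >= r.k2
        assert r.reported_k == pytest.approx(0.1, rel=1e-6)

    def test_collapse_on_single_population(self):
        s = 2.0 + 3.0 * np.exp(-0.05 * self.T)
        r = fit_double_exponential(self.T, s)
        assert r.n_components == 1
        assert r.reported_k == pytest.approx(0.05, rel=1e-6)

    def test_low_amplitude_fast_component_conflict(self):
        """Faster component below 25% of total amplitude: slower rate reported."""
        s = 1.0 + 0.1 * np.exp(-0.1 * self.T) + 0.9 * np.exp(-0.002 * self.T)
        r = fit_double_exponential(self.T, s)
        assert r.n_components == 2
        assert r.reported_k == pytest.approx(0.002, rel=1e-3)
        assert any("conflict" in f for f in r.flags)

    def test_noisy_fast_rate_recovery(self):
        """1% noise: reported rate within 10% of the fast truth in >=95/100."""
        clean = 1.0 + 0.7 * np.exp(-0.1 * self.T) + 0.3 * np.exp(-0.001 * self.T)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(7000 + seed)
            s = clean + rng.normal(0, 0.01 * clean.max(), self.T.shape)
            r = fit_double_exponential(self.T, s)
            hits += abs(r.reported_k / 0.1 - 1.0) < 0.1
        assert hits >= 95


class TestKappFits:
    def test_linear_exact(self):
        c = np.array([1e-7, 3e-7, 1e-6, 3e-6])
        profile = KappProfile(c, 5e4 * c + 1e-3)
        fit = fit_kapp_linear(profile)
        assert fit.k_on == pytest.approx(5e4, rel=1e-9)
        assert fit.k_off_intercept == pytest.approx(1e-3, rel=1e-9)

    def test_linear_degenerate_design(self):
        with pytest.raises(IdentifiabilityError):
            fit_kapp_linear(KappProfile(np.full(5, 1e-6), np.ones(5)))

    def test_hyperbolic_exact(self):
        c = 16 * 2e-7 / 2.0 ** np.arange(8)
        k = (0.02 - 1e-4) * c / (2e-7 + c) + 1e-4
        fit = fit_kapp_hyperbolic(KappProfile(c, k))
        assert fit.k_switch == pytest.approx(0.02, rel=1e-6)
        assert fit.k_base == pytest.approx(1e-4, rel=1e-6)
        assert fit.k_half == pytest.approx(2e-7, rel=1e-6)

    def test_hyperbolic_zero_conc_intercept_and_saturation(self):
        c = np.concatenate([[0.0], 16 * 2e-7 / 2.0 ** np.arange(8)])
        k = (0.02 - 1e-4) * c / (2e-7 + c) + 1e-4
        fit = fit_kapp_hyperbolic(KappProfile(c, k))
        # fitted curve at [C]=0 is exactly k_base; at 100*K_half within 1% of k_switch
        assert fit.k_base == pytest.approx(1e-4, rel=1e-6)
        c_sat = 100 * fit.k_half
        k_sat = (fit.k_switch - fit.k_base) * c_sat / (fit.k_half + c_sat) + fit.k_base
        assert abs(k_sat / fit.k_switch - 1.0) < 0.01

    def test_discrimination_selects_generating_model(self):
        lin, _ = generate_kapp_profile("induced_fit", noise=NoiseSpec(sd=0.05, seed=5))
        hyp, _ = generate_kapp_profile("conformational_selection", noise=NoiseSpec(sd=0.05, seed=5))
        assert discriminate_mechanism(lin).model == "linear"
        assert discriminate_mechanism(hyp).model == "hyperbolic"

    def test_discrimination_guard_small_profile(self):
        with pytest.raises(IdentifiabilityError):
            discriminate_mechanism(KappProfile(np.array([1e-7, 1e-6]), np.array([1e-3, 2e-3])))

    def test_aic_selection_invariant_to_unit_rescaling(self):
        profile, _ = generate_kapp_profile("induced_fit", noise=NoiseSpec(sd=0.05, seed=9))
        base = discriminate_mechanism(profile)
        scaled = KappProfile(profile.concs, profile.kapps * 1000.0)  # s^-1 -> ms^-1
        res = discriminate_mechanism(scaled)
        assert res.model == base.model
        assert (res.aic_linear - res.aic_hyperbolic) == pytest.approx(
            base.aic_linear - base.aic_hyperbolic, abs=1e-6
        )


class TestPolarization:
    @pytest.mark.parametrize(
        "par, perp, expected",
        [(1.0, 1.0, 0.0), (7.5, 0.0, 1000.0), (2.0, 1.0, 1000.0 / 3.0)],
    )
    def test_printed_formula(self, par, perp, expected):
        assert polarization(par, perp) == pytest.approx(expected, rel=1e-12)

    def test_zero_intensity_signaled(self):
        with pytest.raises(ValidationError):
            polarization(0.0, 0.0)


class TestBoundFraction:
    def test_limits(self):
        assert bound_fraction(0.0, 1e-9, 1e-8) == 0.0
        # stoichiometric limit: vanishing K_D with host >= effector saturates
        assert bound_fraction(1e-8, 1e-9, 1e-18) == pytest.approx(1.0, abs=1e-8)

    def test_symmetric_point_closed_form(self):
        """[A] = [C] = K_D = K gives f = (3 - sqrt(5))/2 exactly."""
        expected = (3.0 - math.sqrt(5.0)) / 2.0
        for K in (1e-10, 1e-7, 1e-3):
            assert bound_fraction(K, K, K) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_numeric_equilibrium(self):
        """Cross-check against a numeric solve of the mass balance."""
        from scipy.optimize import brentq

        a_tot, c_tot, kd = 3e-9, 1e-9, 7e-9
        f_num = brentq(
            lambda f: (a_tot - f * c_tot) * (1 - f) - kd * f, 0.0, 1.0, xtol=1e-15
        )
        assert bound_fraction(a_tot, c_tot, kd) == pytest.approx(f_num, rel=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.0, 1e-5), c=st.floats(1e-12, 1e-5), kd=st.floats(0.0, 1e-4),
        da=st.floats(1e-12, 1e-6), dk=st.floats(1e-12, 1e-6),
    )
    def test_monotonicity_and_bounds(self, a, c, kd, da, dk):
        f = bound_fraction(a, c, kd)
        assert 0.0 <= f <= 1.0
        assert bound_fraction(a + da, c, kd) >= f - 1e-12
        assert bound_fraction(a, c, kd + dk) <= f + 1e-12


class TestIsotherm:
    def test_exact_recovery_uncensored(self):
        table, _ = generate_fp_titration(
            p0=50.0, p1=150.0, kd=1e-8, effector_conc=1e-10, noise=NoiseSpec(sd=0.0, seed=0)
        )
        fit = fit_isotherm(table.host_conc_M, table.polarization_mP, 1e-10)
        assert not fit.censored
        assert fit.p0 == pytest.approx(50.0, rel=1e-6)
        assert fit.p1 == pytest.approx(150.0, rel=1e-6)
        assert fit.kd == pytest.approx(1e-8, rel=1e-6)

    def test_censoring_rule_fires(self):
        """K_D well below [C] is reported as the upper bound K_D < [C]."""
        table, _ = generate_fp_titration(
            kd=1e-10, effector_conc=1e-9, noise=NoiseSpec(sd=0.0, seed=0)
        )
        fit = fit_isotherm(table.host_conc_M, table.polarization_mP, 1e-9)
        assert fit.censored
        assert fit.kd == 1e-9
        assert fit.kd_fit < 1e-9

    def test_flat_titration_flagged(self):
        a = 2e-6 / 2.0 ** np.arange(8)
        fit = fit_isotherm(a, np.full(8, 120.0), 1e-9)
        assert any("unidentifiable" in f for f in fit.flags)

    def test_noisy_recovery_median(self):
        """24-well 2-fold design, 2% noise: median K_D within 15% for K_D > 5[C]."""
        kds = []
        for seed in range(20):
            table, _ = generate_fp_titration(
                kd=1e-8, effector_conc=1e-9, noise=NoiseSpec(sd=0.02, seed=400 + seed)
            )
            kds.append(fit_isotherm(table.host_conc_M, table.polarization_mP, 1e-9).kd)
        assert abs(np.median(kds) / 1e-8 - 1.0) < 0.15


class TestCompetitionAndDrift:
    def test_competition_is_rise_fit(self):
        t = np.linspace(0.0, 900.0, 90)
        p = 60.0 + 140.0 * (1.0 - np.exp(-0.005 * t))
        r = fit_competition_timecourse(t, p)
        assert r.k1 == pytest.approx(0.005, rel=1e-9)

    def test_drift_exact_recovery(self):
        t = np.linspace(0.0, 1000.0, 101)
        s = 1.0 + 0.2 / (1.0 + np.exp(-0.01 * (t - 300.0)))
        d = fit_baseline_drift(t, s)
        assert d.s0 == pytest.approx(1.0, abs=1e-9)
        assert d.s1 == pytest.approx(0.2, abs=1e-9)
        assert d.k == pytest.approx(0.01, rel=1e-8)
        assert d.t_half == pytest.approx(300.0, rel=1e-8)

    def test_drift_flat_flagged(self):
        t = np.linspace(0, 100, 11)
        d = fit_baseline_drift(t, np.full_like(t, 3.0))
        assert d.s1 == 0.0
        assert any("flat" in f for f in d.flags)

    def test_subtracting_drift_recovers_decay_rate(self):
        """Drift-contaminated decay: subtraction restores the rate within 5%."""
        t = np.linspace(0.0, 1200.0, 241)
        drift_truth = 0.5 / (1.0 + np.exp(-0.004 * (t - 600.0)))
        decay = 1.0 + 4.0 * np.exp(-0.01 * t)
        rng = np.random.default_rng(17)
        drift_obs = drift_truth + rng.normal(0, 0.002, t.shape)
        d = fit_baseline_drift(t, drift_obs)
        corrected = subtract_drift(t, decay + drift_truth, d)
        r = fit_single_exponential(t, corrected, mode="decay")
        assert abs(r.k1 / 0.01 - 1.0) < 0.05
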