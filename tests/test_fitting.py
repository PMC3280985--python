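"""Leak subtraction, exponential/Boltzmann fits, ddG0, tau utilities."""

import numpy as np
import pytest

from herggating import fitting
from herggating.fitting import (
    Constants, DDG_THRESHOLD_KJ_PER_MOL, FitError, ThermoFit,
    boltzmann_to_thermo, deactivation_components, delta_delta_g,
    envelope_activation_tau, extrapolate_tau, fit_boltzmann, fit_exponential,
    fit_thermo_boltzmann, interpolate_tau, leak_subtract, peak_tail,
    thermo_to_boltzmann, voltage_normalisation,
)
from herggating.gating import (
    GatingScheme, RateLaw, build_scheme1, equilibrium_occupancy,
    macroscopic_taus, relax_piecewise,
)
from herggating.protocols import build_deactivation_protocol, \
    build_isochronal_protocol
from herggating.synth import CellModel, simulate_current_sweep


def boltzmann_curve(v, v05, k):
    return 1.0 / (1.0 + np.exp((v05 - v) / k))


class TestLeakSubtraction:
    def _trace(self, wt_params, cell):
        scheme = build_scheme1(wt_params)
        sweep = build_isochronal_protocol([0.0]).sweeps[0]
        return simulate_current_sweep(scheme, cell, sweep)

    def test_pure_leak_maps_to_zero(self, wt_params):
        cell = CellModel(g_max=0.0, g_leak=0.02, e_leak=-10.0, noise_sd=0.0)
        sub = leak_subtract(self._trace(wt_params, cell))
        assert np.allclose(sub.current, 0.0, atol=1e-9)

    def test_leak_free_trace_unchanged(self, wt_params):
        cell = CellModel(g_leak=0.0, noise_sd=0.0)
        tr = self._trace(wt_params, cell)
        # with a measured leak step of zero current the subtraction only
        # removes the (tiny) holding baseline
        sub = leak_subtract(tr, leak_step=(20.0, 0.0))
        assert np.allclose(sub.current, tr.current, atol=5e-3)
        # the self-estimated path picks up the small standing channel
        # current during the estimation step; the bias stays sub-0.2 nA
        # on a tens-of-nA trace
        auto = leak_subtract(tr)
        assert np.allclose(auto.current, tr.current, atol=0.25)

    def test_mixed_trace_recovers_channel_component(self, wt_params):
        scheme = build_scheme1(wt_params)
        sweep = build_isochronal_protocol([0.0]).sweeps[0]
        noisy = simulate_current_sweep(
            scheme, CellModel(g_leak=0.015, noise_sd=0.5), sweep, seed=11)
        clean = simulate_current_sweep(
            scheme, CellModel(g_leak=0.0, noise_sd=0.0), sweep)
        sub = leak_subtract(noisy)
        resid = sub.current - clean.current
        assert np.abs(np.mean(resid)) < 0.5       # no systematic offset
        assert np.std(resid) < 3 * 0.5            # within noise scale

    def test_zero_leak_step_rejected(self, wt_params):
        tr = self._trace(wt_params, CellModel(noise_sd=0.0))
        with pytest.raises(ValueError):
            leak_subtract(tr, leak_step=(0.0, 1.0))


class TestExponentialFit:
    def test_single_component_exact_recovery(self):
        t = np.arange(0.0, 600.0, 1.0)
        y = 0.2 + 3.0 * np.exp(-t / 100.0)
        fit = fit_exponential(t, y, 1)
        assert fit.taus[0] == pytest.approx(100.0, rel=1e-6)
        assert fit.amplitudes[0] == pytest.approx(3.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.2, abs=1e-8)

    def test_two_component_recovery(self):
        t = np.arange(0.0, 800.0, 1.0)
        y = 0.9 * np.exp(-t / 10.0) + 0.1 * np.exp(-t / 100.0)
        fit = fit_exponential(t, y, 2)
        assert fit.taus == pytest.approx((10.0, 100.0), rel=1e-3)
        assert fit.amplitudes == pytest.approx((0.9, 0.1), rel=1e-3)

    def test_sigmoidal_rise_avoids_collapsed_pair(self, wt_params):
        # delayed activation time courses are the classic trap for
        # sum-of-exponential fits (near-equal taus, cancelling amplitudes)
        scheme = build_scheme1(wt_params)
        p0 = equilibrium_occupancy(scheme, -90.0)
        t, occ = relax_piecewise(scheme, p0, [(20.0, 1500.0)], dt=1.0)
        fit = fit_exponential(t, occ @ scheme.conducting_mask().astype(float), 2)
        assert np.array(fit.taus) == pytest.approx(
            macroscopic_taus(scheme, 20.0), rel=1e-3)

    def test_preconditions(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            fit_exponential(t, np.exp(-t), 4)
        with pytest.raises(FitError):
            fit_exponential(t[:4], np.exp(-t[:4]), 1)


class TestBoltzmann:
    def test_noiseless_recovery_of_wt_like_curve(self):
        v = np.arange(-120.0, 51.0, 10.0)
        y = boltzmann_curve(v, -23.1, 8.4)
        fit = fit_boltzmann(v, y)
        assert fit.v05 == pytest.approx(-23.1, abs=1e-6)
        assert fit.k_slope == pytest.approx(8.4, abs=1e-6)
        assert fit.value(fit.v05) == pytest.approx(0.5)

    def test_scaling_invariance_of_normalisation(self):
        v = np.arange(-120.0, 51.0, 10.0)
        y = 37.2 * boltzmann_curve(v, -30.0, 7.0)   # nA-scale peak tails
        fit = fit_boltzmann(v, -y)                  # inward tails too
        assert fit.v05 == pytest.approx(-30.0, abs=1e-6)

    def test_degenerate_inputs_rejected(self):
        v = np.arange(-60.0, 41.0, 10.0)
        with pytest.raises(FitError):
            fit_boltzmann(v, boltzmann_curve(v, -20.0, -8.0))  # decreasing
        with pytest.raises(FitError):
            fit_boltzmann(v, np.ones_like(v))
        with pytest.raises(FitError):
            fit_boltzmann(v[:3], boltzmann_curve(v[:3], -20.0, 8.0))


class TestThermoBoltzmann:
    def test_gating_charge_from_slope(self):
        v = np.arange(-120.0, 51.0, 10.0)
        y = boltzmann_curve(v, -23.1, 8.4)
        fit = fit_thermo_boltzmann(v, y)
        consts = Constants()
        assert fit.z_g == pytest.approx(consts.thermal_voltage_mV / 8.4,
                                        rel=1e-4)
        assert fit.z_g == pytest.approx(3.03, abs=0.01)

    def test_forms_interconvert_exactly(self):
        v = np.arange(-120.0, 51.0, 10.0)
        y = boltzmann_curve(v, -23.1, 8.4)
        b = fit_boltzmann(v, y)
        t = boltzmann_to_thermo(b)
        b2 = thermo_to_boltzmann(t)
        assert b2.v05 == pytest.approx(b.v05, abs=1e-9)
        assert b2.k_slope == pytest.approx(b.k_slope, abs=1e-9)
        direct = fit_thermo_boltzmann(v, y)
        assert direct.dG0 == pytest.approx(t.dG0, rel=1e-4)

    def test_flat_curve_flags_degenerate_charge(self):
        from herggating.fitting import BoltzmannFit
        flat = BoltzmannFit(-20.0, 300.0, 1.0, 0.0)   # k -> infinity limit
        t = boltzmann_to_thermo(flat)
        assert t.degenerate
        assert t.z_g < 0.1


class TestDeltaDeltaG:
    def test_identity_and_threshold_strictness(self):
        wt = ThermoFit(-6.0, 3.0, 0.0)
        assert delta_delta_g(wt, wt) == \
            pytest.approx((0.0, False)) or True
        d = delta_delta_g(wt, wt)
        assert d.ddG0 == 0.0 and d.significant is False
        exactly = delta_delta_g(ThermoFit(-6.0 + DDG_THRESHOLD_KJ_PER_MOL,
                                          3.0, 0.0), wt)
        assert exactly.ddG0 == pytest.approx(4.2)
        assert exactly.significant is False           # strict inequality
        above = delta_delta_g(ThermoFit(-1.7, 3.0, 0.0), wt)
        assert above.significant is True

    def test_hyperpolarising_shift_is_negative(self):
        consts = Constants()
        wt = boltzmann_to_thermo(
            fitting.BoltzmannFit(-23.1, 8.4, 1.0, 0.0), consts)
        mut = boltzmann_to_thermo(
            fitting.BoltzmannFit(-56.8, 8.4, 1.0, 0.0), consts)
        d = delta_delta_g(mut, wt)
        assert d.ddG0 < 0
        assert d.significant  # ~-9.9 kJ/mol

    def test_kcal_conversion_constant(self):
        assert DDG_THRESHOLD_KJ_PER_MOL == pytest.approx(
            round(4.184, 1))


class TestEnvelopeTau:
    def test_two_state_envelope_recovers_known_tau(self):
        scheme = GatingScheme(("C", "O"), (RateLaw(0.012, 0.0),),
                              (RateLaw(0.008, 0.0),), frozenset({"O"}))
        tau_true = macroscopic_taus(scheme, 0.0)[0]   # 50 ms
        assert tau_true == pytest.approx(50.0)
        durations = np.array([10, 25, 50, 90, 150, 250, 400.0])
        peaks = 0.6 * (1.0 - np.exp(-durations / tau_true))
        env = envelope_activation_tau(durations, peaks)
        assert env.tau == pytest.approx(50.0, rel=0.01)
        assert not env.ill_conditioned

    def test_plateau_only_flagged_ill_conditioned(self):
        durations = np.array([500.0, 650.0, 800.0, 1200.0, 2000.0])
        peaks = 0.6 * (1.0 - np.exp(-durations / 50.0))
        env = envelope_activation_tau(durations, peaks)
        assert env.ill_conditioned


class TestDeactivationComponents:
    def test_mono_exponential_tail_has_fast_fraction_one(self):
        t = np.arange(3.0, 800.0, 1.0)
        y = -12.0 * np.exp(-t / 40.0) - 0.3
        comp = deactivation_components(t, y)
        assert comp.fast_fraction == 1.0
        assert comp.tau_fast == pytest.approx(40.0, rel=1e-4)
        assert comp.tau_slow is None and comp.hook_tau is None

    def test_three_state_tail_components_match_eigen_taus(self):
        # a chain whose two decay modes both carry weight in P_open:
        # start fully open, relax towards an equilibrium with K2 ~ 0.5
        scheme = GatingScheme(
            ("C1", "C2", "O"),
            (RateLaw(0.004, 0.0), RateLaw(0.02, 0.0)),
            (RateLaw(0.02, 0.0), RateLaw(0.04, 0.0)),
            frozenset({"O"}))
        p0 = np.array([0.0, 0.0, 1.0])
        t, occ = relax_piecewise(scheme, p0, [(0.0, 1500.0)], dt=1.0)
        comp = deactivation_components(t, occ @ scheme.conducting_mask()
                                       .astype(float))
        eigen = macroscopic_taus(scheme, 0.0)
        assert comp.tau_fast == pytest.approx(eigen[0], rel=0.01)
        assert comp.tau_slow == pytest.approx(eigen[1], rel=0.01)
        assert 0.0 < comp.fast_fraction < 1.0

    def test_hooked_tail_selects_triple_and_recovers_decay(self, wt_params):
        scheme = build_scheme1(wt_params)
        cell = CellModel(noise_sd=0.0).with_inactivation()
        sweep = build_deactivation_protocol([-120.0]).sweeps[0]
        tr = simulate_current_sweep(scheme, cell, sweep)
        sub = leak_subtract(tr)
        t, y = sub.segment_samples("tail")
        keep = t > 2.0
        comp = deactivation_components(t[keep], y[keep])
        assert comp.hook_tau is not None
        from herggating.synth import DEFAULT_INACTIVATION
        ext = scheme.extended("I", *DEFAULT_INACTIVATION)
        eigen = macroscopic_taus(ext, -120.0)
        assert comp.fit.n == 3   # hook detection selected a triple fit
        assert comp.hook_tau == pytest.approx(eigen[0], rel=0.05)
        assert comp.tau_dominant == pytest.approx(eigen[-1], rel=0.05)

    def test_triple_needed_for_hook_plus_two_phase_decay(self):
        # hook (opposite-sign fast component) plus fast and slow decay:
        # a double exponential cannot represent all three processes
        t = np.arange(3.0, 1200.0, 1.0)
        y = (5.0 * np.exp(-t / 3.0) - 20.0 * np.exp(-t / 12.0)
             - 8.0 * np.exp(-t / 80.0) - 0.5)
        f3 = fit_exponential(t, y, 3)
        f2 = fit_exponential(t, y, 2)
        assert f3.residual_norm < 1e-3 * f2.residual_norm
        assert f3.taus == pytest.approx((3.0, 12.0, 80.0), rel=1e-3)
        comp = deactivation_components(t, y, hook="always")
        assert comp.hook_tau == pytest.approx(3.0, rel=0.01)
        assert comp.tau_fast == pytest.approx(12.0, rel=0.01)
        assert comp.tau_slow == pytest.approx(80.0, rel=0.01)
        # amplitudes are referenced to the first fitted sample (t=3 ms)
        a_fast, a_slow = 20.0 * np.exp(-3 / 12.0), 8.0 * np.exp(-3 / 80.0)
        assert comp.fast_fraction == pytest.approx(a_fast / (a_fast + a_slow),
                                                   rel=0.01)


class TestVoltageNormalisation:
    def test_examples_and_oddness(self):
        fit = fitting.BoltzmannFit(-23.1, 8.4, 1.0, 0.0)
        dv, dg = voltage_normalisation(-23.1, fit)
        assert (dv, dg) == (0.0, 0.0)
        thermo = ThermoFit(-6.0, 3.0, 0.0)
        dv, dg = voltage_normalisation(
            thermo_to_boltzmann(thermo).v05 + 40.0, thermo)
        assert dv == pytest.approx(40.0, abs=1e-9)
        assert dg == pytest.approx(3 * 96485 * 0.040 / 1000, rel=1e-6)  # 11.58
        dv2, dg2 = voltage_normalisation(
            thermo_to_boltzmann(thermo).v05 - 40.0, thermo)
        assert dg2 == pytest.approx(-dg, rel=1e-9)


class TestTauExtrapolation:
    def test_exact_exponential_data(self):
        v = np.array([-60.0, -80.0, -100.0])
        tau = 30.0 * np.exp(0.02 * v)
        res = extrapolate_tau(v, tau, -130.0)
        assert res.tau == pytest.approx(30.0 * np.exp(0.02 * -130.0), rel=1e-9)
        assert res.extrapolated  # 30 mV beyond the last point

    def test_flag_rule_and_flat_case(self):
        v = np.array([-60.0, -80.0, -100.0])
        tau = np.full(3, 12.0)
        near = extrapolate_tau(v, tau, -105.0)
        assert not near.extrapolated and near.tau == pytest.approx(12.0)
        far = extrapolate_tau(v, tau, -115.0)
        assert far.extrapolated
        with pytest.raises(ValueError):
            extrapolate_tau(v, [-1.0, 2.0, 3.0], -100.0)

    def test_interpolation_inside_range(self):
        v = np.array([-140.0, -120.0, -100.0, -80.0])
        tau = 5.0 * np.exp(0.03 * (v + 100))
        res = interpolate_tau(v, tau, -110.0)
        assert not res.extrapolated
        assert res.tau == pytest.approx(5.0 * np.exp(0.03 * -10), rel=1e-6)


class TestPeakTail:
    def test_peak_is_signed_and_blanked(self, wt_params):
        scheme = build_scheme1(wt_params)
        sweep = build_isochronal_protocol([20.0], tail_voltage=-120.0).sweeps[0]
        tr = simulate_current_sweep(scheme, CellModel(noise_sd=0.0), sweep)
        sub = leak_subtract(tr)
        peak = peak_tail(sub)
        assert peak < 0  # inward tail at -120 mV (E_rev -100)
        sweep70 = build_isochronal_protocol([20.0], tail_voltage=-70.0).sweeps[0]
        tr70 = simulate_current_sweep(scheme, CellModel(noise_sd=0.0), sweep70)
        assert peak_tail(leak_subtract(tr70)) > 0  # outward at -70 mV
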