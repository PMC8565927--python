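"""Analytic cable constants and the compartmental solver."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from stellate.cable import (
    IntegrationError,
    PassiveProperties,
    SynapseSpec,
    Trace,
    biexp_conductance,
    biexp_half_width,
    biexp_peak,
    biexp_peak_time,
    compartmentalize,
    input_resistance,
    lambda_ac,
    lambda_dc,
    membrane_time_constant,
    simulate_current_clamp,
    simulate_voltage_clamp,
)
from stellate.morphology import build_idealized_sc


class TestAnalyticConstants:
    @pytest.mark.parametrize("Ri,expected", [(100.0, 485), (200.0, 343)])
    def test_lambda_dc_stellate_values(self, Ri, expected):
        assert round(lambda_dc(0.47, 20000.0, Ri)) == expected

    def test_lambda_dc_sqrt_scaling(self):
        assert lambda_dc(4 * 0.47, 20000, 150) == pytest.approx(
            2 * lambda_dc(0.47, 20000, 150)
        )

    def test_lambda_ac_simplified_1khz(self):
        assert round(lambda_ac(0.47, 20000, 200, 0.9, 1000, simplified=True)) == 46

    def test_lambda_ac_low_frequency_limit(self):
        full = lambda_ac(0.47, 20000, 150, 0.9, 1e-6)
        assert full == pytest.approx(lambda_dc(0.47, 20000, 150), rel=1e-6)

    def test_lambda_ac_full_form_1khz(self):
        # direct evaluation of the full expression at the default Ri
        assert lambda_ac(0.47, 20000, 150, 0.9, 1000) == pytest.approx(
            52.40, abs=0.05
        )

    @pytest.mark.parametrize("Cm,expected", [(0.9, 18.0), (0.85, 17.0)])
    def test_membrane_time_constant(self, Cm, expected):
        assert membrane_time_constant(20000, Cm) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            lambda_dc(-1, 20000, 150)
        with pytest.raises(ValueError):
            lambda_ac(0.47, 20000, 150, 0.9, 0)


class TestBiexpConductance:
    def test_zero_at_onset_and_before(self, immature_synapse):
        s = immature_synapse
        assert biexp_conductance(s.onset, s) == 0.0
        assert biexp_conductance(s.onset - 0.5, s) == 0.0

    def test_immature_peak(self, immature_synapse):
        assert biexp_peak(immature_synapse) == pytest.approx(0.00175, abs=5e-6)
        assert biexp_peak_time(immature_synapse) == pytest.approx(0.1289, abs=1e-4)

    def test_adult_peak_within_one_percent(self, adult_synapse):
        assert biexp_peak(adult_synapse) == pytest.approx(0.00133, rel=0.01)

    def test_half_widths(self, immature_synapse, adult_synapse):
        assert biexp_half_width(immature_synapse) == pytest.approx(0.36, abs=0.005)
        assert biexp_half_width(adult_synapse) == pytest.approx(0.341, rel=0.005)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            SynapseSpec(tau0=0.3, tau1=0.2, gmax=1.0)


class TestCompartmentalize:
    def test_axial_resistance_closed_form(self, idealized_model):
        # 0.47 µm cylinder, 1 µm long, Ri 150 -> 4*Ri*dx/(pi d^2) = 8.65 MΩ
        g = idealized_model.g_axial[2]
        assert 1.0 / g == pytest.approx(8.6458, rel=1e-3)

    def test_soma_sphere_area(self, idealized_model):
        assert idealized_model.area[0] * 1e8 == pytest.approx(
            math.pi * 8.0 ** 2, rel=1e-9
        )

    def test_total_dendritic_area(self, idealized_model):
        lateral = math.pi * 0.47e-4 * 90e-4
        assert idealized_model.area[1:].sum() == pytest.approx(lateral, rel=1e-3)

    def test_compartment_lookup_beyond_tip(self, idealized_model):
        with pytest.raises(ValueError, match="distal"):
            idealized_model.compartment_at(200.0)


class TestVoltageClamp:
    def test_rest_equals_hold_gives_zero_current(self, idealized_model):
        res = simulate_voltage_clamp(idealized_model, [], hold=-70.0,
                                     duration=2.0)
        assert np.allclose(res["clamp_current"].samples, 0.0, atol=1e-9)

    def test_ideal_clamp_identity_at_soma(self, immature_synapse):
        """With the synapse at the clamped soma the clamp current equals
        g(t)·(hold − E_rev) at machine accuracy; peak 122.5 pA."""
        m = build_idealized_sc(8, 1, 90, 0.47, 1, 1)
        model = compartmentalize(m, PassiveProperties(), 1.0)
        syn = SynapseSpec(0.073, 0.26, 0.004, onset=1.0, location=0)
        res = simulate_voltage_clamp(model, [syn], hold=-70.0, duration=10.0)
        t = res["clamp_current"].times
        expected = biexp_conductance(t, syn) * (-70.0) * 1e3
        assert np.max(np.abs(res["clamp_current"].samples - expected)) < 1e-6
        assert np.max(np.abs(res["clamp_current"].samples)) == pytest.approx(
            122.5, rel=2e-3
        )

    def test_dendritic_synapse_smaller_and_slower(self, idealized_model,
                                                  immature_synapse):
        from stellate.events import waveform_stats
        from dataclasses import replace

        stats = {}
        for dist in (0.0, 45.0):
            loc = idealized_model.compartment_at(dist) if dist else 0
            syn = replace(immature_synapse, onset=1.0, location=loc)
            res = simulate_voltage_clamp(idealized_model, [syn], hold=-70.0,
                                         duration=10.0)
            tr = res["clamp_current"]
            stats[dist] = waveform_stats(
                Trace(dt=tr.dt, samples=tr.samples - tr.samples[0], unit="pA"),
                baseline=0.0,
            )
        assert stats[45.0].amplitude < stats[0.0].amplitude
        assert stats[45.0].rise_10_90 > stats[0.0].rise_10_90
        assert stats[45.0].half_width > stats[0.0].half_width

    def test_branch_invariance(self, immature_props, immature_synapse):
        """Adding resting dendrites changes the response to a synapse on
        another dendrite by < 0.1 %."""
        from dataclasses import replace

        peaks = []
        for n_dend in (1, 3):
            m = build_idealized_sc(8, n_dend, 90, 0.47, 1, 1)
            model = compartmentalize(m, immature_props, 1.0)
            loc = model.compartment_at(45.0)
            syn = replace(immature_synapse, onset=1.0, location=loc)
            res = simulate_voltage_clamp(model, [syn], hold=-70.0, duration=10.0)
            i = res["clamp_current"].samples
            peaks.append(np.max(np.abs(i - i[0])))
        assert abs(peaks[1] - peaks[0]) / peaks[0] < 1e-3

    def test_convergence_under_refinement(self, immature_props,
                                          immature_synapse):
        from dataclasses import replace

        def peak(dx, dt):
            m = build_idealized_sc(8, 1, 90, 0.47, 1, min(dx, 1.0))
            model = compartmentalize(m, immature_props, dx)
            syn = replace(immature_synapse, onset=1.0,
                          location=model.compartment_at(45.0))
            res = simulate_voltage_clamp(model, [syn], hold=-70.0,
                                         duration=8.0, dt=dt)
            i = res["clamp_current"].samples
            return np.max(np.abs(i - i[0]))

        coarse = peak(1.0, 0.005)
        fine = peak(0.5, 0.0025)
        assert abs(fine - coarse) / coarse < 5e-3

    def test_divergence_reported(self, idealized_model):
        # absurdly large dt with a fast conductance must not silently blow up
        syn = SynapseSpec(0.073, 0.26, 0.004, onset=1.0, location=0)
        try:
            simulate_voltage_clamp(idealized_model, [syn], hold=-70.0,
                                   duration=10.0, dt=5.0)
        except IntegrationError:
            pass  # acceptable: diagnosed divergence


class TestCurrentClamp:
    def test_ohmic_steady_state_on_sphere(self, immature_props):
        m = build_idealized_sc(8, 0)
        model = compartmentalize(m, immature_props, 1.0)
        i0 = 0.01  # nA
        res = simulate_current_clamp(
            model, [], injected=(0, lambda t: i0), dt=0.05, duration=150.0
        )
        v = res["soma_voltage"].samples
        r_in = input_resistance(model, 0)
        assert v[-1] - v[0] == pytest.approx(i0 * r_in, rel=1e-3)

    def test_steady_state_profile_matches_sealed_cable(self, immature_props):
        """V(x)/V(0) = cosh((L−x)/λ)/cosh(L/λ) within 1 %."""
        m = build_idealized_sc(8, 1, 90, 0.47, 1, 1)
        model = compartmentalize(m, immature_props, 1.0)
        res = simulate_current_clamp(
            model, [], injected=(0, lambda t: 0.005), dt=0.1, duration=400.0
        )
        v = res["voltages"][-1] - res["voltages"][0]
        lam = lambda_dc(0.47, immature_props.Rm, immature_props.Ri)
        x = model.junction_distance[1:]
        profile = v[1:] / v[1]
        x0 = x[0]
        expected = np.cosh((90.0 - x) / lam) / np.cosh((90.0 - x0) / lam)
        assert np.max(np.abs(profile - expected)) < 0.01

    def test_step_response_decays_with_tau_m(self, immature_props):
        m = build_idealized_sc(8, 0)
        model = compartmentalize(m, immature_props, 1.0)
        res = simulate_current_clamp(
            model, [], injected=(0, lambda t: 0.01 if t < 60 else 0.0),
            dt=0.02, duration=140.0,
        )
        tr = res["soma_voltage"]
        t = tr.times
        decay = tr.samples[t >= 61.0] - tr.samples[0]
        td = t[t >= 61.0] - 61.0

        def expdec(t, a, tau):
            return a * np.exp(-t / tau)

        popt, _ = curve_fit(expdec, td, decay, p0=[decay[0], 18.0])
        assert popt[1] == pytest.approx(immature_props.tau_m, rel=0.01)


class TestInputResistance:
    def test_isolated_sphere(self, immature_props):
        m = build_idealized_sc(8, 0)
        model = compartmentalize(m, immature_props, 1.0)
        # Rm/(pi d^2) = 20000 / (201.06e-8 cm²) ≈ 9.95 GΩ
        assert input_resistance(model, 0) == pytest.approx(9947, rel=1e-3)

    def test_sealed_cable_composition(self, immature_props):
        """Soma input resistance = parallel(sphere, R_inf·coth(L/λ)) within 1 %."""
        m = build_idealized_sc(8, 1, 90, 0.47, 1, 1)
        model = compartmentalize(m, immature_props, 0.25)
        lam_cm = lambda_dc(0.47, immature_props.Rm, immature_props.Ri) / 1e4
        d_cm = 0.47e-4
        r_inf = (
            2.0 * (immature_props.Rm * immature_props.Ri) ** 0.5
            / (math.pi * d_cm ** 1.5)
        ) / 1e6  # MΩ
        r_cable = r_inf / math.tanh(90e-4 / lam_cm)
        r_soma = immature_props.Rm / (math.pi * (8e-4) ** 2) / 1e6
        expected = 1.0 / (1.0 / r_cable + 1.0 / r_soma)
        assert input_resistance(model, 0) == pytest.approx(expected, rel=0.01)

    def test_monotone_increase_to_tip(self, idealized_model):
        r = [input_resistance(idealized_model, i)
             for i in range(0, idealized_model.n, 10)]
        assert np.all(np.diff(r) > 0)


class TestChargeConservation:
    def test_two_compartment_model_vs_dense_ode(self, immature_props):
        """CN solver matches an independent stiff ODE integration of the
        same two-compartment system, including the injected charge."""
        m = build_idealized_sc(8, 1, 2, 0.47, 1, 2)
        model = compartmentalize(m, immature_props, 2.0)
        assert model.n == 2
        syn = SynapseSpec(0.073, 0.26, 0.004, onset=0.5, location=1)
        hold = -70.0
        res = simulate_voltage_clamp(model, [syn], hold=hold, dt=0.002,
                                     duration=8.0)

        gl = model.g_leak
        ga = model.g_axial
        c = model.c_membrane
        p = model.properties

        def rhs(t, y):
            v1 = y[0]
            g = biexp_conductance(t, syn)
            i1 = (-gl[1] * (v1 - p.E_leak) - g * (v1 - syn.E_rev)
                  - ga[1] * (v1 - hold))
            return [i1 / c[1]]

        sol = solve_ivp(rhs, (0, 8.0), [hold], method="LSODA",
                        rtol=1e-10, atol=1e-12, dense_output=True)
        ts = res["times"]
        v1 = sol.sol(ts)[0]
        i_clamp_nA = gl[0] * (hold - p.E_leak) + ga[1] * (hold - v1)
        # pointwise agreement to 0.5 % of the peak (the onset kink limits
        # local accuracy to the discretization order)
        np.testing.assert_allclose(
            res["clamp_current"].samples, i_clamp_nA * 1e3,
            atol=5e-3 * np.max(np.abs(i_clamp_nA * 1e3)),
        )
        # charge through the clamp equals the ODE-integrated charge
        q_cn = np.trapezoid(res["clamp_current"].samples, dx=0.002)
        q_ode = np.trapezoid(i_clamp_nA * 1e3, dx=0.002)
        assert q_cn == pytest.approx(q_ode, rel=1e-3)
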