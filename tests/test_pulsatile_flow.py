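"""Womersley solution, waveform decomposition and flow-regime screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dissectwall.pulsatile_flow import (
    DimensionlessNumbers,
    FlowWaveform,
    FluidProperties,
    decompose_waveform,
    dimensionless_numbers,
    peacock_critical_reynolds,
    reconstruct_waveform,
    womersley_number,
    womersley_pressure_gradient,
    womersley_velocity,
    womersley_wall_shear,
)

T = 0.8
PROPS = FluidProperties()


def _waveform(q_func, n=64):
    t = np.linspace(0, T, n, endpoint=False)
    return FlowWaveform(t, q_func(t), T)


class TestDecompose:
    def test_constant_flow_has_only_dc_term(self):
        wf = _waveform(lambda t: np.full_like(t, 2.5e-4))
        c = decompose_waveform(wf, 4)
        assert c[0] == pytest.approx(2.5e-4)
        assert np.allclose(c[1:], 0.0, atol=1e-18)

    def test_pure_tone_reconstructs_exactly(self):
        wf = _waveform(lambda t: np.sin(2 * np.pi * t / T))
        c = decompose_waveform(wf, 1)
        rec = reconstruct_waveform(c, T, wf.times)
        assert np.sqrt(np.mean((rec - wf.flow) ** 2)) < 1e-10

    def test_packaged_waveform_8_harmonics_within_2pct_of_peak(self):
        wf = FlowWaveform.default()
        c = decompose_waveform(wf, 8)
        rec = reconstruct_waveform(c, wf.period, wf.times)
        rms = np.sqrt(np.mean((rec - wf.flow) ** 2))
        assert rms < 0.02 * wf.peak_flow

    def test_rms_error_decreases_with_harmonics(self):
        wf = FlowWaveform.default()
        errs = []
        for n in (1, 2, 4, 8, 16):
            c = decompose_waveform(wf, n)
            rec = reconstruct_waveform(c, wf.period, wf.times)
            errs.append(np.sqrt(np.mean((rec - wf.flow) ** 2)))
        assert all(a >= b for a, b in zip(errs, errs[1:]))

    def test_dc_coefficient_is_mean_flow(self):
        wf = FlowWaveform.default()
        assert decompose_waveform(wf, 6)[0].real == pytest.approx(wf.mean_flow)

    def test_too_few_samples_rejected(self):
        wf = _waveform(lambda t: np.sin(2 * np.pi * t / T), n=8)
        with pytest.raises(ValueError, match="harmonics"):
            decompose_waveform(wf, 6)

    def test_nonuniform_grid_rejected_or_resampled(self):
        t = np.sort(np.random.default_rng(0).uniform(0, T, 32))
        t[0] = 0.0
        wf = FlowWaveform(t, np.sin(2 * np.pi * t / T), T)
        with pytest.raises(ValueError, match="uniform"):
            decompose_waveform(wf, 4)
        c = decompose_waveform(wf, 4, on_nonuniform="resample")
        assert len(c) == 5


class TestWomersley:
    def test_poiseuille_wall_shear_exact(self):
        q = 3e-4
        r = 0.0125
        c = np.array([q + 0j])
        tau = womersley_wall_shear(c, r, PROPS, T, np.linspace(0, T, 16))
        assert np.allclose(tau, 4 * PROPS.viscosity * q / (np.pi * r**3), rtol=1e-10)

    def test_poiseuille_velocity_profile(self):
        q = 3e-4
        r = 0.0125
        c = np.array([q + 0j])
        rr = np.linspace(0, r, 50)
        u = womersley_velocity(c, r, PROPS, T, np.array([0.0]), rr)
        expected = 2 * q / (np.pi * r**2) * (1 - (rr / r) ** 2)
        assert np.allclose(u[:, 0], expected, rtol=1e-10, atol=1e-12)

    def test_quasi_steady_limit_tracks_poiseuille(self):
        # huge period -> alpha ~ 0 -> tau follows the instantaneous Poiseuille value
        period = 800.0
        r = 0.0125
        q0, q1 = 3e-4, 1e-4
        c = np.array([q0, q1 / 2.0], dtype=complex)
        times = np.linspace(0, period, 32, endpoint=False)
        tau = womersley_wall_shear(c, r, PROPS, period, times)
        q_t = q0 + q1 * np.cos(2 * np.pi * times / period)
        expected = 4 * PROPS.viscosity * q_t / (np.pi * r**3)
        assert np.allclose(tau, expected, rtol=0.01)

    def test_womersley_number_value(self):
        # R = 1 cm, T = 0.8 s, nu = mu/rho for the standard blood model
        alpha = womersley_number(0.01, 0.8, PROPS.kinematic_viscosity)
        assert alpha == pytest.approx(16.155, abs=5e-3)

    def test_no_slip_at_wall(self, waveform):
        c = decompose_waveform(waveform, 8)
        r = 0.0125
        times = np.linspace(0, T, 32, endpoint=False)
        u = womersley_velocity(c, r, PROPS, T, times, np.array([0.0, 0.5 * r, r]))
        assert np.max(np.abs(u[-1])) < 1e-12 * np.max(np.abs(u))

    def test_wall_shear_matches_finite_difference(self, waveform):
        # oracle equivalence: analytic J1-based derivative vs one-sided FD
        c = decompose_waveform(waveform, 8)
        r = 0.0125
        h = r / 1e4
        times = np.linspace(0, T, 16, endpoint=False)
        u = womersley_velocity(c, r, PROPS, T, times, np.array([r - 2 * h, r - h, r]))
        dudr = (3 * u[2] - 4 * u[1] + u[0]) / (2 * h)
        tau_fd = -PROPS.viscosity * dudr
        tau = womersley_wall_shear(c, r, PROPS, T, times)
        assert np.max(np.abs(tau - tau_fd)) / np.max(np.abs(tau)) < 1e-4

    def test_flow_recovered_by_section_integration(self, waveform):
        from scipy.integrate import simpson

        c = decompose_waveform(waveform, 8)
        r = 0.0125
        times = np.linspace(0, T, 8, endpoint=False)
        rr = np.linspace(0, r, 801)
        u = womersley_velocity(c, r, PROPS, T, times, rr)
        q_num = simpson(u * (2 * np.pi * rr)[:, None], x=rr, axis=0)
        q_ref = reconstruct_waveform(c, T, times)
        assert np.allclose(q_num, q_ref, rtol=5e-3, atol=5e-3 * np.max(np.abs(q_ref)))

    def test_pressure_gradient_steady_term(self):
        q = 3e-4
        r = 0.0125
        g = womersley_pressure_gradient(np.array([q + 0j]), r, PROPS, T, np.array([0.0]))
        assert g[0] == pytest.approx(8 * PROPS.viscosity * q / (np.pi * r**4), rel=1e-12)

    def test_huge_alpha_stays_finite(self):
        # alpha ~ 1600: naive Bessel evaluation overflows; asymptotics must kick in
        c = np.array([1e-4, 5e-5], dtype=complex)
        r = 1.0
        tau = womersley_wall_shear(c, r, PROPS, T, np.linspace(0, T, 8))
        u = womersley_velocity(c, r, PROPS, T, np.linspace(0, T, 4), np.linspace(0, r, 20))
        assert np.all(np.isfinite(tau)) and np.all(np.isfinite(u))

    def test_invalid_radius_and_position(self):
        c = np.array([1e-4 + 0j])
        with pytest.raises(ValueError):
            womersley_velocity(c, -0.01, PROPS, T, np.array([0.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            womersley_velocity(c, 0.01, PROPS, T, np.array([0.0]), np.array([0.02]))


class TestDimensionless:
    def test_peak_reynolds_formula(self):
        # U_peak = 0.5 m/s in a 3 cm tube with standard blood
        d = 0.03
        q_peak = 0.5 * np.pi * d**2 / 4
        wf = _waveform(lambda t: q_peak * (0.6 + 0.4 * np.cos(2 * np.pi * t / T)))
        dn = dimensionless_numbers(wf, d)
        assert dn.re_peak == pytest.approx(4984.3, abs=0.5)

    def test_womersley_alpha_value(self):
        wf = FlowWaveform.default()
        dn = dimensionless_numbers(wf, 0.02)
        assert dn.alpha == pytest.approx(16.16, abs=0.01)

    def test_subcritical_across_physiologic_diameters(self):
        # waveform scaled with D^2 (fixed peak velocity) over 2-3.5 cm
        wf = FlowWaveform.default()
        for d in np.linspace(0.02, 0.035, 7):
            dn = dimensionless_numbers(wf.scaled((d / 0.03) ** 2), d)
            assert dn.subcritical, f"supercritical at D={d}"

    def test_zero_mean_flow_rejected(self):
        wf = _waveform(lambda t: 1e-4 * np.sin(2 * np.pi * t / T))
        with pytest.raises(ValueError, match="Strouhal"):
            dimensionless_numbers(wf, 0.03)

    @settings(derandomize=True, max_examples=50)
    @given(
        a1=st.floats(5, 40), a2=st.floats(5, 40),
        s1=st.floats(0.02, 0.5), s2=st.floats(0.02, 0.5),
    )
    def test_critical_reynolds_monotone(self, a1, a2, s1, s2):
        lo_a, hi_a = sorted((a1, a2))
        lo_s, hi_s = sorted((s1, s2))
        assert peacock_critical_reynolds(hi_a, lo_s) >= peacock_critical_reynolds(lo_a, lo_s)
        assert peacock_critical_reynolds(lo_a, hi_s) <= peacock_critical_reynolds(lo_a, lo_s)

    def test_consistency_flag(self):
        dn = DimensionlessNumbers(alpha=20, strouhal=0.1, re_peak=4000, re_crit=4500)
        assert dn.subcritical
        assert not DimensionlessNumbers(20, 0.1, 5000, 4500).subcritical
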