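"""Phasor transform, calibration, lifetimes and two-component unmixing."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import phasorflim as pf
from phasorflim import scene as sc

from conftest import IRF_SIGMA, N_BINS, OMEGA, PERIOD, TAU_REF, mono_stack


def _single_pixel_field(g, s, intensity=1.0, calibrated=True):
    return pf.PhasorField(
        g=np.array([[float(g)]]), s=np.array([[float(s)]]),
        intensity=np.array([[float(intensity)]]),
        valid=np.array([[True]]), omega=OMEGA, calibrated=calibrated,
    )


class TestMonoExpPhasor:
    @pytest.mark.parametrize("tau, expected", [
        (0.0, (1.0, 0.0)),
        (1.5, (0.6375, 0.4807)),
        (2.23, (0.4432, 0.4968)),
        (1e6, (0.0, 0.0)),
    ])
    def test_closed_form_values(self, tau, expected):
        g, s = pf.mono_exp_phasor(tau, OMEGA)
        assert (g, s) == pytest.approx(expected, abs=1e-4)

    @given(tau=hst.floats(min_value=0.0, max_value=50.0))
    @settings(deadline=None)
    def test_always_on_universal_semicircle(self, tau):
        g, s = pf.mono_exp_phasor(tau, OMEGA)
        assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-12)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            pf.mono_exp_phasor(-1.0, OMEGA)


class TestPhasorTransform:
    def test_first_bin_histogram_near_g1_s0(self):
        counts = np.zeros((1, 1, N_BINS))
        counts[0, 0, 0] = 1e4
        stack = pf.DecayStack(counts, 80.0, N_BINS, PERIOD / N_BINS, 0.2, "t")
        f = pf.phasor_transform(stack)
        assert f.g[0, 0] == pytest.approx(1.0, abs=0.01)
        assert f.s[0, 0] == pytest.approx(0.0, abs=0.02)

    def test_uniform_histogram_maps_to_origin(self):
        counts = np.full((1, 1, N_BINS), 7.0)
        stack = pf.DecayStack(counts, 80.0, N_BINS, PERIOD / N_BINS, 0.2, "t")
        f = pf.phasor_transform(stack)
        assert abs(f.g[0, 0]) < 1e-12 and abs(f.s[0, 0]) < 1e-12

    def test_matches_closed_form_for_smooth_decay(self):
        f = pf.phasor_transform(mono_stack(1.5, 1e6, irf_sigma=0.0, n_bins=4096))
        g_th, s_th = pf.mono_exp_phasor(1.5, OMEGA)
        assert (f.g[0, 0], f.s[0, 0]) == pytest.approx((g_th, s_th), abs=1e-3)

    def test_invalid_harmonic_rejected(self):
        with pytest.raises(ValueError, match="harmonic"):
            pf.phasor_transform(mono_stack(1.5, 100), harmonic=0)

    def test_zero_count_pixels_flagged_invalid(self):
        counts = np.zeros((2, 1, N_BINS))
        counts[0, 0, 5] = 10
        stack = pf.DecayStack(counts, 80.0, N_BINS, PERIOD / N_BINS, 0.2, "t")
        f = pf.phasor_transform(stack)
        assert f.valid[0, 0] and not f.valid[1, 0]
        assert np.isnan(f.g[1, 0]) and np.isnan(f.s[1, 0])

    def test_linearity_of_stack_sums(self):
        """Phasor of a summed stack is the intensity-weighted phasor mean."""
        a = mono_stack(0.8, 3e5, noise=False)
        b = mono_stack(3.0, 7e5, noise=False)
        summed = dataclasses.replace(a, counts=a.counts + b.counts)
        fa, fb = pf.phasor_transform(a), pf.phasor_transform(b)
        fs = pf.phasor_transform(summed)
        wa = fa.intensity[0, 0] / (fa.intensity[0, 0] + fb.intensity[0, 0])
        assert fs.g[0, 0] == pytest.approx(wa * fa.g[0, 0] + (1 - wa) * fb.g[0, 0], abs=1e-12)
        assert fs.s[0, 0] == pytest.approx(wa * fa.s[0, 0] + (1 - wa) * fb.s[0, 0], abs=1e-12)


class TestCalibration:
    def test_reference_at_theory_gives_identity(self):
        f = _single_pixel_field(*pf.mono_exp_phasor(TAU_REF, OMEGA), calibrated=False)
        corr = pf.calibration_from_reference(f, TAU_REF)
        assert corr.delta_phi == pytest.approx(0.0, abs=1e-12)
        assert corr.mod_factor == pytest.approx(1.0, abs=1e-12)

    def test_constructed_rotation_recovered(self):
        g0, s0 = pf.mono_exp_phasor(TAU_REF, OMEGA)
        rot = 0.3
        g = g0 * np.cos(rot) - s0 * np.sin(rot)
        s = g0 * np.sin(rot) + s0 * np.cos(rot)
        corr = pf.calibration_from_reference(
            _single_pixel_field(g, s, calibrated=False), TAU_REF)
        assert corr.delta_phi == pytest.approx(-0.3, abs=1e-12)
        assert corr.mod_factor == pytest.approx(1.0, abs=1e-12)

    def test_correction_maps_reference_onto_theory(self, calibration):
        ref = sc.simulate_reference(TAU_REF, 1e6, noise=False)
        f = pf.apply_calibration(pf.phasor_transform(ref), calibration)
        assert pf.aggregate_phasor(f) == pytest.approx(
            pf.mono_exp_phasor(TAU_REF, OMEGA), abs=1e-6)

    def test_irf_cancellation_for_other_lifetime(self, calibration):
        """Calibrating on one lifetime corrects any other despite the IRF."""
        f = pf.apply_calibration(pf.phasor_transform(
            mono_stack(1.1, 1e6, noise=False)), calibration)
        assert (f.g[0, 0], f.s[0, 0]) == pytest.approx(
            pf.mono_exp_phasor(1.1, OMEGA), abs=0.01)

    def test_identity_correction_is_noop(self):
        f = _single_pixel_field(0.3, 0.4)
        corr = pf.CalibrationCorrection(0.0, 1.0, TAU_REF, OMEGA)
        out = pf.apply_calibration(dataclasses.replace(f, calibrated=False), corr)
        assert out.g[0, 0] == pytest.approx(0.3) and out.s[0, 0] == pytest.approx(0.4)
        assert out.calibrated

    def test_pi_rotation_flips_g(self):
        f = _single_pixel_field(1.0, 0.0, calibrated=False)
        corr = pf.CalibrationCorrection(np.pi, 1.0, TAU_REF, OMEGA)
        out = pf.apply_calibration(f, corr)
        assert (out.g[0, 0], out.s[0, 0]) == pytest.approx((-1.0, 0.0), abs=1e-12)

    def test_omega_mismatch_rejected(self):
        f = _single_pixel_field(0.5, 0.2, calibrated=False)
        corr = pf.CalibrationCorrection(0.0, 1.0, TAU_REF, OMEGA * 2)
        with pytest.raises(ValueError, match="omega"):
            pf.apply_calibration(f, corr)

    def test_zero_modulus_reference_rejected(self):
        with pytest.raises(ValueError, match="unusable"):
            pf.calibration_from_reference(
                _single_pixel_field(0.0, 0.0, calibrated=False), TAU_REF)


class TestLifetimes:
    @pytest.mark.parametrize("g, s, tau", [
        (1.0, 0.0, 0.0),
        (0.4432, 0.4968, 2.23),
        (0.6375, 0.4807, 1.5),
    ])
    def test_phase_lifetime_inverts_closed_form(self, g, s, tau):
        assert pf.phase_lifetime(g, s, OMEGA) == pytest.approx(tau, abs=5e-3)

    def test_nonpositive_g_flagged(self):
        assert np.isnan(pf.phase_lifetime(0.0, 0.3, OMEGA))
        assert np.isnan(pf.phase_lifetime(-0.2, 0.3, OMEGA))

    def test_modulation_equals_phase_on_semicircle(self):
        g, s = pf.mono_exp_phasor(1.5, OMEGA)
        assert pf.modulation_lifetime(g, s, OMEGA) == pytest.approx(1.5, abs=1e-9)
        assert pf.modulation_lifetime(1.0, 0.0, OMEGA) == 0.0

    def test_interior_point_has_tau_m_above_tau_phi(self):
        tau_m = pf.modulation_lifetime(0.5, 0.25, OMEGA)
        tau_phi = pf.phase_lifetime(0.5, 0.25, OMEGA)
        assert tau_m != pytest.approx(tau_phi, abs=1e-6)

    def test_unphysical_modulus_flagged(self):
        assert np.isnan(pf.modulation_lifetime(1.2, 0.3, OMEGA))


class TestUnmixing:
    def test_endpoint_gives_full_fraction(self):
        a, b = (1.0, 0.0), (0.4432, 0.4968)
        frac, resid = pf.linear_unmix_two(a, a, b)
        assert frac == pytest.approx(1.0) and resid == pytest.approx(0.0)

    def test_midpoint_gives_half(self):
        a, b = np.array([1.0, 0.0]), np.array([0.4432, 0.4968])
        frac, _ = pf.linear_unmix_two((a + b) / 2, a, b)
        assert frac == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_endpoints_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            pf.linear_unmix_two((0.5, 0.2), (0.3, 0.3), (0.3, 0.3))

    def test_off_segment_point_clips_and_reports_residual(self):
        frac, resid = pf.linear_unmix_two((1.2, -0.1), (1.0, 0.0), (0.0, 0.0))
        assert 0.0 <= frac <= 1.0 and resid > 0

    def test_simulated_70_30_mixture_recovered(self):
        """Intensity mixture of SHG-like and elastin-like decays unmixes to 0.7."""
        h = sc.simulate_decay_histogram(
            [(0.7, 0.0), (0.3, 2.23)], 1e6, N_BINS, PERIOD, IRF_SIGMA, noise=False)
        ref = sc.simulate_reference(TAU_REF, 1e6, noise=False)
        corr = pf.calibration_from_reference(pf.phasor_transform(ref), TAU_REF)
        stack = pf.DecayStack(h[None, None], 80.0, N_BINS, PERIOD / N_BINS, 0.2, "t")
        f = pf.apply_calibration(pf.phasor_transform(stack), corr)
        frac, resid = pf.linear_unmix_two(
            (f.g[0, 0], f.s[0, 0]),
            (1.0, 0.0), pf.mono_exp_phasor(2.23, OMEGA))
        assert frac == pytest.approx(0.70, abs=0.02)
        assert resid < 0.01


class TestMedianFilter:
    def test_window_one_is_identity(self):
        f = _single_pixel_field(0.4, 0.3)
        out = pf.median_filter_phasor(f, 1)
        assert out.g[0, 0] == f.g[0, 0]

    def test_constant_field_unchanged(self):
        g = np.full((5, 5), 0.4)
        f = pf.PhasorField(g=g.copy(), s=g.copy(), intensity=np.ones_like(g),
                           valid=np.ones_like(g, bool), omega=OMEGA, calibrated=True)
        out = pf.median_filter_phasor(f, 3)
        assert np.allclose(out.g, 0.4) and np.allclose(out.s, 0.4)

    def test_outlier_replaced_by_neighbourhood_constant(self):
        g = np.full((5, 5), 0.4)
        g[2, 2] = 0.9
        f = pf.PhasorField(g=g, s=np.full((5, 5), 0.2), intensity=np.ones_like(g),
                           valid=np.ones_like(g, bool), omega=OMEGA, calibrated=True)
        out = pf.median_filter_phasor(f, 3)
        assert out.g[2, 2] == pytest.approx(0.4)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            pf.median_filter_phasor(_single_pixel_field(0.4, 0.3), 2)


class TestRecoveryProperties:
    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 4.0])
    def test_phase_lifetime_recovery_across_range(self, tau, calibration):
        """Aggregate >= 1e5 Poisson counts recover tau within 0.05 ns."""
        stack = mono_stack(tau, 2e5, noise=True, seed=int(tau * 10))
        f = pf.apply_calibration(pf.phasor_transform(stack), calibration)
        tau_phi = pf.phase_lifetime(*pf.aggregate_phasor(f), OMEGA)
        assert tau_phi == pytest.approx(tau, abs=0.05)
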