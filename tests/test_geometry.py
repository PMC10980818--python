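"""Closed-form slab/view geometry and waveform design."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import propsim as ps
from propsim.geometry import (
    ConvergenceError,
    design_shear_waveform,
    local_view_angle,
    predicted_surface,
    shear_rate_for_view,
    shutter_row_speed,
    slab_bounds,
    viewing_angle,
)


def _sweep(span=200.0, duration=1.0):
    return ps.SweepConfig(-50.0, -50.0 + span, 201, duration)


class TestSlabBounds:
    def test_depth_law_and_center(self):
        optics = ps.OpticsConfig(45.0, z_max=128.0)
        shutter = ps.ShutterConfig(width_W=3.536, center_c0=20.0)
        slab = slab_bounds(shutter, optics, _sweep(), ps.ShearWaveform(rate_r=1.0))
        assert slab.z_depth == pytest.approx(3.536 * math.cos(math.radians(45)), abs=1e-6)
        assert slab.z_depth == pytest.approx(2.5, abs=0.01)
        assert slab.z_center == pytest.approx(20.0 * math.cos(math.radians(45)))

    def test_zero_width_empty_slab(self):
        optics = ps.OpticsConfig(37.0, z_max=128.0)
        slab = slab_bounds(ps.ShutterConfig(width_W=0.0, center_c0=30.0), optics,
                           _sweep(), ps.ShearWaveform(rate_r=1.0))
        assert slab.z_depth == 0.0

    def test_small_tilt_limit(self):
        optics = ps.OpticsConfig(0.01, z_max=128.0)
        slab = slab_bounds(ps.ShutterConfig(width_W=10.0, center_c0=20.0), optics,
                           _sweep(), ps.ShearWaveform(rate_r=1.0))
        assert slab.z_depth == pytest.approx(10.0, rel=1e-6)

    def test_delay_moves_slab_up(self):
        optics = ps.OpticsConfig(45.0, z_max=500.0)
        sweep = _sweep(span=100.0, duration=0.1)  # v_s = 1000 µm/s
        shear = ps.ShearWaveform(rate_r=2.0)  # v_u = 2000 µm/s
        s0 = slab_bounds(ps.ShutterConfig(10.0, center_c0=50.0), optics, sweep, shear)
        s1 = slab_bounds(ps.ShutterConfig(10.0, center_c0=50.0, delay_tau=0.01),
                         optics, sweep, shear)
        assert s1.z_center - s0.z_center == pytest.approx(
            2000.0 * 0.01 * optics.cos_phi
        )

    def test_clamped_with_warning(self):
        optics = ps.OpticsConfig(45.0, z_max=10.0)
        with pytest.warns(UserWarning, match="clipped"):
            slab = slab_bounds(ps.ShutterConfig(100.0, center_c0=0.0), optics,
                               _sweep(), ps.ShearWaveform(rate_r=1.0))
        assert slab.z_lo == pytest.approx(0.0)
        assert slab.z_hi == pytest.approx(10.0)

    def test_rejects_nonlinear_or_unsynchronized(self):
        optics = ps.OpticsConfig(45.0)
        q = (np.array([-50.0, 150.0]), np.array([0.0, 5.0]))
        with pytest.raises(ValueError, match="linear"):
            slab_bounds(ps.ShutterConfig(10.0), optics, _sweep(),
                        ps.ShearWaveform(rate_r=1.0, nonlinear_q=q))
        with pytest.raises(ValueError, match="synchronized"):
            slab_bounds(ps.ShutterConfig(10.0, synchronized=False), optics,
                        _sweep(), ps.ShearWaveform(rate_r=1.0))


class TestViewingAngle:
    @pytest.mark.parametrize("phi", [30.0, 45.0, 60.0])
    def test_top_down_rate(self, phi):
        optics = ps.OpticsConfig(phi)
        view = viewing_angle(ps.ShearWaveform(rate_r=1.0 / optics.sin_phi), optics)
        assert view.psi == pytest.approx(0.0, abs=1e-9)

    def test_known_angles_at_45(self):
        optics = ps.OpticsConfig(45.0)
        assert viewing_angle(ps.ShearWaveform(rate_r=0.70711), optics).psi == pytest.approx(
            -45.0, abs=1e-3
        )
        assert viewing_angle(
            ps.ShearWaveform(rate_r=2 * math.sqrt(2)), optics
        ).psi == pytest.approx(math.degrees(math.atan(0.5)), abs=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(
        phi=st.floats(5.0, 85.0),
        psi=st.floats(-80.0, 80.0),
    )
    def test_rate_view_round_trip(self, phi, psi):
        optics = ps.OpticsConfig(phi)
        if psi >= phi - 0.5:
            return
        r = shear_rate_for_view(psi, optics)
        assert r > 0
        back = viewing_angle(ps.ShearWaveform(rate_r=r), optics)
        assert back.psi == pytest.approx(psi, abs=1e-6)

    def test_unreachable_angle_rejected(self):
        optics = ps.OpticsConfig(45.0)
        with pytest.raises(ValueError, match="unreachable"):
            shear_rate_for_view(45.0, optics)


def _arc_surface(z0=30.0, R=100.0, xc=64.0, half=48.0, hw=2.5):
    x = np.arange(xc - half, xc + half + 0.01, 1.0)
    z = z0 + R - np.sqrt(R**2 - (x - xc) ** 2)
    return ps.SurfaceSpec(x, z, half_width=hw)


class TestWaveformDesign:
    def setup_method(self):
        self.optics = ps.OpticsConfig(45.0, z_max=127.0)
        self.shear = ps.ShearWaveform(rate_r=1.0 / self.optics.sin_phi)
        self.shutter = ps.ShutterConfig(width_W=7.07, center_c0=0.0)
        self.sweep = ps.SweepConfig(-80.0, 130.0, 211, 0.1)

    def test_flat_surface_constant_q(self):
        z0 = 25.0
        surf = ps.SurfaceSpec(np.array([10.0, 110.0]), np.array([z0, z0]))
        wave = design_shear_waveform(surf, self.optics, self.shutter, self.shear, self.sweep)
        q = np.asarray(wave.q(self.sweep.s_grid()))
        v_u = shutter_row_speed(self.shear, self.sweep)
        expected = self.shutter.center_c0 + v_u * self.shutter.delay_tau - z0 / self.optics.cos_phi
        assert np.allclose(q, expected, atol=1e-9)

    def test_arc_round_trip_within_half_micron(self):
        surf = _arc_surface()
        wave = design_shear_waveform(surf, self.optics, self.shutter, self.shear, self.sweep)
        pred = predicted_surface(wave, self.optics, self.shutter, self.sweep, surf.x_grid)
        assert np.max(np.abs(pred.z_of_x - surf.z_of_x)) < 0.5
        assert pred.half_width == pytest.approx(
            self.shutter.width_W * self.optics.cos_phi / 2.0
        )

    def test_steep_surface_rejected(self):
        # slope reaches 1.2 > 1/tan(45°): the scan map s(x) folds back
        x = np.arange(0.0, 40.01, 0.5)
        z = 1.2 * x
        surf = ps.SurfaceSpec(x, z + 10.0)
        with pytest.raises(ValueError, match="not invertible"):
            design_shear_waveform(surf, self.optics, self.shutter, self.shear,
                                  ps.SweepConfig(-200, 200, 401, 0.1))

    def test_surface_beyond_scan_range_rejected(self):
        surf = _arc_surface()
        with pytest.raises(ValueError, match="beyond the sweep"):
            design_shear_waveform(surf, self.optics, self.shutter, self.shear,
                                  ps.SweepConfig(0.0, 10.0, 11, 0.1))

    def test_predicted_surface_without_q_matches_slab(self):
        shutter = ps.ShutterConfig(width_W=7.07, center_c0=30.0, delay_tau=0.002)
        slab = slab_bounds(shutter, self.optics, self.sweep, self.shear)
        pred = predicted_surface(self.shear, self.optics, shutter, self.sweep,
                                 np.linspace(0, 100, 11))
        assert np.allclose(pred.z_of_x, slab.z_center, atol=1e-9)

    @pytest.mark.parametrize("a", [-0.5, 0.3, 0.9])
    def test_linear_ramp_fixed_point_matches_analytic(self, a):
        # q(s) = a·s  ->  z_c = cosφ·(c − a·x)/(1 − a·sinφ)
        s = np.linspace(-300.0, 300.0, 601)
        shear = ps.ShearWaveform(rate_r=1.0, nonlinear_q=(s, a * s))
        shutter = ps.ShutterConfig(width_W=5.0, center_c0=80.0)
        x = np.linspace(0.0, 50.0, 11)
        pred = predicted_surface(shear, self.optics, shutter, self.sweep, x)
        c = shutter.center_c0
        expected = self.optics.cos_phi * (c - a * x) / (1.0 - a * self.optics.sin_phi)
        assert np.allclose(pred.z_of_x, expected, atol=0.02)

    def test_local_view_angle_matches_effective_rate(self):
        a = 0.4
        s = np.linspace(-300.0, 300.0, 601)
        shear = ps.ShearWaveform(rate_r=1.0, nonlinear_q=(s, a * s))
        psi_local = local_view_angle(shear, self.optics, 0.0)
        psi_eff = viewing_angle(ps.ShearWaveform(rate_r=1.0 + a), self.optics).psi
        assert psi_local == pytest.approx(psi_eff, abs=1e-6)


class TestConfigValidation:
    def test_invalid_optics(self):
        with pytest.raises(ValueError):
            ps.OpticsConfig(0.0)
        with pytest.raises(ValueError):
            ps.OpticsConfig(95.0)
        with pytest.raises(ValueError):
            ps.OpticsConfig(45.0, pixel_pitch=0.0)

    def test_invalid_waveform_grid(self):
        with pytest.raises(ValueError, match="increasing"):
            ps.ShearWaveform(rate_r=1.0, nonlinear_q=(np.array([0.0, 0.0, 1.0]),
                                                      np.zeros(3)))
        with pytest.raises(ValueError):
            ps.ShearWaveform(rate_r=-1.0)

    def test_surface_invariants(self):
        with pytest.raises(ValueError):
            ps.SurfaceSpec(np.array([1.0, 0.0]), np.array([0.0, 0.0]))
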