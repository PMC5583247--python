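"""Forward simulator: source waveforms, motion sampling, delay physics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsomotion import (MotionModel, Phantom, ScanGeometry, SphereAbsorber,
                       SurfaceSheet, nwave_pulse, sample_motion,
                       simulate_sinogram)
from rsomotion.simulate import MotionTrace, gabor_wavelet, vessel_chain


class TestNWave:
    C = 1500.0

    def test_zero_outside_support_and_at_center(self):
        r = 20.0
        tau = r / self.C
        assert nwave_pulse(r, self.C, 2 * tau) == 0.0
        assert nwave_pulse(r, self.C, 0.0) == 0.0

    def test_extrema_equal_magnitude_opposite_sign(self):
        r = 20.0
        tau = r / self.C
        lead = float(nwave_pulse(r, self.C, -tau))
        trail = float(nwave_pulse(r, self.C, +tau))
        assert lead == pytest.approx(-trail)
        assert lead == pytest.approx(1.0)        # leading compression

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(min_value=-1.0, max_value=1.0, allow_nan=False))
    def test_odd_symmetry(self, t):
        r, c = 35.0, 1500.0
        assert float(nwave_pulse(r, c, t)) == pytest.approx(
            -float(nwave_pulse(r, c, -t)), abs=1e-12)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            nwave_pulse(-1.0, self.C, 0.0)

    def test_gabor_is_odd_and_finite(self):
        w = gabor_wavelet(2.0, 0.002)
        assert w.size % 2 == 1
        assert np.allclose(w + w[::-1], 0.0, atol=1e-12)


class TestSampleMotion:
    def geom(self, n_fs=10, n_ss=50, prr=100.0):
        return ScanGeometry(n_fs=n_fs, n_ss=n_ss, step_um=20.0, prr_hz=prr,
                            focal_length_um=900.0, aperture_um=818.0,
                            band_lo_mhz=20.0, band_hi_mhz=180.0, n_t=256)

    def test_zero_model_gives_zero_trace(self):
        m = MotionModel(breathing_amplitude_um=0.0, jitter_sd_um=0.0)
        tr = sample_motion(m, self.geom(), seed=0)
        assert np.allclose(tr.z_offset_um, 0.0)

    def test_pure_sinusoid_matches_closed_form(self):
        g = self.geom()
        m = MotionModel(breathing_amplitude_um=25.0, breathing_freq_hz=0.25,
                        phase_rad=0.3, jitter_sd_um=0.0, mode="per_bscan")
        tr = sample_motion(m, g, seed=0)
        t_b = np.arange(g.n_ss) * g.n_fs / g.prr_hz
        expect = 25.0 * np.sin(2 * np.pi * 0.25 * t_b + 0.3)
        assert np.allclose(tr.z_offset_um, expect[:, None])
        assert np.abs(tr.z_offset_um).max() <= 25.0 + 1e-9

    def test_breathing_cycle_count_over_70s(self):
        # 15 cycles/min over a 70 s scan -> 17.5 cycles
        g = self.geom(n_fs=10, n_ss=700, prr=100.0)   # 70 s scan
        m = MotionModel(breathing_amplitude_um=30.0,
                        breathing_freq_hz=15.0 / 60.0, jitter_sd_um=0.0)
        assert m.breathing_freq_hz * (g.n_fs * g.n_ss / g.prr_hz) == 17.5
        tr = sample_motion(m, g, seed=0)
        zero_up = np.sum((tr.z_offset_um[:-1, 0] < 0)
                         & (tr.z_offset_um[1:, 0] >= 0))
        assert zero_up in (17, 18)

    def test_per_bscan_constant_along_fs(self):
        m = MotionModel(breathing_amplitude_um=10.0, jitter_sd_um=5.0)
        tr = sample_motion(m, self.geom(), seed=3)
        assert np.all(np.ptp(tr.z_offset_um, axis=1) == 0.0)

    def test_seed_reproducibility(self):
        m = MotionModel(breathing_amplitude_um=10.0, jitter_sd_um=5.0)
        a = sample_motion(m, self.geom(), seed=7).z_offset_um
        b = sample_motion(m, self.geom(), seed=7).z_offset_um
        assert np.array_equal(a, b)


class TestSimulateSinogram:
    def test_empty_phantom_zero_noise_all_zero(self, small_geometry):
        surface = SurfaceSheet(depth_um=1050.0, melanin_absorption=0.0,
                               artifact_gain=0.0)
        ph = Phantom(surface=surface, absorbers=[],
                     extent_um=((-100, 500), (-100, 500)))
        sino = simulate_sinogram(ph, small_geometry)
        assert np.allclose(sino.data, 0.0)

    def test_on_axis_sphere_delay_oracle(self, point_sinogram, small_geometry):
        # analytic delay: depth 1250 um at 1500 um/us and 500 MHz
        g = small_geometry
        trace = np.abs(point_sinogram.data[10, 10])
        expected = round(1250.0 / g.c_um_per_us * g.sampling_mhz)
        assert abs(int(np.argmax(trace)) - expected) <= 3

    def test_uniform_offset_shifts_arrivals(self, point_phantom, small_geometry):
        g = small_geometry
        base = simulate_sinogram(point_phantom, g)
        # +30 um offset at 1500 um/us, 500 MHz -> 10 samples later on axis
        off = MotionTrace(np.full((g.n_ss, g.n_fs), 30.0))
        moved = simulate_sinogram(point_phantom, g, motion=off)
        d0 = int(np.argmax(np.abs(base.data[10, 10])))
        d1 = int(np.argmax(np.abs(moved.data[10, 10])))
        assert d1 - d0 == 10

    def test_motion_reciprocity(self, small_geometry):
        # offset +delta == motion-free scan of the phantom shifted +delta in z
        g = small_geometry
        surface = SurfaceSheet(depth_um=1050.0, melanin_absorption=0.0,
                               artifact_gain=0.0)
        ext = ((-100, 500), (-100, 500))
        delta = 30.0
        ph = Phantom(surface, [SphereAbsorber((200., 200., 1250.), 6.0, 1.0)], ext)
        ph_shift = Phantom(surface,
                           [SphereAbsorber((200., 200., 1250. + delta), 6.0, 1.0)],
                           ext)
        off = MotionTrace(np.full((g.n_ss, g.n_fs), delta))
        moved = simulate_sinogram(ph, g, motion=off)
        shifted = simulate_sinogram(ph_shift, g)
        assert np.allclose(moved.data, shifted.data, atol=1e-9)

    def test_linearity_for_disjoint_absorbers(self, small_geometry):
        g = small_geometry
        surface = SurfaceSheet(depth_um=1050.0, melanin_absorption=0.0,
                               artifact_gain=0.0)
        a = SphereAbsorber((150.0, 150.0, 1250.0), 10.0, 1.0)
        b = SphereAbsorber((250.0, 250.0, 1300.0), 10.0, 2.0)
        ext = ((-100, 500), (-100, 500))
        sino_a = simulate_sinogram(Phantom(surface, [a], ext), g)
        sino_b = simulate_sinogram(Phantom(surface, [b], ext), g)
        sino_ab = simulate_sinogram(Phantom(surface, [a, b], ext), g)
        assert np.allclose(sino_ab.data, sino_a.data + sino_b.data, atol=1e-9)

    def test_seeded_noise_is_deterministic(self, point_phantom, small_geometry):
        a = simulate_sinogram(point_phantom, small_geometry, noise_sd=0.5, seed=9)
        b = simulate_sinogram(point_phantom, small_geometry, noise_sd=0.5, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_cone_gating_excludes_lateral_absorber(self, small_geometry):
        g = small_geometry
        surface = SurfaceSheet(depth_um=1050.0, melanin_absorption=0.0,
                               artifact_gain=0.0)
        # 2 mm outside the scan area: beyond every acceptance cone
        far = SphereAbsorber((2400.0, 200.0, 1250.0), 10.0, 5.0)
        ph = Phantom(surface=surface, absorbers=[far],
                     extent_um=((-100, 2500), (-100, 500)))
        sino = simulate_sinogram(ph, g)
        assert np.allclose(sino.data, 0.0)

    def test_absorber_above_surface_rejected(self, small_geometry):
        surface = SurfaceSheet(depth_um=1050.0)
        bad = SphereAbsorber((200.0, 200.0, 1000.0), 10.0, 1.0)
        ph = Phantom(surface=surface, absorbers=[bad],
                     extent_um=((-100, 500), (-100, 500)))
        with pytest.raises(ValueError, match="above the surface"):
            simulate_sinogram(ph, small_geometry)

    def test_motion_shape_mismatch_rejected(self, point_phantom, small_geometry):
        with pytest.raises(ValueError, match="motion trace shape"):
            simulate_sinogram(point_phantom, small_geometry,
                              motion=MotionTrace(np.zeros((3, 3))))

    def test_vessel_chain_geometry(self):
        chain = vessel_chain((0, 0, 1200), (0, 1000, 1200), radius_um=25.0,
                             spacing_um=10.0)
        assert len(chain) >= 100
        ys = [s.center_um[1] for s in chain]
        assert ys[0] == 0.0 and ys[-1] == 1000.0
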