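"""Smoothed synthetic surface, offset maps and their application."""

import numpy as np
import pytest

from rsomotion import (MotionCorrection, OffsetMap, Phantom, SphereAbsorber,
                       SurfaceSheet, SuspiciousMotionError, apply_offsets,
                       beamform, compute_offsets, shift_sinogram,
                       simulate_sinogram, smooth_surface)
from rsomotion.simulate import MotionTrace
from rsomotion.surface import SurfaceMap


def smap(arr):
    return SurfaceMap(t_surface=np.asarray(arr, dtype=float), method="lowfreq")


class TestSmoothSurface:
    def test_constant_map_is_fixed_point(self):
        m = smap(np.full((50, 30), 7.25))
        out = smooth_surface(m, 200, 10)
        assert np.allclose(out.t_surface, 7.25)

    def test_unit_spike_response(self):
        m = np.zeros((400, 40))
        m[200, 20] = 1.0
        out = smooth_surface(smap(m), 200, 10)
        assert out.t_surface.max() == pytest.approx(1.0 / 2000.0, rel=1e-12)

    def test_linear_ramp_unchanged_in_interior(self):
        ramp = np.tile(np.arange(300.0)[:, None], (1, 20))
        out = smooth_surface(smap(ramp), 101, 5)     # symmetric windows
        assert np.allclose(out.t_surface[60:-60], ramp[60:-60])

    def test_spans_clamped_to_grid(self):
        m = smap(np.arange(12.0).reshape(3, 4))
        out = smooth_surface(m, 200, 10)              # clamps to 3 x 4
        assert np.isfinite(out.t_surface).all()
        one = smap(np.array([[5.0]]))
        assert smooth_surface(one, 200, 10).t_surface[0, 0] == 5.0


class TestComputeOffsets:
    def test_identical_surfaces_zero_offsets(self, small_geometry):
        d = smap(np.full((5, 4), 100.0))
        out = compute_offsets(d, d, small_geometry)
        assert np.allclose(out.dz_um, 0.0)

    def test_ten_samples_is_30um(self, small_geometry):
        d = smap(np.full((5, 4), 110.0))
        s = smap(np.full((5, 4), 100.0))
        out = compute_offsets(d, s, small_geometry)
        assert np.allclose(out.dz_um, 30.0)           # 10 / 500 MHz * 1500

    def test_shape_mismatch_rejected(self, small_geometry):
        with pytest.raises(ValueError, match="shapes differ"):
            compute_offsets(smap(np.zeros((5, 4))), smap(np.zeros((4, 5))),
                            small_geometry)

    def test_smoothed_plus_offsets_reconstructs_detected(self, small_geometry,
                                                         rng):
        g = small_geometry
        detected = smap(500.0 + rng.normal(0, 5, size=(40, 30)))
        smoothed = smooth_surface(detected)
        off = compute_offsets(detected, smoothed, g)
        back = smoothed.t_surface + off.dz_um / g.c_um_per_us * g.sampling_mhz
        assert np.allclose(back, detected.t_surface, atol=1e-9)

    def test_residual_mean_small_over_window(self, small_geometry, rng):
        # moving-average residual: windowed mean << RMS
        detected = smap(500.0 + rng.normal(0, 5, size=(300, 40)))
        smoothed = smooth_surface(detected, 200, 10)
        off = compute_offsets(detected, smoothed, small_geometry)
        inner = off.dz_um[100:200, 15:25]
        assert abs(inner.mean()) <= 0.1 * np.sqrt((off.dz_um ** 2).mean())


class TestApplyOffsets:
    def test_zero_offsets_keep_geometry(self, small_geometry):
        g = small_geometry
        fz = apply_offsets(g, OffsetMap(np.zeros((g.n_ss, g.n_fs))))
        assert np.allclose(fz, g.focal_length_um)
        assert np.allclose(apply_offsets(g, None), g.focal_length_um)

    def test_sign_convention(self, small_geometry):
        g = small_geometry
        off = OffsetMap(np.full((g.n_ss, g.n_fs), 30.0))
        fz = apply_offsets(g, off)
        # surface farther away -> focal point pulled back from the sample
        assert np.allclose(fz, g.focal_length_um - 30.0)

    def test_sanity_bound(self, small_geometry):
        g = small_geometry
        off = OffsetMap(np.full((g.n_ss, g.n_fs), 700.0))
        with pytest.raises(SuspiciousMotionError):
            apply_offsets(g, off)
        apply_offsets(g, off, sanity_bound_um=1000.0)   # configurable

    def test_geometric_vs_timeshift_equivalence(self, small_geometry):
        """Constant +30 um offset: the corrected-geometry form and the
        -dz/c time-shift form must agree on where and how strongly the
        source reconstructs.

        The forms are not voxel-identical: the time shift mis-times
        off-axis contributions by (1 - cos a)*dz (up to ~0.9 samples at
        the cone edge here), which matters for the wideband content; the
        residual voxelwise difference scales linearly with dz.
        """
        g = small_geometry
        surface = SurfaceSheet(depth_um=1050.0, melanin_absorption=0.0,
                               artifact_gain=0.0)
        ph = Phantom(surface, [SphereAbsorber((200., 200., 1250.), 20.0, 1.0)],
                     ((-100, 500), (-100, 500)))
        roi = ((100, 300), (100, 300), (1150, 1350))
        vox = (10.0, 10.0, 1.5)
        diffs = {}
        for dz in (3.0, 30.0):
            off = OffsetMap(np.full((g.n_ss, g.n_fs), dz))
            sino = simulate_sinogram(ph, g, motion=MotionTrace(off.dz_um))
            vol_geo = beamform(sino, offsets=off, voxel_um=vox, roi_um=roi)
            vol_shift = beamform(shift_sinogram(sino, off), offsets=None,
                                 voxel_um=vox, roi_um=roi)
            # identical lateral localization, axial within one voxel
            i_g = np.unravel_index(vol_geo.data.argmax(), vol_geo.shape)
            i_s = np.unravel_index(vol_shift.data.argmax(), vol_shift.shape)
            assert i_g[:2] == i_s[:2] and abs(i_g[2] - i_s[2]) <= 1
            assert (abs(vol_geo.data.max() - vol_shift.data.max())
                    <= 0.10 * vol_geo.data.max())
            diffs[dz] = (np.abs(vol_geo.data - vol_shift.data).max()
                         / vol_geo.data.max())
        assert diffs[30.0] <= 0.25
        # obliquity residual shrinks with the offset size
        assert diffs[3.0] <= 0.4 * diffs[30.0]


@pytest.fixture(scope="module")
def fitted(small_geometry):
    g = small_geometry
    surface = SurfaceSheet(depth_um=1050.0, melanin_absorption=1.0,
                           artifact_gain=0.5)
    ph = Phantom(surface=surface, absorbers=[],
                 extent_um=((-100, 500), (-100, 500)))
    dz = np.repeat(10.0 * np.sin(np.linspace(0, 4 * np.pi, g.n_ss))[:, None],
                   g.n_fs, axis=1)
    sino = simulate_sinogram(ph, g, motion=MotionTrace(dz))
    return MotionCorrection(sino, method="lowfreq").fit(), dz


class TestModelInterface:

    def test_offsets_track_injected_motion(self, fitted):
        res, dz = fitted
        c = np.corrcoef(res.offsets.dz_um.ravel(), dz.ravel())[0, 1]
        assert c >= 0.95

    def test_summary_reports_key_fields(self, fitted):
        res, _ = fitted
        text = res.summary()
        for key in ("surface method", "offset RMS", "smoothing spans",
                    "dominant motion"):
            assert key in text

    def test_corrected_focal_depths_sign(self, fitted, small_geometry):
        res, _ = fitted
        fz = res.corrected_focal_depths()
        assert np.allclose(fz, small_geometry.focal_length_um
                           - res.offsets.dz_um)

    def test_per_bscan_aggregation(self, fitted):
        res, _ = fitted
        per_b = res.offsets.per_bscan()
        assert np.all(np.ptp(per_b.dz_um, axis=1) == 0.0)

    def test_invalid_method_rejected(self, fitted):
        with pytest.raises(ValueError, match="method"):
            MotionCorrection(fitted[0].model.sinogram, method="nope")
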