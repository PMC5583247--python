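"""Delay-and-sum reconstruction, sub-band splitting, MAPs."""

import numpy as np
import pytest

from rsomotion import (BandPair, Phantom, Sinogram, SphereAbsorber,
                       SurfaceSheet, beamform, equalize_overlay, lateral_map,
                       simulate_sinogram, split_subbands, vertical_map)
from rsomotion.geometry import Volume
from rsomotion.recon import _das_numpy

ROI = ((100, 300), (100, 300), (1150, 1350))
VOX = (10.0, 10.0, 1.5)


class TestBeamform:
    def test_zero_sinogram_zero_volume(self, small_geometry):
        g = small_geometry
        sino = Sinogram(np.zeros((g.n_ss, g.n_fs, g.n_t)), g)
        vol = beamform(sino, voxel_um=VOX, roi_um=ROI)
        assert np.allclose(vol.data, 0.0)

    def test_point_source_localized_within_one_voxel(self, point_sinogram):
        vol = beamform(point_sinogram, voxel_um=VOX, roi_um=ROI)
        i = np.unravel_index(vol.data.argmax(), vol.shape)
        pos = (vol.x_axis_um()[i[0]], vol.y_axis_um()[i[1]], vol.z_axis_um()[i[2]])
        assert abs(pos[0] - 200.0) <= VOX[0]
        assert abs(pos[1] - 200.0) <= VOX[1]
        assert abs(pos[2] - 1250.0) <= 4 * VOX[2]   # envelope peak vs rim

    def test_linearity_in_sinogram(self, small_geometry):
        g = small_geometry
        surface = SurfaceSheet(depth_um=1050.0, melanin_absorption=0.0,
                               artifact_gain=0.0)
        ext = ((-100, 500), (-100, 500))
        a = SphereAbsorber((150.0, 150.0, 1250.0), 6.0, 1.0)
        b = SphereAbsorber((250.0, 250.0, 1250.0), 6.0, 1.0)
        sa = simulate_sinogram(Phantom(surface, [a], ext), g)
        sb = simulate_sinogram(Phantom(surface, [b], ext), g)
        both = sa.copy_with(sa.data + sb.data)
        va = beamform(sa, voxel_um=VOX, roi_um=ROI, envelope=False)
        vb = beamform(sb, voxel_um=VOX, roi_um=ROI, envelope=False)
        vab = beamform(both, voxel_um=VOX, roi_um=ROI, envelope=False)
        assert np.allclose(vab.data, va.data + vb.data, atol=1e-9)

    def test_lateral_grid_of_sources_all_recovered(self, small_geometry):
        g = small_geometry
        surface = SurfaceSheet(depth_um=1050.0, melanin_absorption=0.0,
                               artifact_gain=0.0)
        centers = [(150.0, 150.0), (250.0, 150.0), (150.0, 250.0),
                   (250.0, 250.0)]
        spheres = [SphereAbsorber((x, y, 1250.0), 6.0, 1.0) for x, y in centers]
        sino = simulate_sinogram(
            Phantom(surface, spheres, ((-100, 500), (-100, 500))), g)
        vol = beamform(sino, voxel_um=VOX, roi_um=ROI)
        img = lateral_map(vol, 1230.0, 1270.0)
        for x, y in centers:
            ix = int(round((x - 100) / VOX[0]))
            iy = int(round((y - 100) / VOX[1]))
            local = img[max(ix - 1, 0):ix + 2, max(iy - 1, 0):iy + 2]
            assert local.max() >= 0.8 * img.max()

    def test_numba_and_numpy_kernels_agree(self, point_sinogram,
                                           small_geometry):
        from rsomotion import _kernels

        g = small_geometry
        xv = np.arange(150.0, 250.0, 10.0)
        yv = np.arange(150.0, 250.0, 10.0)
        zv = np.arange(1200.0, 1300.0, 3.0)
        data = np.ascontiguousarray(point_sinogram.data)
        fz = np.full((g.n_ss, g.n_fs), g.focal_length_um)
        samp = g.sampling_mhz / g.c_um_per_us
        args = (data, g.x_positions_um(), g.y_positions_um(), fz,
                g.focal_length_um * samp, samp, g.tan_half_angle, xv, yv, zv)
        out_nb = np.zeros((xv.size, yv.size, zv.size))
        _kernels.das_kernel(*args, out_nb)
        out_np = np.zeros_like(out_nb)
        _das_numpy(*args, out_np)
        assert np.allclose(out_nb, out_np, rtol=1e-10, atol=1e-12)

    def test_empty_roi_rejected(self, point_sinogram):
        with pytest.raises(ValueError, match="ROI"):
            beamform(point_sinogram, voxel_um=VOX,
                     roi_um=((100, 300), (100, 300), (1350, 1150)))


class TestSubbands:
    def test_band_pair_validation(self):
        with pytest.raises(ValueError):
            BandPair(low=(20.0, 60.0), high=(70.0, 180.0))   # gap
        pair = BandPair.parse("14-42,42-126")
        assert pair.low == (14.0, 42.0) and pair.high == (42.0, 126.0)

    def test_tone_routing(self, small_geometry):
        g = small_geometry
        t = np.arange(g.n_t) / g.sampling_mhz
        bands = BandPair.rsom100()
        for f_mhz, into_low in ((30.0, True), (100.0, False)):
            cube = np.zeros((g.n_ss, g.n_fs, g.n_t))
            cube[0, 0] = np.sin(2 * np.pi * f_mhz * t)
            sino = Sinogram(cube, g)
            low, high = split_subbands(sino, bands)
            e_in = np.sum(cube ** 2)
            e_low = np.sum(low.data ** 2)
            e_high = np.sum(high.data ** 2)
            if into_low:
                assert e_low >= 0.99 * e_in and e_high <= 0.01 * e_in
            else:
                assert e_high >= 0.99 * e_in and e_low <= 0.01 * e_in

    def test_zero_in_zero_out(self, small_geometry):
        g = small_geometry
        sino = Sinogram(np.zeros((g.n_ss, g.n_fs, g.n_t)), g)
        low, high = split_subbands(sino, BandPair.rsom100())
        assert np.allclose(low.data, 0.0) and np.allclose(high.data, 0.0)

    def test_band_energies_bounded_by_total(self, small_geometry, rng):
        g = small_geometry
        sino = Sinogram(rng.normal(size=(g.n_ss, g.n_fs, g.n_t)), g)
        low, high = split_subbands(sino, BandPair.rsom100())
        total = np.sum(sino.data ** 2)
        assert np.sum(low.data ** 2) + np.sum(high.data ** 2) <= total * (1 + 1e-9)

    def test_small_spheres_dominate_high_band(self, small_geometry):
        """Two-scale phantom: 20 um spheres radiate mostly above the
        crossover, 120 um spheres below it."""
        g = small_geometry
        surface = SurfaceSheet(depth_um=1050.0, melanin_absorption=0.0,
                               artifact_gain=0.0)
        ext = ((-100, 500), (-100, 500))
        small = Phantom(surface, [SphereAbsorber((150., 150., 1250.), 20.0, 1.0)], ext)
        big = Phantom(surface, [SphereAbsorber((250., 250., 1250.), 120.0, 1.0)], ext)
        bands = BandPair.rsom100()
        ratios = {}
        for name, ph in (("small", small), ("big", big)):
            sino = simulate_sinogram(ph, g)
            low, high = split_subbands(sino, bands)
            vl = beamform(low, voxel_um=VOX, roi_um=ROI)
            vh = beamform(high, voxel_um=VOX, roi_um=ROI)
            ratios[name] = np.sum(vh.data ** 2) / np.sum(vl.data ** 2)
        # the small sphere puts a clearly larger share of its energy into
        # the high band; the margin is modest because ideal sharp-rimmed
        # spheres of any radius radiate edge harmonics across the band
        assert ratios["small"] > 1.5 * ratios["big"]


class TestOverlayAndMaps:
    def vol(self, data):
        return Volume(data=data, voxel_um=(10.0, 10.0, 2.0))

    def test_scale_invariant_equalization(self, rng):
        base = np.abs(rng.normal(size=(8, 8, 20)))
        ov = equalize_overlay(self.vol(2 * base), self.vol(base))
        assert np.allclose(ov.red.data, ov.green.data)
        assert ov.red.data.min() >= 0 and ov.red.data.max() <= 1

    def test_zero_channel_stays_zero(self, rng):
        base = np.abs(rng.normal(size=(4, 4, 6)))
        ov = equalize_overlay(self.vol(np.zeros_like(base)), self.vol(base))
        assert np.allclose(ov.red.data, 0.0)

    def test_range_clipped_to_unit_interval(self, rng):
        a = np.abs(rng.normal(size=(6, 6, 10)))
        b = np.abs(rng.normal(size=(6, 6, 10)))
        ov = equalize_overlay(self.vol(a), self.vol(b), percentile=90.0)
        for ch in (ov.red, ov.green):
            assert ch.data.min() >= 0.0 and ch.data.max() <= 1.0

    def test_single_voxel_projections(self):
        data = np.zeros((5, 6, 7))
        data[2, 3, 4] = 3.0
        v = self.vol(data)
        vm = vertical_map(v, axis="ss")              # [x][z]
        assert np.count_nonzero(vm) == 1 and vm[2, 4] == 3.0
        lm = lateral_map(v, v.z_axis_um()[3], v.z_axis_um()[5])
        assert np.count_nonzero(lm) == 1 and lm[2, 3] == 3.0
        # voxel outside the slab is absent
        lm2 = lateral_map(v, v.z_axis_um()[0], v.z_axis_um()[2])
        assert np.count_nonzero(lm2) == 0

    def test_map_homogeneity(self, rng):
        data = np.abs(rng.normal(size=(5, 6, 7)))
        v = self.vol(data)
        assert np.allclose(vertical_map(self.vol(3.0 * data)),
                           3.0 * vertical_map(v))

    def test_empty_slab_rejected(self):
        v = self.vol(np.ones((3, 3, 3)))
        with pytest.raises(ValueError, match="depth range"):
            lateral_map(v, 500.0, 600.0)
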