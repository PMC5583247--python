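"""Shared fixtures: small geometries and phantoms, all generated at
test time (no stored data)."""

from __future__ import annotations

import numpy as np
import pytest

from rsomotion import (Phantom, ScanGeometry, SphereAbsorber, SurfaceSheet,
                       simulate_sinogram)


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    """21x21 scan, short focal length, fast to simulate and beamform."""
    return ScanGeometry(n_fs=21, n_ss=21, step_um=20.0, prr_hz=500.0,
                        focal_length_um=900.0, aperture_um=818.0,
                        band_lo_mhz=20.0, band_hi_mhz=180.0, n_t=768)


@pytest.fixture(scope="session")
def point_phantom(small_geometry) -> Phantom:
    """A single small on-grid sphere below a non-absorbing surface
    (pure point-source world for delay oracles)."""
    g = small_geometry
    surface = SurfaceSheet(depth_um=g.focal_length_um + 150.0,
                           melanin_absorption=0.0, artifact_gain=0.0)
    sphere = SphereAbsorber(center_um=(200.0, 200.0, 1250.0), radius_um=6.0,
                            absorption=1.0)
    return Phantom(surface=surface, absorbers=[sphere],
                   extent_um=((-100.0, 500.0), (-100.0, 500.0)))


@pytest.fixture(scope="session")
def point_sinogram(point_phantom, small_geometry):
    return simulate_sinogram(point_phantom, small_geometry)


@pytest.fixture(scope="session")
def skin_phantom(small_geometry) -> Phantom:
    """Flat melanin surface with lens artifact plus two deep vessels."""
    g = small_geometry
    sz = g.focal_length_um + 150.0
    surface = SurfaceSheet(depth_um=sz, melanin_absorption=1.0,
                           artifact_gain=0.5, artifact_offset_um=600.0)
    absorbers = [SphereAbsorber((150.0, 150.0, sz + 500.0), 25.0, 1.0),
                 SphereAbsorber((250.0, 250.0, sz + 500.0), 25.0, 1.0)]
    return Phantom(surface=surface, absorbers=absorbers,
                   extent_um=((-100.0, 500.0), (-100.0, 500.0)))


@pytest.fixture(scope="session")
def skin_sinogram(skin_phantom, small_geometry):
    return simulate_sinogram(skin_phantom, small_geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
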