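"""Ready-made simulation set-ups (phantom + geometry + motion).

The presets state the simulated world once: scan grids and steps of the
two instrument classes, a melanin surface with the 1–3 MHz lens-artifact
footprint ~600 µm below it, capillary-loop spheres at the
epidermal-dermal-junction depth, breathing at 15 cycles/min with a few
micrometres of inter-B-scan jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import ScanGeometry
from .recon import BandPair
from .simulate import (MotionModel, Phantom, SphereAbsorber, SurfaceSheet,
                       vessel_chain)
from .spectral import default_spectra

__all__ = ["SimulationSetup", "nevus", "hairy_forearm", "vessel_grid", "get"]


@dataclass
class SimulationSetup:
    """A fully specified simulated acquisition."""

    name: str
    geometry: ScanGeometry
    phantom: Phantom
    motion: MotionModel
    bands: BandPair
    surface_z_um: float
    snr_db: float
    targets_um: list = field(default_factory=list)
    target_depth_um: float = 0.0
    wavelengths_nm: tuple = ()
    vessel_so2: float | None = None
    #: what the SNR refers to: the strongest echo overall ("global") or
    #: the echo of the target absorbers ("targets"); the melanin sheet
    #: is far stronger than any capillary, so a global reference would
    #: put the structures of interest below the noise floor
    noise_reference: str = "global"


def nevus(n_fs: int = 80, n_ss: int = 80) -> SimulationSetup:
    """High-resolution RSOM100 scan of capillary-loop targets.

    80×80 grid at Δ = 20 µm and 500 Hz PRR (12.8 s scan, ≈3.2 breathing
    cycles at 15 cycles/min); six 20 µm-radius spheres 300 µm below a
    flat melanin surface; breathing amplitude 40 µm plus 3 µm
    per-B-scan jitter.
    """
    geom = ScanGeometry.rsom100(n_fs=n_fs, n_ss=n_ss, step_um=20.0, prr_hz=500.0)
    surface_z = geom.focal_length_um + 150.0        # focus slightly above skin
    target_z = surface_z + 300.0
    lx, ly = (n_fs - 1) * geom.step_um, (n_ss - 1) * geom.step_um
    xs = [0.25 * lx, 0.5 * lx, 0.75 * lx]
    ys = [0.32 * ly, 0.68 * ly]
    targets = [(x, y, target_z) for y in ys for x in xs]
    absorbers = [SphereAbsorber(center_um=t, radius_um=20.0, absorption=1.0)
                 for t in targets]
    surface = SurfaceSheet(depth_um=surface_z, melanin_absorption=1.0,
                           artifact_gain=0.5, artifact_offset_um=600.0)
    margin = 150.0
    phantom = Phantom(surface=surface, absorbers=absorbers,
                      extent_um=((-margin, lx + margin), (-margin, ly + margin)))
    motion = MotionModel(breathing_amplitude_um=40.0, breathing_freq_hz=15.0 / 60.0,
                         jitter_sd_um=3.0, mode="per_bscan")
    return SimulationSetup(name="nevus", geometry=geom, phantom=phantom,
                           motion=motion, bands=BandPair.rsom100(),
                           surface_z_um=surface_z, snr_db=20.0,
                           targets_um=targets, target_depth_um=target_z,
                           noise_reference="targets")


def hairy_forearm(n_fs: int = 64, n_ss: int = 64) -> SimulationSetup:
    """Clinical RSOM55 scan of hairy forearm skin with dermal vessels."""
    geom = ScanGeometry.rsom55(n_fs=n_fs, n_ss=n_ss, step_um=25.0, prr_hz=1000.0)
    surface_z = geom.focal_length_um + 150.0
    lx, ly = (n_fs - 1) * geom.step_um, (n_ss - 1) * geom.step_um
    surface = SurfaceSheet(depth_um=surface_z, melanin_absorption=1.0,
                           artifact_gain=0.5, artifact_offset_um=600.0)
    target_z = surface_z + 350.0
    absorbers = vessel_chain((0.2 * lx, 0.5 * ly, target_z),
                             (0.8 * lx, 0.5 * ly, target_z),
                             radius_um=50.0, spacing_um=10.0, absorption=1.5)
    margin = 200.0
    phantom = Phantom(surface=surface, absorbers=absorbers,
                      extent_um=((-margin, lx + margin), (-margin, ly + margin)))
    motion = MotionModel(breathing_amplitude_um=40.0, breathing_freq_hz=15.0 / 60.0,
                         jitter_sd_um=3.0, mode="per_bscan")
    return SimulationSetup(name="hairy_forearm", geometry=geom, phantom=phantom,
                           motion=motion, bands=BandPair.rsom55(),
                           surface_z_um=surface_z, snr_db=30.0,
                           target_depth_um=target_z)


def vessel_grid(n_fs: int = 40, n_ss: int = 60) -> SimulationSetup:
    """Two-wavelength MSOM scan of a single dermal vessel (sO2 = 0.65)
    running along the slow axis."""
    geom = ScanGeometry.rsom55(n_fs=n_fs, n_ss=n_ss, step_um=25.0, prr_hz=1000.0)
    surface_z = geom.focal_length_um + 150.0
    lx, ly = (n_fs - 1) * geom.step_um, (n_ss - 1) * geom.step_um
    wavelengths = (560.0, 578.0)
    spectra = default_spectra().subset(wavelengths)
    so2 = 0.65
    hb_amp = {wl: (so2 * spectra.extinction["hbo2"][i]
                   + (1 - so2) * spectra.extinction["hb"][i]) / 50.0
              for i, wl in enumerate(wavelengths)}
    mel_amp = {wl: spectra.extinction["melanin"][i] / 10.0
               for i, wl in enumerate(wavelengths)}
    vessel_z = surface_z + 300.0
    absorbers = vessel_chain((0.5 * lx, -100.0, vessel_z),
                             (0.5 * lx, ly + 100.0, vessel_z),
                             radius_um=50.0, spacing_um=10.0, absorption=hb_amp)
    surface = SurfaceSheet(depth_um=surface_z, melanin_absorption=mel_amp,
                           artifact_gain=0.5, artifact_offset_um=600.0)
    margin = 200.0
    phantom = Phantom(surface=surface, absorbers=absorbers,
                      extent_um=((-margin, lx + margin), (-margin, ly + margin)))
    motion = MotionModel(breathing_amplitude_um=30.0, breathing_freq_hz=15.0 / 60.0,
                         jitter_sd_um=3.0, mode="per_bscan")
    return SimulationSetup(name="vessel_grid", geometry=geom, phantom=phantom,
                           motion=motion, bands=BandPair.rsom55(),
                           surface_z_um=surface_z, snr_db=25.0,
                           target_depth_um=vessel_z, wavelengths_nm=wavelengths,
                           vessel_so2=so2, noise_reference="targets")


_PRESETS = {"nevus": nevus, "hairy_forearm": hairy_forearm,
            "vessel_grid": vessel_grid}


def get(name: str, **kw) -> SimulationSetup:
    try:
        return _PRESETS[name](**kw)
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
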