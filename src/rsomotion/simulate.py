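"""Forward simulator of raster-scanned optoacoustic acquisition.

The imaged world is a layered skin phantom: a smooth melanin-bearing
surface sheet (discretised into point sources) above spherical absorbers
standing in for capillary loops and dermal microvessels.  Each uniformly
absorbing sphere radiates the classic bipolar N-shaped pressure pulse of
duration ``2·radius/c``; contributions are summed per scan point with a
``1/distance`` amplitude law inside the acceptance cone of the focused
detector, band-limited by the detector response, and corrupted by
vertical motion plus additive Gaussian noise.

Two deliberate deviations from a literal acoustic model, both documented
in the methods note:

* The focused detector is treated as a virtual point detector at its
  focal point, so an on-axis source at depth ``z`` arrives at ``t = z/c``.
  This makes the forward model exactly consistent with the
  virtual-detector delay-and-sum beamformer.
* The 1–3 MHz lens artifact (a one-cycle Gabor wavelet delayed by an
  extra ~600 µm) is added *after* the detector band filter, because it
  originates inside the detector and is recorded despite lying far below
  the acoustic detection band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import signal as _signal

from .filters import detector_response
from .geometry import ScanGeometry, Sinogram

__all__ = [
    "SphereAbsorber",
    "SurfaceSheet",
    "Phantom",
    "MotionModel",
    "MotionTrace",
    "nwave_pulse",
    "gabor_wavelet",
    "sample_motion",
    "simulate_sinogram",
    "vessel_chain",
]


# ---------------------------------------------------------------------------
# Phantom description
# ---------------------------------------------------------------------------

@dataclass
class SphereAbsorber:
    """Uniformly absorbing sphere (capillary-loop / microvessel stand-in).

    ``absorption`` is either a scalar amplitude (wavelength independent)
    or a mapping ``{wavelength_nm: amplitude}``.
    """

    center_um: tuple
    radius_um: float
    absorption: float | dict = 1.0

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ValueError("sphere radius must be positive")
        if self.center_um[2] <= 0:
            raise ValueError("sphere must lie below the detector plane (z > 0)")

    def absorption_at(self, wavelength_nm: float | None) -> float:
        if isinstance(self.absorption, dict):
            if wavelength_nm is None:
                raise ValueError("wavelength required for per-wavelength absorber")
            return float(self.absorption[wavelength_nm])
        return float(self.absorption)


@dataclass
class SurfaceSheet:
    """Smooth melanin-containing skin surface over the scan area.

    ``depth_um`` is the mean surface depth below the detector plane;
    ``height_fn(x, y)``, if given, adds a smooth perturbation (µm,
    positive deeper).  The sheet also carries the low-frequency lens
    artifact: a wavelet delayed by ``artifact_offset_um`` below the
    surface, with relative amplitude ``artifact_gain``.
    """

    depth_um: float
    melanin_absorption: float | dict = 1.0
    artifact_gain: float = 0.5
    artifact_offset_um: float = 600.0
    height_fn: Callable | None = None
    source_radius_um: float = 5.0

    def __post_init__(self):
        if self.depth_um <= 0:
            raise ValueError("surface depth must be positive")
        if self.artifact_offset_um < 0:
            raise ValueError("artifact offset must be >= 0")

    def height(self, x_um, y_um):
        """Surface depth (µm) at lateral position(s) (x, y)."""
        base = np.full(np.broadcast(np.asarray(x_um), np.asarray(y_um)).shape,
                       self.depth_um, dtype=float)
        if self.height_fn is not None:
            base = base + self.height_fn(np.asarray(x_um, dtype=float),
                                         np.asarray(y_um, dtype=float))
        return base

    def absorption_at(self, wavelength_nm: float | None) -> float:
        if isinstance(self.melanin_absorption, dict):
            if wavelength_nm is None:
                raise ValueError("wavelength required for per-wavelength surface")
            return float(self.melanin_absorption[wavelength_nm])
        return float(self.melanin_absorption)


@dataclass
class Phantom:
    """Surface sheet plus spherical absorbers within lateral bounds
    ``extent_um = ((x0, x1), (y0, y1))``."""

    surface: SurfaceSheet
    absorbers: list = field(default_factory=list)
    extent_um: tuple = ((0.0, 1600.0), (0.0, 1600.0))

    def validate(self):
        for a in self.absorbers:
            h = float(np.asarray(self.surface.height(a.center_um[0], a.center_um[1])))
            if a.center_um[2] <= h:
                raise ValueError(
                    f"absorber at {a.center_um} lies above the surface (z={h:.1f} um)")


def vessel_chain(p0_um: Sequence[float], p1_um: Sequence[float],
                 radius_um: float, spacing_um: float = 10.0,
                 absorption: float | dict = 1.0) -> list:
    """Straight vessel built as a chain of spheres from p0 to p1."""
    p0 = np.asarray(p0_um, dtype=float)
    p1 = np.asarray(p1_um, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.floor(length / spacing_um)) + 1, 2)
    return [SphereAbsorber(center_um=tuple(p0 + (p1 - p0) * s), radius_um=radius_um,
                           absorption=absorption)
            for s in np.linspace(0.0, 1.0, n)]


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------

@dataclass
class MotionModel:
    """Sinusoidal breathing plus random jitter of the skin surface
    relative to the detector.

    Positive offset = surface farther from the detector = later arrival.
    In ``per_bscan`` mode the sinusoid is evaluated and the jitter drawn
    once per B-scan (motion between, not within, fast-axis sweeps).
    """

    breathing_amplitude_um: float = 40.0
    breathing_freq_hz: float = 15.0 / 60.0   # 15 cycles per minute
    phase_rad: float = 0.0
    jitter_sd_um: float = 3.0
    mode: str = "per_bscan"
    seed: int | None = None

    def __post_init__(self):
        if self.breathing_amplitude_um < 0 or self.jitter_sd_um < 0:
            raise ValueError("amplitude and jitter sd must be >= 0")
        if self.breathing_freq_hz < 0:
            raise ValueError("breathing frequency must be >= 0")
        if self.mode not in ("per_bscan", "per_ascan"):
            raise ValueError("mode must be 'per_bscan' or 'per_ascan'")


@dataclass
class MotionTrace:
    """Ground-truth vertical skin displacement (µm) at the instant of
    each A-scan, indexed ``[ss][fs]``."""

    z_offset_um: np.ndarray

    def __post_init__(self):
        self.z_offset_um = np.asarray(self.z_offset_um, dtype=float)
        if self.z_offset_um.ndim != 2:
            raise ValueError("motion trace must be a 2-D [ss][fs] map")
        if not np.all(np.isfinite(self.z_offset_um)):
            raise ValueError("motion trace must be finite")

    @classmethod
    def zeros(cls, geometry: ScanGeometry) -> "MotionTrace":
        return cls(np.zeros((geometry.n_ss, geometry.n_fs)))


def sample_motion(model: MotionModel, geometry: ScanGeometry,
                  seed: int | None = None) -> MotionTrace:
    """Evaluate the motion model on the acquisition timeline.

    A-scan ``(ss, fs)`` is acquired at ``t = (ss·n_fs + fs) / PRR``; in
    ``per_bscan`` mode the B-scan start time is used for the whole sweep.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    n_ss, n_fs = geometry.n_ss, geometry.n_fs
    if model.mode == "per_bscan":
        t = (np.arange(n_ss) * n_fs) / geometry.prr_hz
        off = model.breathing_amplitude_um * np.sin(
            2 * np.pi * model.breathing_freq_hz * t + model.phase_rad)
        off = off + rng.normal(0.0, model.jitter_sd_um, size=n_ss)
        z = np.repeat(off[:, None], n_fs, axis=1)
    else:
        idx = np.arange(n_ss * n_fs).reshape(n_ss, n_fs)
        t = idx / geometry.prr_hz
        z = model.breathing_amplitude_um * np.sin(
            2 * np.pi * model.breathing_freq_hz * t + model.phase_rad)
        z = z + rng.normal(0.0, model.jitter_sd_um, size=(n_ss, n_fs))
    return MotionTrace(z_offset_um=z)


# ---------------------------------------------------------------------------
# Source waveforms
# ---------------------------------------------------------------------------

def nwave_pulse(radius_um: float, c_um_per_us: float, t_us) -> np.ndarray:
    """Analytic N-wave of a uniformly absorbing sphere.

    ``p(t) = -t / (radius/c)`` for ``|t| <= radius/c`` and zero outside:
    odd symmetric about the arrival time, leading compression peak at
    ``t = -radius/c``.
    """
    if radius_um <= 0 or c_um_per_us <= 0:
        raise ValueError("radius and speed of sound must be positive")
    t = np.asarray(t_us, dtype=float)
    tau = radius_um / c_um_per_us
    p = np.where(np.abs(t) <= tau, -t / tau, 0.0)
    return p


def _nwave_kernel(radius_um: float, c_um_per_us: float, dt_us: float) -> np.ndarray:
    """Discretised, centred N-wave kernel (odd length)."""
    tau = radius_um / c_um_per_us
    n = max(int(np.ceil(tau / dt_us)), 1)
    t = np.arange(-n, n + 1) * dt_us
    return nwave_pulse(radius_um, c_um_per_us, t)


def gabor_wavelet(f0_mhz: float, dt_us: float, n_cycles: float = 1.0) -> np.ndarray:
    """One-cycle Gabor wavelet used for the low-frequency lens artifact."""
    period = 1.0 / f0_mhz
    sigma = n_cycles * period / 2.0
    half = int(np.ceil(3.0 * sigma / dt_us))
    t = np.arange(-half, half + 1) * dt_us
    return np.sin(2 * np.pi * f0_mhz * t) * np.exp(-0.5 * (t / sigma) ** 2)


# ---------------------------------------------------------------------------
# Core forward model
# ---------------------------------------------------------------------------

def _deposit(trace: np.ndarray, a: np.ndarray, w: np.ndarray):
    """Linear-interpolation deposition of weights at fractional samples."""
    n_t = trace.shape[0]
    i0 = np.floor(a).astype(np.int64)
    frac = a - i0
    ok = (i0 >= 0) & (i0 < n_t - 1)
    if not np.any(ok):
        return
    i0, frac, w = i0[ok], frac[ok], w[ok]
    np.add.at(trace, i0, w * (1.0 - frac))
    np.add.at(trace, i0 + 1, w * frac)


def simulate_sinogram(phantom: Phantom, geometry: ScanGeometry,
                      motion: MotionTrace | None = None,
                      wavelength_nm: float | None = None,
                      noise_sd: float = 0.0,
                      seed: int | None = None,
                      surface_pitch_um: float | None = None,
                      artifact_f0_mhz: float = 2.0) -> Sinogram:
    """Simulate the full 3-D sinogram of a phantom under motion.

    The surface sheet is discretised at ``surface_pitch_um`` (default
    step/2, below the scan sampling so its wave front is continuous per
    the Huygens picture).  The per-point amplitude is normalised by the
    patch area so the result is independent of the discretisation pitch.
    """
    g = geometry
    phantom.validate()
    if motion is None:
        motion = MotionTrace.zeros(g)
    if motion.z_offset_um.shape != (g.n_ss, g.n_fs):
        raise ValueError(
            f"motion trace shape {motion.z_offset_um.shape} does not match "
            f"scan grid {(g.n_ss, g.n_fs)}")
    dz = motion.z_offset_um
    tan_half = g.tan_half_angle
    f = g.focal_length_um
    dt = g.dt_us
    samp_per_um = g.sampling_mhz / g.c_um_per_us     # samples per µm of path
    t0_samp = f * samp_per_um                        # focal time in samples

    x_s = g.x_positions_um()
    y_s = g.y_positions_um()

    # --- surface sheet discretisation -------------------------------------
    pitch = g.step_um / 2.0 if surface_pitch_um is None else surface_pitch_um
    (x0, x1), (y0, y1) = phantom.extent_um
    px = np.arange(x0, x1 + pitch / 2, pitch)
    py = np.arange(y0, y1 + pitch / 2, pitch)
    surf_amp = phantom.surface.absorption_at(wavelength_nm) * (pitch / 10.0) ** 2
    surf_z_grid = phantom.surface.height(px[None, :], py[:, None])  # [y][x]
    if float(np.min(surf_z_grid)) <= f:
        raise ValueError("surface sheet must lie below the focal plane")

    # --- sphere absorbers --------------------------------------------------
    sph_xyz = np.array([a.center_um for a in phantom.absorbers], dtype=float)
    sph_amp = np.array([a.absorption_at(wavelength_nm) for a in phantom.absorbers],
                       dtype=float)
    sph_rad = np.array([a.radius_um for a in phantom.absorbers], dtype=float)

    # accumulation cubes, one per convolution kernel
    acc_surface = np.zeros((g.n_ss, g.n_fs, g.n_t))
    acc_artifact = (np.zeros_like(acc_surface)
                    if phantom.surface.artifact_gain > 0 else None)
    unique_radii = np.unique(sph_rad) if len(sph_rad) else np.array([])
    acc_spheres = {r: np.zeros_like(acc_surface) for r in unique_radii}

    art_extra_samp = phantom.surface.artifact_offset_um * samp_per_um
    art_gain = phantom.surface.artifact_gain

    # pad the candidate window by the largest possible cone radius
    z_deep = float(np.max(surf_z_grid)) + np.max(np.abs(dz), initial=0.0) - f
    r_win = tan_half * max(z_deep, 0.0) + 2 * pitch

    for iss in range(g.n_ss):
        for ifs in range(g.n_fs):
            d = dz[iss, ifs]
            xs, ys = x_s[ifs], y_s[iss]
            # surface patch inside the acceptance cone
            jx0 = np.searchsorted(px, xs - r_win)
            jx1 = np.searchsorted(px, xs + r_win, side="right")
            jy0 = np.searchsorted(py, ys - r_win)
            jy1 = np.searchsorted(py, ys + r_win, side="right")
            if jx1 > jx0 and jy1 > jy0:
                zx = surf_z_grid[jy0:jy1, jx0:jx1] + d - f   # depth below focus
                lx = px[jx0:jx1][None, :] - xs
                ly = py[jy0:jy1][:, None] - ys
                q2 = lx * lx + ly * ly
                inside = (zx > 0) & (q2 <= (tan_half * zx) ** 2)
                if np.any(inside):
                    r = np.sqrt(q2[inside] + zx[inside] ** 2)
                    a = t0_samp + r * samp_per_um
                    w = surf_amp * f / (f + r)
                    _deposit(acc_surface[iss, ifs], a, w)
                    if acc_artifact is not None:
                        _deposit(acc_artifact[iss, ifs], a + art_extra_samp,
                                 art_gain * w)
            # spheres
            if len(sph_rad):
                zx = sph_xyz[:, 2] + d - f
                lx = sph_xyz[:, 0] - xs
                ly = sph_xyz[:, 1] - ys
                q2 = lx * lx + ly * ly
                inside = (zx > 0) & (q2 <= (tan_half * zx) ** 2)
                if np.any(inside):
                    r = np.sqrt(q2[inside] + zx[inside] ** 2)
                    a = t0_samp + r * samp_per_um
                    w = sph_amp[inside] * f / (f + r)
                    for rad in unique_radii:
                        sel = sph_rad[inside] == rad
                        if np.any(sel):
                            _deposit(acc_spheres[rad][iss, ifs], a[sel], w[sel])

    # --- convolve with source waveforms ------------------------------------
    acoustic = _convolve_t(acc_surface,
                           _nwave_kernel(phantom.surface.source_radius_um,
                                         g.c_um_per_us, dt))
    for rad, cube in acc_spheres.items():
        acoustic += _convolve_t(cube, _nwave_kernel(rad, g.c_um_per_us, dt))

    if np.any(acoustic):
        data = detector_response(acoustic, g.sampling_mhz,
                                 g.band_lo_mhz, g.band_hi_mhz)
    else:
        data = acoustic
    if acc_artifact is not None and np.any(acc_artifact):
        data = data + _convolve_t(acc_artifact, gabor_wavelet(artifact_f0_mhz, dt))

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)

    return Sinogram(data=data, geometry=g, wavelength_nm=wavelength_nm)


def _convolve_t(cube: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-mode convolution along the time axis with a centred kernel."""
    k = kernel[None, None, :]
    return _signal.oaconvolve(cube, k, mode="same", axes=-1)
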