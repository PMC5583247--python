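"""Acquisition geometry, coordinate conventions and scan kinematics.

Conventions used throughout the package
---------------------------------------
* Indices are 0-based everywhere.  A sinogram is indexed ``[ss][fs][t]``
  (slow axis outermost); a volume is indexed ``[x][y][z]`` with ``x``
  along the fast axis, ``y`` along the slow axis and ``z`` increasing
  with depth into the tissue.
* Time sample 0 coincides with the laser pulse.  Optoacoustic
  propagation is one-way (light in, sound out), so arrival time maps to
  depth as ``depth = t * c`` — *not* halved as in pulse-echo ultrasound.
* The virtual focal point of the focused detector sits at depth
  ``focal_length_um`` below the detector plane.  An on-axis source at
  depth ``z`` therefore arrives at ``t = z / c`` regardless of the
  focal length.
* Lengths are micrometres, times microseconds, frequencies MHz unless a
  suffix says otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanGeometry",
    "Sinogram",
    "Volume",
    "InvalidGeometryError",
    "compute_scan_speeds",
    "scan_duration",
    "sample_to_depth",
    "depth_to_sample",
]


class InvalidGeometryError(ValueError):
    """Raised when acquisition geometry parameters are inconsistent."""


def _default_n_t(focal_length_um: float, sampling_mhz: float,
                 c_um_per_us: float, depth_below_focus_um: float = 2000.0) -> int:
    """Number of samples covering the focus plus a tissue depth margin,
    rounded up to a multiple of 256."""
    depth = focal_length_um + depth_below_focus_um
    n = int(np.ceil(depth / c_um_per_us * sampling_mhz))
    return int(np.ceil(n / 256.0)) * 256


@dataclass(frozen=True)
class ScanGeometry:
    """Raster-scan acquisition geometry of a focused-detector RSOM system.

    Parameters
    ----------
    n_fs, n_ss : int
        Number of scan points along the fast and slow axes.
    step_um : float
        Scan step Δ between neighbouring scan points (µm), identical on
        both axes.
    prr_hz : float
        Laser pulse repetition rate (Hz); one A-scan per pulse.
    sampling_mhz : float
        Digitiser sampling rate of each A-scan (MHz).
    n_t : int
        Samples per A-scan.
    c_um_per_us : float
        Speed of sound (µm/µs).  Default 1500 (soft tissue / water).
    focal_length_um, aperture_um : float
        Focal distance and active aperture of the detector (µm).
    f_number : float, optional
        If given, must agree with ``focal_length_um / aperture_um``
        within 1 %; derived otherwise.
    band_lo_mhz, band_hi_mhz : float
        Detector detection band.
    """

    n_fs: int
    n_ss: int
    step_um: float
    prr_hz: float
    focal_length_um: float
    aperture_um: float
    band_lo_mhz: float
    band_hi_mhz: float
    sampling_mhz: float = 500.0
    n_t: int = 0
    c_um_per_us: float = 1500.0
    f_number: float = 0.0

    def __post_init__(self):
        positive = {
            "n_fs": self.n_fs, "n_ss": self.n_ss, "step_um": self.step_um,
            "prr_hz": self.prr_hz, "focal_length_um": self.focal_length_um,
            "aperture_um": self.aperture_um, "band_lo_mhz": self.band_lo_mhz,
            "band_hi_mhz": self.band_hi_mhz, "sampling_mhz": self.sampling_mhz,
            "c_um_per_us": self.c_um_per_us,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise InvalidGeometryError(f"{name} must be strictly positive, got {value!r}")
        if self.n_t == 0:
            object.__setattr__(self, "n_t", _default_n_t(
                self.focal_length_um, self.sampling_mhz, self.c_um_per_us))
        if self.n_t <= 0:
            raise InvalidGeometryError(f"n_t must be strictly positive, got {self.n_t!r}")
        derived_f = self.focal_length_um / self.aperture_um
        if self.f_number == 0.0:
            object.__setattr__(self, "f_number", derived_f)
        elif abs(self.f_number - derived_f) > 0.01 * derived_f:
            raise InvalidGeometryError(
                f"f_number {self.f_number} inconsistent with focal_length/aperture "
                f"= {derived_f:.4g} (must agree within 1%)")
        if self.band_lo_mhz >= self.band_hi_mhz:
            raise InvalidGeometryError("band_lo_mhz must be below band_hi_mhz")
        if self.band_hi_mhz >= self.sampling_mhz / 2:
            raise InvalidGeometryError("detection band exceeds Nyquist frequency")

    # -- derived quantities -------------------------------------------------
    @property
    def l_fs_um(self) -> float:
        """Fast-axis extent l_fs = n_fs * Δ."""
        return self.n_fs * self.step_um

    @property
    def l_ss_um(self) -> float:
        return self.n_ss * self.step_um

    @property
    def dt_us(self) -> float:
        return 1.0 / self.sampling_mhz

    @property
    def tan_half_angle(self) -> float:
        """Tangent of the acceptance-cone half angle, aperture/(2·focal)."""
        return self.aperture_um / (2.0 * self.focal_length_um)

    @property
    def focal_time_us(self) -> float:
        return self.focal_length_um / self.c_um_per_us

    @property
    def max_depth_um(self) -> float:
        """Depth reached by the last time sample."""
        return sample_to_depth(self.n_t - 1, self)

    def x_positions_um(self) -> np.ndarray:
        """Fast-axis scan positions (length n_fs)."""
        return np.arange(self.n_fs) * self.step_um

    def y_positions_um(self) -> np.ndarray:
        """Slow-axis scan positions (length n_ss)."""
        return np.arange(self.n_ss) * self.step_um

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})

    # -- instrument presets -------------------------------------------------
    @classmethod
    def rsom100(cls, n_fs: int = 80, n_ss: int = 80, step_um: float = 20.0,
                prr_hz: float = 500.0, **kw) -> "ScanGeometry":
        """High-frequency set-up: 20–180 MHz band, 1.5 mm aperture, f/1.1."""
        kw.setdefault("focal_length_um", 1650.0)
        kw.setdefault("aperture_um", 1500.0)
        kw.setdefault("band_lo_mhz", 20.0)
        kw.setdefault("band_hi_mhz", 180.0)
        return cls(n_fs=n_fs, n_ss=n_ss, step_um=step_um, prr_hz=prr_hz, **kw)

    @classmethod
    def rsom55(cls, n_fs: int = 80, n_ss: int = 80, step_um: float = 25.0,
               prr_hz: float = 1000.0, **kw) -> "ScanGeometry":
        """Clinical set-up: 14–126 MHz band, 3 mm aperture, f/1.0."""
        kw.setdefault("focal_length_um", 3000.0)
        kw.setdefault("aperture_um", 3000.0)
        kw.setdefault("band_lo_mhz", 14.0)
        kw.setdefault("band_hi_mhz", 126.0)
        return cls(n_fs=n_fs, n_ss=n_ss, step_um=step_um, prr_hz=prr_hz, **kw)


@dataclass
class Sinogram:
    """Raw acquisition cube: one A-scan per raster scan point.

    ``data`` is indexed ``[ss][fs][t]``; a B-scan is one ``[fs][t]``
    slice.
    """

    data: np.ndarray
    geometry: ScanGeometry
    wavelength_nm: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        expected = (self.geometry.n_ss, self.geometry.n_fs, self.geometry.n_t)
        if self.data.shape != expected:
            raise ValueError(f"sinogram shape {self.data.shape} != geometry {expected}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def bscan(self, ss: int) -> np.ndarray:
        return self.data[ss]

    def copy_with(self, data: np.ndarray) -> "Sinogram":
        return Sinogram(data=data, geometry=self.geometry,
                        wavelength_nm=self.wavelength_nm)


@dataclass
class Volume:
    """Reconstructed absorption volume R(x_i, y_j, z_k).

    ``data`` is indexed ``[x][y][z]`` (x fast axis, y slow axis, z depth,
    downward positive); ``origin_um`` locates voxel (0, 0, 0) in scan
    coordinates.
    """

    data: np.ndarray
    voxel_um: tuple
    origin_um: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D")
        if len(self.voxel_um) != 3 or any(v <= 0 for v in self.voxel_um):
            raise ValueError("voxel_um must be three positive spacings")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def x_axis_um(self) -> np.ndarray:
        return self.origin_um[0] + np.arange(self.shape[0]) * self.voxel_um[0]

    def y_axis_um(self) -> np.ndarray:
        return self.origin_um[1] + np.arange(self.shape[1]) * self.voxel_um[1]

    def z_axis_um(self) -> np.ndarray:
        return self.origin_um[2] + np.arange(self.shape[2]) * self.voxel_um[2]

    def copy_with(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, voxel_um=self.voxel_um, origin_um=self.origin_um)


# ---------------------------------------------------------------------------
# Scan kinematics
# ---------------------------------------------------------------------------

def compute_scan_speeds(geometry: ScanGeometry) -> tuple[float, float]:
    """Acquisition speeds along the two scan axes, in mm/s.

    The detector advances one step Δ per laser pulse along the fast
    axis, so ``v_fs = PRR · Δ``; one slow-axis step is taken per
    fast-axis sweep, giving ``v_ss = v_fs · Δ / l_fs``.
    """
    v_fs_mm_s = geometry.prr_hz * geometry.step_um * 1e-3
    v_ss_mm_s = v_fs_mm_s * geometry.step_um / geometry.l_fs_um
    return v_fs_mm_s, v_ss_mm_s


def scan_duration(geometry: ScanGeometry, n_wavelengths: int = 1) -> float:
    """Total scan time in seconds: one pulse per scan point per wavelength."""
    if n_wavelengths < 1:
        raise ValueError("n_wavelengths must be >= 1")
    return geometry.n_fs * geometry.n_ss * n_wavelengths / geometry.prr_hz


def sample_to_depth(sample_index, geometry: ScanGeometry):
    """Map a (fractional) time-sample index to one-way depth in µm.

    Optoacoustic propagation is one way; the time of flight is *not*
    halved as in pulse-echo imaging.
    """
    return np.asarray(sample_index) / geometry.sampling_mhz * geometry.c_um_per_us


def depth_to_sample(depth_um, geometry: ScanGeometry):
    """Inverse of :func:`sample_to_depth` (fractional samples)."""
    return np.asarray(depth_um) / geometry.c_um_per_us * geometry.sampling_mhz
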