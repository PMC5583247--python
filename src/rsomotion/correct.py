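"""Smoothed synthetic surface, per-scan-point offsets, and their
application to the acquisition geometry.

The estimator is a moving-average residual: the detected (motion
corrupted) surface minus its 200×10-pixel moving average is the vertical
skin displacement at each scan point.  Positive offset = surface farther
from the detector = later arrival; the correction displaces the virtual
focal point *away from the sample* by the same amount during
reconstruction (equivalently, advances the A-scan by ``dz/c``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import ScanGeometry, Sinogram
from .surface import SurfaceMap

__all__ = [
    "OffsetMap",
    "SuspiciousMotionError",
    "smooth_surface",
    "compute_offsets",
    "apply_offsets",
    "shift_sinogram",
]


class SuspiciousMotionError(ValueError):
    """Offset magnitude exceeds the configured sanity bound."""


@dataclass
class OffsetMap:
    """Vertical displacement map ``dz_um[ss][fs]`` (µm), positive =
    surface farther from the detector than the smooth reference."""

    dz_um: np.ndarray

    def __post_init__(self):
        self.dz_um = np.asarray(self.dz_um, dtype=float)
        if self.dz_um.ndim != 2:
            raise ValueError("offset map must be 2-D [ss][fs]")
        if not np.all(np.isfinite(self.dz_um)):
            raise ValueError("offset map must be finite")

    @property
    def shape(self) -> tuple:
        return self.dz_um.shape

    def rms_um(self) -> float:
        return float(np.sqrt(np.mean(self.dz_um ** 2)))

    def per_bscan(self) -> "OffsetMap":
        """Aggregate to one offset per B-scan (median along the fast axis)."""
        med = np.median(self.dz_um, axis=1, keepdims=True)
        return OffsetMap(np.repeat(med, self.dz_um.shape[1], axis=1))


def _clamp_span(span: int, dim: int) -> int:
    """Clamp a moving-average span to the map dimension."""
    return max(int(min(span, dim)), 1)


def smooth_surface(surface: SurfaceMap, span_ss: int = 200, span_fs: int = 10,
                   edge_mode: str = "reflect") -> SurfaceMap:
    """Artificial smooth surface: separable uniform moving average.

    Default spans are 200 pixels along the slow axis and 10 along the
    fast axis (the spans that perform best on clinical scans); spans
    larger than the grid are clamped to it.  Even spans are honoured
    as given (the window then extends half a pixel further towards
    smaller indices, scipy's convention).  Reflective edge padding
    avoids offset bias at the scan borders, where the breathing phase
    is arbitrary.
    """
    t = surface.t_surface
    s_ss = _clamp_span(span_ss, t.shape[0])
    s_fs = _clamp_span(span_fs, t.shape[1])
    smooth = ndimage.uniform_filter(t, size=(s_ss, s_fs), mode=edge_mode)
    return SurfaceMap(t_surface=smooth, method=surface.method,
                      confidence=surface.confidence)


def compute_offsets(detected: SurfaceMap, smoothed: SurfaceMap,
                    geometry: ScanGeometry) -> OffsetMap:
    """Offsets dz (µm) = (detected − smoothed arrival time) · c / f_s.

    One-way time-of-flight conversion; see :mod:`rsomotion.geometry`.
    """
    if detected.shape != smoothed.shape:
        raise ValueError(
            f"surface map shapes differ: {detected.shape} vs {smoothed.shape}")
    dt_samples = detected.t_surface - smoothed.t_surface
    dz = dt_samples / geometry.sampling_mhz * geometry.c_um_per_us
    return OffsetMap(dz_um=dz)


def apply_offsets(geometry: ScanGeometry, offsets: OffsetMap | None,
                  sanity_bound_um: float = 500.0) -> np.ndarray:
    """Per-scan-point corrected focal depth (µm), shape ``[ss][fs]``.

    A positive offset means the skin moved away from the detector; the
    reconstruction compensates by pulling the virtual focal point back by
    the same amount: ``focal_z = focal_length − dz``.  This is exact for
    the forward model (shifting all sources by +dz equals shifting the
    focus by −dz).
    """
    f = geometry.focal_length_um
    if offsets is None:
        return np.full((geometry.n_ss, geometry.n_fs), f)
    if offsets.shape != (geometry.n_ss, geometry.n_fs):
        raise ValueError(
            f"offset map shape {offsets.shape} does not match scan grid "
            f"{(geometry.n_ss, geometry.n_fs)}")
    peak = float(np.max(np.abs(offsets.dz_um)))
    if peak > sanity_bound_um:
        raise SuspiciousMotionError(
            f"offset magnitude {peak:.1f} um exceeds sanity bound "
            f"{sanity_bound_um:.1f} um")
    return f - offsets.dz_um


def shift_sinogram(sinogram: Sinogram, offsets: OffsetMap,
                   sanity_bound_um: float = 500.0) -> Sinogram:
    """Alternate correction: advance each A-scan by ``dz/c``.

    Sub-sample shifts use frequency-domain phase ramps, which preserve
    the wideband content better than linear interpolation.  Agrees with
    the corrected-geometry form for spatially uniform offsets (the
    geometric form additionally captures the small obliquity term for
    off-axis contributions).
    """
    g = sinogram.geometry
    if offsets.shape != (g.n_ss, g.n_fs):
        raise ValueError("offset map does not match the scan grid")
    peak = float(np.max(np.abs(offsets.dz_um)))
    if peak > sanity_bound_um:
        raise SuspiciousMotionError(
            f"offset magnitude {peak:.1f} um exceeds sanity bound "
            f"{sanity_bound_um:.1f} um")
    shift_samples = offsets.dz_um / g.c_um_per_us * g.sampling_mhz
    n_t = g.n_t
    freqs = np.fft.rfftfreq(n_t)                     # cycles per sample
    spec = np.fft.rfft(sinogram.data, axis=-1)
    # advance by dz/c: s'(t) = s(t + dz/c)
    ramp = np.exp(2j * np.pi * freqs[None, None, :] * shift_samples[..., None])
    data = np.fft.irfft(spec * ramp, n=n_t, axis=-1)
    return sinogram.copy_with(data)
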