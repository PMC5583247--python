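"""Model/Results interface tying the correction pipeline together.

``MotionCorrection`` is constructed from a sinogram, ``fit()`` runs
surface detection, moving-average smoothing and offset estimation, and
returns a ``MotionCorrectionResults`` carrying the estimates, their
diagnostics, a ``summary()`` table, and methods to apply the correction
(corrected geometry for beamforming, or a time-shifted sinogram).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correct import OffsetMap, apply_offsets, compute_offsets, shift_sinogram, smooth_surface
from .geometry import Sinogram
from .surface import SurfaceMap, detect_surface_hairless, detect_surface_lowfreq

__all__ = ["MotionCorrection", "MotionCorrectionResults"]


class MotionCorrection:
    """Estimate per-scan-point vertical motion offsets from a sinogram.

    Parameters
    ----------
    sinogram : Sinogram
    method : {'lowfreq', 'hairless'}
        Surface-detection regime: the 1–3 MHz lens-artifact footprint
        (hairy skin) or the parabolic-slab stratum-corneum echo
        (hairless skin).
    span_ss, span_fs : int
        Moving-average spans of the synthetic smooth surface (pixels
        along the slow / fast axis).
    per_bscan : bool
        Aggregate offsets to one value per B-scan (median along the
        fast axis).  Default False: offsets are estimated per A-scan.

    Examples
    --------
    >>> res = MotionCorrection(sino, method="lowfreq").fit()
    >>> print(res.summary())
    >>> vol = beamform(sino, offsets=res.offsets)
    """

    def __init__(self, sinogram: Sinogram, method: str = "lowfreq",
                 span_ss: int = 200, span_fs: int = 10,
                 slab_half_samples: int = 50, window_us: float = 2.0,
                 per_bscan: bool = False, sanity_bound_um: float = 500.0):
        if method not in ("lowfreq", "hairless"):
            raise ValueError("method must be 'lowfreq' or 'hairless'")
        self.sinogram = sinogram
        self.method = method
        self.span_ss = span_ss
        self.span_fs = span_fs
        self.slab_half_samples = slab_half_samples
        self.window_us = window_us
        self.per_bscan = per_bscan
        self.sanity_bound_um = sanity_bound_um

    def fit(self) -> "MotionCorrectionResults":
        if self.method == "hairless":
            detected = detect_surface_hairless(
                self.sinogram, slab_half_samples=self.slab_half_samples)
        else:
            detected = detect_surface_lowfreq(
                self.sinogram, window_us=self.window_us)
        smoothed = smooth_surface(detected, span_ss=self.span_ss,
                                  span_fs=self.span_fs)
        offsets = compute_offsets(detected, smoothed, self.sinogram.geometry)
        if self.per_bscan:
            offsets = offsets.per_bscan()
        return MotionCorrectionResults(model=self, surface_detected=detected,
                                       surface_smooth=smoothed, offsets=offsets)


@dataclass
class MotionCorrectionResults:
    """Fitted motion estimate with diagnostics."""

    model: MotionCorrection
    surface_detected: SurfaceMap
    surface_smooth: SurfaceMap
    offsets: OffsetMap

    # -- diagnostics --------------------------------------------------------
    @property
    def rms_offset_um(self) -> float:
        return self.offsets.rms_um()

    @property
    def peak_to_peak_um(self) -> float:
        return float(np.ptp(self.offsets.dz_um))

    def breathing_cycles_per_min(self) -> float:
        """Dominant motion frequency, from the per-B-scan median offset
        series on the acquisition timeline."""
        g = self.model.sinogram.geometry
        series = np.median(self.offsets.dz_um, axis=1)
        series = series - series.mean()
        if np.allclose(series, 0):
            return 0.0
        spec = np.abs(np.fft.rfft(series))
        spec[0] = 0.0
        k = int(np.argmax(spec))
        bscan_rate_hz = g.prr_hz / g.n_fs
        return k / series.size * bscan_rate_hz * 60.0

    # -- applying the correction -------------------------------------------
    def corrected_focal_depths(self) -> np.ndarray:
        """Per-scan-point focal z for offset-corrected beamforming."""
        return apply_offsets(self.model.sinogram.geometry, self.offsets,
                             sanity_bound_um=self.model.sanity_bound_um)

    def corrected_sinogram(self) -> Sinogram:
        """Alternate form: A-scans advanced by dz/c (band-limited shift)."""
        return shift_sinogram(self.model.sinogram, self.offsets,
                              sanity_bound_um=self.model.sanity_bound_um)

    def summary(self) -> str:
        g = self.model.sinogram.geometry
        dz = self.offsets.dz_um
        samp_um = g.c_um_per_us / g.sampling_mhz
        lines = [
            "Motion correction results",
            "=" * 45,
            f"surface method     : {self.surface_detected.method}",
            f"scan grid          : {g.n_ss} (ss) x {g.n_fs} (fs), step {g.step_um:g} um",
            f"smoothing spans    : {self.model.span_ss} (ss) x {self.model.span_fs} (fs) px",
            f"offset RMS         : {self.rms_offset_um:8.2f} um "
            f"({self.rms_offset_um / samp_um:.2f} samples)",
            f"offset peak-to-peak: {self.peak_to_peak_um:8.2f} um",
            f"offset mean        : {float(dz.mean()):8.3f} um",
            f"dominant motion    : {self.breathing_cycles_per_min():8.1f} cycles/min",
            "=" * 45,
        ]
        return "\n".join(lines)

    def plot_surfaces(self, ax=None):
        """Detected vs. smoothed surface along the slow axis (median
        over the fast axis), in µm depth."""
        import matplotlib.pyplot as plt

        g = self.model.sinogram.geometry
        if ax is None:
            _, ax = plt.subplots()
        scale = g.c_um_per_us / g.sampling_mhz
        y = g.y_positions_um()
        ax.plot(y, np.median(self.surface_detected.t_surface, axis=1) * scale,
                label="detected")
        ax.plot(y, np.median(self.surface_smooth.t_surface, axis=1) * scale,
                label="smoothed")
        ax.set_xlabel("slow axis position (um)")
        ax.set_ylabel("surface depth (um)")
        ax.invert_yaxis()
        ax.legend()
        return ax
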