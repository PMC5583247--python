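"""Zero-phase band filters and envelope detection for A-scan data.

All filters act along the last (time) axis and are zero phase, so they
never displace the arrival times that the surface tracker and the
beamformer rely on.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "exponential_bandpass",
    "exponential_band_window",
    "butter_bandpass",
    "detector_response",
    "envelope",
]


def exponential_band_window(freqs_mhz: np.ndarray, f_lo_mhz: float,
                            f_hi_mhz: float, rolloff_mhz: float) -> np.ndarray:
    """Frequency-domain window: unity inside [f_lo, f_hi], exponential
    skirts ``exp(-(f_lo - f)/rolloff)`` below and ``exp(-(f - f_hi)/rolloff)``
    above."""
    f = np.asarray(freqs_mhz, dtype=float)
    w = np.ones_like(f)
    below = f < f_lo_mhz
    above = f > f_hi_mhz
    w[below] = np.exp(-(f_lo_mhz - f[below]) / rolloff_mhz)
    w[above] = np.exp(-(f[above] - f_hi_mhz) / rolloff_mhz)
    return w


def exponential_bandpass(traces: np.ndarray, sampling_mhz: float,
                         f_lo_mhz: float = 1.0, f_hi_mhz: float = 3.0,
                         rolloff_mhz: float = 0.5) -> np.ndarray:
    """Exponential bandpass used to isolate the low-frequency lens
    artifact (1–3 MHz by default).

    The window is applied to the real FFT of each trace, which makes the
    filter exactly zero phase.
    """
    if not (0 < f_lo_mhz < f_hi_mhz):
        raise ValueError("need 0 < f_lo < f_hi")
    if f_hi_mhz >= sampling_mhz / 2:
        raise ValueError("f_hi exceeds the Nyquist frequency")
    if rolloff_mhz <= 0:
        raise ValueError("rolloff must be positive")
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_mhz)
    w = exponential_band_window(freqs, f_lo_mhz, f_hi_mhz, rolloff_mhz)
    return np.fft.irfft(np.fft.rfft(traces, axis=-1) * w, n=n, axis=-1)


def butter_bandpass(traces: np.ndarray, sampling_mhz: float,
                    f_lo_mhz: float, f_hi_mhz: float, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward filtering)."""
    nyq = sampling_mhz / 2.0
    if not (0 < f_lo_mhz < f_hi_mhz < nyq):
        raise ValueError(
            f"band ({f_lo_mhz}, {f_hi_mhz}) MHz invalid for Nyquist {nyq} MHz")
    sos = signal.butter(order, [f_lo_mhz / nyq, f_hi_mhz / nyq],
                        btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, np.asarray(traces, dtype=float), axis=-1)


def detector_response(traces: np.ndarray, sampling_mhz: float,
                      band_lo_mhz: float, band_hi_mhz: float) -> np.ndarray:
    """Detector band limitation: linear, zero phase, DC-free, with
    passband gain within 1 dB of unity and |H| <= 1 everywhere (so output
    energy never exceeds input energy)."""
    return butter_bandpass(traces, sampling_mhz, band_lo_mhz, band_hi_mhz, order=3)


def envelope(traces: np.ndarray, axis: int = -1) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert envelope)."""
    return np.abs(signal.hilbert(np.asarray(traces, dtype=float), axis=axis))
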