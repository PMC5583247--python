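"""Multi-wavelength unmixing, vessel segmentation and oxygen-saturation
profiling.

Per-voxel non-negative least squares solves
``amplitude(λ) ≈ Σ_c ε_c(λ) · q_c`` for chromophore amounts ``q_c ≥ 0``;
oxygen saturation is ``sO2 = HbO2 / (HbO2 + Hb)``.  A vessel is
segmented by thresholding a reconstructed cuboid at 20 % of its maximum
(strictly greater than), and sO2 is averaged across the vessel diameter
slice by slice along the vessel axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .geometry import Volume

__all__ = [
    "ChromophoreSpectra",
    "ComponentVolumes",
    "VesselMask",
    "OxyProfile",
    "default_spectra",
    "unmix_chromophores",
    "compute_so2",
    "segment_vessel",
    "so2_along_vessel",
]


@dataclass
class ChromophoreSpectra:
    """Extinction coefficients per chromophore per wavelength.

    ``extinction`` maps chromophore name -> array aligned with
    ``wavelengths_nm``.  Units are arbitrary but must be common across
    chromophores; only ratios matter for unmixing.
    """

    wavelengths_nm: tuple
    extinction: dict

    def __post_init__(self):
        n = len(self.wavelengths_nm)
        self.extinction = {k: np.asarray(v, dtype=float)
                           for k, v in self.extinction.items()}
        for name, eps in self.extinction.items():
            if eps.shape != (n,):
                raise ValueError(f"extinction for {name!r} must have length {n}")
            if np.any(eps <= 0):
                raise ValueError(f"extinction for {name!r} must be strictly positive")
        # a table may carry more chromophores than wavelengths; the
        # wavelengths >= chromophores requirement applies at unmixing time

    def subset(self, wavelengths_nm) -> "ChromophoreSpectra":
        idx = [self.wavelengths_nm.index(w) for w in wavelengths_nm]
        return ChromophoreSpectra(
            wavelengths_nm=tuple(wavelengths_nm),
            extinction={k: v[idx] for k, v in self.extinction.items()})

    def matrix(self, chromophores) -> np.ndarray:
        """(n_wavelengths, n_chromophores) extinction matrix."""
        return np.column_stack([self.extinction[c] for c in chromophores])


def default_spectra() -> ChromophoreSpectra:
    """SYNTHETIC reference spectra (stand-in fixture).

    Representative *shapes* of oxy-/deoxy-hemoglobin and melanin
    extinction in the visible/NIR, adequate for simulation and testing.
    They are inputs to the pipeline, not authoritative optical
    constants; replace with a measured table for quantitative work.
    """
    wl = (532.0, 545.0, 560.0, 578.0, 650.0, 750.0, 850.0)
    return ChromophoreSpectra(
        wavelengths_nm=wl,
        extinction={
            # arbitrary common units; ratios follow the familiar
            # isosbestic/crossover structure of hemoglobin
            "hbo2":    np.array([44.5, 52.1, 32.6, 64.5, 0.37, 0.52, 1.06]),
            "hb":      np.array([40.1, 49.8, 53.8, 37.0, 3.75, 1.41, 0.78]),
            "melanin": np.array([11.0, 10.2, 9.4, 8.5, 5.2, 3.1, 1.9]),
        })


@dataclass
class ComponentVolumes:
    """Unmixed chromophore amplitude volumes (non-negative)."""

    hbo2: Volume
    hb: Volume
    melanin: Volume | None = None
    residual: Volume | None = None

    def total_hemoglobin(self) -> Volume:
        return self.hbo2.copy_with(self.hbo2.data + self.hb.data)


@dataclass
class VesselMask:
    """Binary segmentation cuboid; 1 = vessel voxel."""

    seg: np.ndarray

    def __post_init__(self):
        self.seg = np.asarray(self.seg)
        if not np.isin(self.seg, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        if not self.seg.any():
            raise ValueError("vessel mask is empty")


@dataclass
class OxyProfile:
    """Mean oxygen saturation per slice along the vessel axis.

    ``valid`` is False where the mask slice is empty (sO2 undefined,
    never interpolated).
    """

    y_um: np.ndarray
    so2: np.ndarray
    valid: np.ndarray

    def peak_to_peak(self) -> float:
        v = self.so2[self.valid]
        if v.size == 0:
            raise ValueError("no valid slices in profile")
        return float(v.max() - v.min())


# ---------------------------------------------------------------------------
# Unmixing
# ---------------------------------------------------------------------------

def _nnls_two(E: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact vectorised NNLS for two chromophores.

    The 2-variable NNLS optimum is either the unconstrained solution (if
    feasible) or the best of the two single-axis projections; all
    candidates are evaluated and the feasible one with minimal residual
    chosen per voxel.
    """
    G = E.T @ E
    b = E.T @ Y                                   # (2, n_vox)
    det = G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]
    x0 = (G[1, 1] * b[0] - G[0, 1] * b[1]) / det
    x1 = (G[0, 0] * b[1] - G[1, 0] * b[0]) / det
    interior = np.stack([x0, x1])
    edge0 = np.stack([np.maximum(b[0] / G[0, 0], 0.0), np.zeros_like(x0)])
    edge1 = np.stack([np.zeros_like(x0), np.maximum(b[1] / G[1, 1], 0.0)])

    def sse(x):
        r = Y - E @ x
        return np.sum(r * r, axis=0)

    out = np.where((interior >= 0).all(axis=0), interior,
                   np.where(sse(edge0) <= sse(edge1), edge0, edge1))
    return out


def unmix_chromophores(volumes_per_wavelength: dict,
                       spectra: ChromophoreSpectra,
                       chromophores: tuple = ("hbo2", "hb")) -> ComponentVolumes:
    """Per-voxel non-negative least-squares spectral unmixing.

    Parameters
    ----------
    volumes_per_wavelength : dict
        ``{wavelength_nm: Volume}`` of co-registered (motion-corrected)
        reconstructions.
    """
    wavelengths = sorted(volumes_per_wavelength)
    vols = [volumes_per_wavelength[w] for w in wavelengths]
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape:
            raise ValueError("per-wavelength volumes must be co-registered")
    if len(wavelengths) < len(chromophores):
        raise ValueError("need at least as many wavelengths as chromophores")
    E = spectra.subset(wavelengths).matrix(chromophores)
    if np.linalg.matrix_rank(E) < len(chromophores):
        raise ValueError("rank-deficient extinction matrix")

    Y = np.stack([v.data.ravel() for v in vols])   # (n_wl, n_vox)
    if len(chromophores) == 2:
        X = _nnls_two(E, Y)
    else:
        X = np.empty((len(chromophores), Y.shape[1]))
        for i in range(Y.shape[1]):
            X[:, i], _ = optimize.nnls(E, Y[:, i])
    resid = np.sqrt(np.sum((Y - E @ X) ** 2, axis=0)).reshape(ref.shape)

    def vol(i):
        return ref.copy_with(X[i].reshape(ref.shape))

    named = dict(zip(chromophores, range(len(chromophores))))
    return ComponentVolumes(
        hbo2=vol(named["hbo2"]),
        hb=vol(named["hb"]),
        melanin=vol(named["melanin"]) if "melanin" in named else None,
        residual=ref.copy_with(resid))


def compute_so2(hbo2_volume: Volume, hb_volume: Volume,
                epsilon: float = 1e-12) -> tuple[Volume, np.ndarray]:
    """Voxel-wise oxygen saturation HbO2/(HbO2+Hb).

    Returns the sO2 volume and a boolean validity mask; voxels with
    total hemoglobin ≤ ``epsilon`` are invalid (sO2 set to 0 there).
    """
    if hbo2_volume.shape != hb_volume.shape:
        raise ValueError("hemoglobin volumes must share dimensions")
    total = hbo2_volume.data + hb_volume.data
    valid = total > epsilon
    so2 = np.zeros_like(total)
    np.divide(hbo2_volume.data, total, out=so2, where=valid)
    return hbo2_volume.copy_with(so2), valid


def segment_vessel(cuboid: Volume) -> VesselMask:
    """Threshold a vessel cuboid at 20 % of its maximum amplitude.

    A voxel belongs to the vessel iff its amplitude is strictly greater
    than ``0.2 · max`` (Heaviside of amplitude − 0.2·max)."""
    m = float(cuboid.data.max())
    if m <= 0:
        raise ValueError("cannot segment an all-zero cuboid")
    return VesselMask(seg=(cuboid.data > 0.2 * m).astype(np.uint8))


def so2_along_vessel(mask: VesselMask, so2_volume: Volume,
                     valid: np.ndarray | None = None,
                     axis: int = 1) -> OxyProfile:
    """Mean sO2 across the vessel diameter, slice by slice along
    ``axis`` (default y, the slow axis).

    Each slice average weights voxels by the binary mask only; slices
    with an empty mask are flagged invalid.
    """
    if mask.seg.shape != so2_volume.shape:
        raise ValueError("mask and volume dimensions differ")
    seg = mask.seg.astype(float)
    if valid is not None:
        seg = seg * valid
    other = tuple(i for i in range(3) if i != axis)
    num = np.sum(seg * so2_volume.data, axis=other)
    den = np.sum(seg, axis=other)
    ok = den > 0
    so2 = np.zeros_like(num)
    np.divide(num, den, out=so2, where=ok)
    pos = (so2_volume.origin_um[axis]
           + np.arange(so2_volume.shape[axis]) * so2_volume.voxel_um[axis])
    return OxyProfile(y_um=pos, so2=so2, valid=ok)
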