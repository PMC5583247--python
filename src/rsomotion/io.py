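"""File formats: HDF5 sinogram/volume containers, TIFF/CSV maps, YAML
configuration.

The sinogram container is self-describing: the dataset ``sinogram``
(float32, chunked by B-scan) carries every :class:`ScanGeometry` field
as an HDF5 attribute, plus the excitation wavelength and, for simulated
data, the ground-truth motion trace.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import ScanGeometry, Sinogram, Volume
from .simulate import MotionTrace
from .surface import SurfaceMap

__all__ = [
    "FormatError",
    "write_sinogram",
    "read_sinogram",
    "write_volume",
    "read_volume",
    "write_map_tiff",
    "write_map_csv",
    "write_rgb_tiff",
    "load_config",
    "geometry_from_config",
]


class FormatError(ValueError):
    """A container is missing a mandatory attribute or is malformed."""


_GEOMETRY_FIELDS = [f.name for f in dataclasses.fields(ScanGeometry)]


def write_sinogram(path, sinogram: Sinogram,
                   motion: MotionTrace | None = None,
                   extras: dict | None = None) -> None:
    """Write a sinogram with full geometry metadata (lossless float32)."""
    g = sinogram.geometry
    with h5py.File(path, "w") as h5:
        dset = h5.create_dataset("sinogram",
                                 data=sinogram.data.astype(np.float32),
                                 chunks=(1, g.n_fs, g.n_t))
        for name in _GEOMETRY_FIELDS:
            dset.attrs[name] = getattr(g, name)
        if sinogram.wavelength_nm is not None:
            dset.attrs["wavelength_nm"] = sinogram.wavelength_nm
        if motion is not None:
            h5.create_dataset("motion/z_offset_um", data=motion.z_offset_um)
        for key, value in (extras or {}).items():
            h5.attrs[key] = value


def read_sinogram(path) -> tuple[Sinogram, MotionTrace | None]:
    """Read a sinogram container; returns (sinogram, ground-truth
    motion or None).  Raises :class:`FormatError` naming any missing
    geometry attribute."""
    with h5py.File(path, "r") as h5:
        if "sinogram" not in h5:
            raise FormatError("container has no 'sinogram' dataset")
        dset = h5["sinogram"]
        attrs = {}
        for name in _GEOMETRY_FIELDS:
            if name not in dset.attrs:
                raise FormatError(f"container missing mandatory attribute {name!r}")
            value = dset.attrs[name]
            attrs[name] = int(value) if name in ("n_fs", "n_ss", "n_t") else float(value)
        geometry = ScanGeometry(**attrs)
        wavelength = dset.attrs.get("wavelength_nm")
        data = np.asarray(dset[...], dtype=np.float64)
        motion = None
        if "motion/z_offset_um" in h5:
            motion = MotionTrace(np.asarray(h5["motion/z_offset_um"][...]))
    sino = Sinogram(data=data, geometry=geometry,
                    wavelength_nm=None if wavelength is None else float(wavelength))
    return sino, motion


def write_volume(path, volume: Volume, tiff_path=None) -> None:
    """HDF5 volume (float32) plus an optional multi-page TIFF mirror
    (one page per depth plane)."""
    with h5py.File(path, "w") as h5:
        dset = h5.create_dataset("volume", data=volume.data.astype(np.float32))
        dset.attrs["voxel_um"] = np.asarray(volume.voxel_um, dtype=float)
        dset.attrs["origin_um"] = np.asarray(volume.origin_um, dtype=float)
    if tiff_path is not None:
        pages = np.moveaxis(volume.data.astype(np.float32), 2, 0)
        tifffile.imwrite(tiff_path, pages)


def read_volume(path) -> Volume:
    with h5py.File(path, "r") as h5:
        if "volume" not in h5:
            raise FormatError("container has no 'volume' dataset")
        dset = h5["volume"]
        return Volume(data=np.asarray(dset[...], dtype=float),
                      voxel_um=tuple(dset.attrs["voxel_um"]),
                      origin_um=tuple(dset.attrs["origin_um"]))


def write_map_tiff(path, map_2d: np.ndarray) -> None:
    """Single-page float32 TIFF of a 2-D map (surface, offsets, MAPs)."""
    tifffile.imwrite(path, np.asarray(map_2d, dtype=np.float32))


def write_map_csv(path, map_2d: np.ndarray) -> None:
    pd.DataFrame(np.asarray(map_2d)).to_csv(path, index=False, header=False,
                                            float_format="%.6g")


def write_rgb_tiff(path, rgb: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(rgb, dtype=np.uint8))


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config must be a YAML mapping")
    return cfg


def geometry_from_config(cfg: dict) -> ScanGeometry:
    """Build a geometry from a YAML ``geometry:`` block with field
    names identical to :class:`ScanGeometry`."""
    block = cfg.get("geometry", cfg)
    try:
        return ScanGeometry.from_dict(block)
    except TypeError as exc:
        raise FormatError(f"invalid geometry config: {exc}") from exc


def export_surface_map(stem: Path, surface: SurfaceMap) -> None:
    write_map_tiff(str(stem) + ".tif", surface.t_surface)
    write_map_csv(str(stem) + ".csv", surface.t_surface)
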