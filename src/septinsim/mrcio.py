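"""Minimal MRC2014 I/O plus sidecar text formats (.tlt angle files,
YAML metadata).

Only mode 2 (float32) single-volume / stack files are produced, with
the voxel size recorded in the cell dimensions, which is all this
pipeline needs; a full-featured MRC library is deliberately not a
dependency of the runtime environment.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import yaml

from .phantom import DensityVolume, GridParams
from .tiltsim import GeometryMode, OpticsParams, TiltSeries

__all__ = [
    "write_mrc",
    "read_mrc",
    "write_tlt",
    "read_tlt",
    "save_volume",
    "load_volume",
    "save_tilt_series",
    "load_tilt_series",
]

_HEADER_SIZE = 1024
_MODE_FLOAT32 = 2


def write_mrc(path, data: np.ndarray, voxel_size: float = 1.0,
              is_stack: bool = False) -> None:
    """Write a 2D image, 3D volume or image stack as MRC mode 2."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    nz, ny, nx = data.shape
    mz = 1 if is_stack else nz
    cella_z = (mz if is_stack else nz) * voxel_size

    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, _MODE_FLOAT32)
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # nxstart/nystart/nzstart
    struct.pack_into("<3i", header, 28, nx, ny, mz)
    struct.pack_into(
        "<3f", header, 40, nx * voxel_size, ny * voxel_size, cella_z
    )
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76,
        float(data.min()), float(data.max()), float(data.mean()),
    )
    struct.pack_into("<i", header, 88, 0 if is_stack else 1)  # ispg
    struct.pack_into("<i", header, 92, 0)  # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))  # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    struct.pack_into("<i", header, 220, 0)  # nlabl

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC file; returns (data as (nz, ny, nx) float array,
    voxel size in Å from the cell/sampling ratio)."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise ValueError(f"truncated MRC header in {path}")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        xlen, ylen, zlen = struct.unpack_from("<3f", header, 40)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        dtype = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}.get(
            mode
        )
        if dtype is None:
            raise ValueError(f"unsupported MRC mode {mode}")
        fh.seek(_HEADER_SIZE + nsymbt)
        data = np.frombuffer(
            fh.read(nx * ny * nz * np.dtype(dtype).itemsize), dtype=dtype
        ).reshape(nz, ny, nx)
    voxel = xlen / mx if mx else 1.0
    return np.array(data, dtype=np.float32), float(voxel)


def write_tlt(path, angles) -> None:
    """One tilt angle per line (IMOD .tlt dialect)."""
    Path(path).write_text(
        "".join(f"{a:8.2f}\n" for a in angles)
    )


def read_tlt(path) -> tuple[float, ...]:
    return tuple(
        float(ln) for ln in Path(path).read_text().split() if ln.strip()
    )


def save_volume(path, volume: DensityVolume) -> None:
    write_mrc(path, volume.values, volume.grid.voxel_size)


def load_volume(path) -> DensityVolume:
    data, voxel = read_mrc(path)
    return DensityVolume(GridParams(data.shape, voxel), data)


def save_tilt_series(prefix, series: TiltSeries) -> None:
    """Write <prefix>.mrc (stack), <prefix>.tlt and <prefix>.yaml."""
    prefix = Path(prefix)
    write_mrc(prefix.with_suffix(".mrc"), series.images,
              series.pixel_size, is_stack=True)
    write_tlt(prefix.with_suffix(".tlt"), series.angles)
    meta = {
        "pixel_size": float(series.pixel_size),
        "geometry": series.geometry.value,
        "snr": "inf" if np.isinf(series.snr) else float(series.snr),
        "seed": int(series.seed),
        "optics": None,
        "meta": series.meta,
    }
    if series.optics is not None:
        meta["optics"] = {
            "voltage": series.optics.voltage,
            "defocus": series.optics.defocus,
            "spherical_aberration": series.optics.spherical_aberration,
            "amplitude_contrast": series.optics.amplitude_contrast,
        }
    prefix.with_suffix(".yaml").write_text(
        yaml.safe_dump(meta, sort_keys=False)
    )


def load_tilt_series(prefix) -> TiltSeries:
    prefix = Path(prefix)
    images, voxel = read_mrc(prefix.with_suffix(".mrc"))
    angles = read_tlt(prefix.with_suffix(".tlt"))
    meta_path = prefix.with_suffix(".yaml")
    geometry = GeometryMode.PERPENDICULAR_TO_TILT_AXIS
    optics = None
    snr, seed, extra = float("inf"), 0, {}
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        voxel = meta.get("pixel_size", voxel)
        geometry = GeometryMode(meta.get("geometry", geometry.value))
        snr = meta.get("snr", "inf")
        snr = float("inf") if snr == "inf" else float(snr)
        seed = int(meta.get("seed", 0))
        extra = meta.get("meta") or {}
        if meta.get("optics"):
            optics = OpticsParams(**meta["optics"])
    return TiltSeries(images, angles, voxel, geometry, optics, snr, seed,
                      meta=extra)
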