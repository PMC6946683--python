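"""Minimal MRC2014 volume I/O (numpy-only).

Writes and reads the subset of the MRC2014 format needed for label volumes:
mode 0 (int8) or mode 2 (float32), single volume, voxel size in the cell
header.  Axis order on disk is the MRC convention (sections, rows, columns)
which matches the package's (nz, ny, nx) arrays.
"""

from __future__ import annotations

import struct

import numpy as np

from .datatypes import LabeledVolume
from .exceptions import ParameterError

__all__ = ["write_mrc", "read_mrc"]

_MODE_FOR_DTYPE = {np.dtype(np.int8): 0, np.dtype(np.float32): 2}
_DTYPE_FOR_MODE = {0: np.int8, 1: np.int16, 2: np.float32}


def write_mrc(path, volume: LabeledVolume) -> None:
    """Write a labeled volume as MRC2014 (mode 0 for uint8/int8 labels)."""
    data = volume.data
    if data.dtype == np.uint8:
        data = data.astype(np.int8)
    if data.dtype not in _MODE_FOR_DTYPE:
        data = data.astype(np.float32)
    mode = _MODE_FOR_DTYPE[data.dtype]
    nz, ny, nx = data.shape
    vs = volume.voxel_size
    header = bytearray(1024)
    struct.pack_into("<3i", header, 0, nx, ny, nz)  # NX NY NZ
    struct.pack_into("<i", header, 12, mode)  # MODE
    struct.pack_into("<3i", header, 16, 0, 0, 0)  # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # MX MY MZ
    struct.pack_into("<3f", header, 40, nx * vs, ny * vs, nz * vs)  # CELLA (A~nm)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<2i", header, 88, 0, 0)  # ISPG, NSYMBT
    struct.pack_into("<3f", header, 196, *volume.origin.astype(float))  # ORIGIN
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(data).tobytes())


def read_mrc(path) -> LabeledVolume:
    """Read an MRC2014 volume written by :func:`write_mrc` (modes 0/1/2)."""
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024 or header[208:212] != b"MAP ":
            raise ParameterError(f"{path}: not an MRC2014 file")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        if mode not in _DTYPE_FOR_MODE:
            raise ParameterError(f"{path}: unsupported MRC mode {mode}")
        mx = struct.unpack_from("<3i", header, 28)[0]
        cella = struct.unpack_from("<3f", header, 40)
        voxel = cella[0] / mx if mx else 1.0
        origin = np.array(struct.unpack_from("<3f", header, 196))
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        fh.seek(1024 + nsymbt)
        dtype = np.dtype(_DTYPE_FOR_MODE[mode]).newbyteorder("<")
        data = np.frombuffer(fh.read(), dtype=dtype, count=nx * ny * nz)
    data = data.reshape(nz, ny, nx)
    if mode == 0:
        data = data.astype(np.uint8)
    return LabeledVolume(
        data=np.array(data), voxel_size=float(voxel), origin=origin, meta={}
    )
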