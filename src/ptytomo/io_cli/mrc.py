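"""Minimal MRC2014 reader/writer.

Supports modes 0 (int8), 1 (int16), 2 (float32) and 6 (uint16),
little-endian, no extended header on write. Volumes are stored
(sections, rows, columns) = numpy (z, y, x) with the voxel size (nm)
carried in the cell dimensions (MRC cells are in angstroms).
"""

from __future__ import annotations

import struct

import numpy as np

_HEADER_BYTES = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


class MrcParseError(ValueError):
    pass


def write_mrc(path, data: np.ndarray, voxel_size_nm: float = 1.0) -> None:
    """Write a 2D image or 3D volume as a float32 MRC2014 file."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise MrcParseError("data must be 2D or 3D")
    nz, ny, nx = data.shape
    data32 = np.ascontiguousarray(data, dtype="<f4")
    cell = (nx * voxel_size_nm * 10.0, ny * voxel_size_nm * 10.0,
            nz * voxel_size_nm * 10.0)
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<10i", header, 0, nx, ny, nz, 2, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<6f", header, 40, *cell, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)
    struct.pack_into("<3f", header, 76, float(data32.min()),
                     float(data32.max()), float(data32.mean()))
    struct.pack_into("<2i", header, 88, 0, 0)     # ispg, nsymbt
    struct.pack_into("<3f", header, 196, 0.0, 0.0, 0.0)  # origin
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])  # little-endian machst
    struct.pack_into("<f", header, 216, float(data32.std()))
    struct.pack_into("<i", header, 220, 0)        # nlabl
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data32.tobytes())


def read_mrc(path) -> tuple[np.ndarray, float]:
    """Read an MRC file; returns (data as (z, y, x) float array,
    voxel size in nm)."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_BYTES)
        if len(header) < _HEADER_BYTES:
            raise MrcParseError("truncated MRC header")
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise MrcParseError("bad MRC header: missing MAP magic (word 53)")
        if mode not in _MODE_DTYPES:
            raise MrcParseError(f"bad MRC header: unsupported mode {mode}")
        if min(nx, ny, nz) < 1:
            raise MrcParseError(
                f"bad MRC header: non-positive dimensions nx={nx} ny={ny} nz={nz}")
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        if nsymbt:
            fh.seek(nsymbt, 1)
        dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
        count = nx * ny * nz
        raw = fh.read(count * dtype.itemsize)
        if len(raw) < count * dtype.itemsize:
            raise MrcParseError("truncated MRC data section")
        data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx)
    voxel_nm = cella[0] / mx / 10.0 if mx else 1.0
    return data.astype(np.float64), float(voxel_nm)
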