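"""MRC/CCP4 map I/O (float32, mode 2) and tab-separated tables.

On disk the MRC fastest axis (columns) is x, rows are y and sections z,
with the helical axis on z.  In memory volumes are numpy ``(z, y, x)``
arrays (:class:`helixforge.synthgen.DensityVolume`); segment stacks are
stored as one section per image.
"""

from __future__ import annotations

import os
import struct


import gemmi
import numpy as np
import pandas as pd

from .synthgen import DensityVolume, SegmentStack

__all__ = [
    "write_mrc",
    "read_mrc_volume",
    "write_stack",
    "read_stack",
    "write_table",
    "read_table",
]

_HEADER_BYTES = 1024
_MODE_SIZES = {0: 1, 1: 2, 2: 4, 6: 2}


class MRCParseError(ValueError):
    pass


def _validate_mrc(path: str) -> tuple[int, int, int, int]:
    """Pre-validate header and file size; returns (nx, ny, nz, mode)."""
    size = os.path.getsize(path)
    if size < _HEADER_BYTES:
        raise MRCParseError(
            f"{path}: file is {size} bytes, shorter than the {_HEADER_BYTES}-byte MRC header"
        )
    with open(path, "rb") as fh:
        head = fh.read(16)
    nx, ny, nz, mode = struct.unpack("<4i", head)
    if mode not in _MODE_SIZES:
        raise MRCParseError(f"{path}: unsupported MRC mode {mode} (byte offset 12)")
    if min(nx, ny, nz) <= 0 or max(nx, ny, nz) > 100000:
        raise MRCParseError(f"{path}: implausible dimensions {nx}x{ny}x{nz} (byte offset 0)")
    expected = _HEADER_BYTES + nx * ny * nz * _MODE_SIZES[mode]
    if size < expected:
        raise MRCParseError(
            f"{path}: truncated at byte {size}, expected at least {expected} "
            f"({nx}x{ny}x{nz} mode {mode})"
        )
    return nx, ny, nz, mode


def _to_gemmi(data_zyx: np.ndarray, voxel: float) -> gemmi.Ccp4Map:
    # gemmi's FloatGrid takes the numpy array with axis 0 fastest on disk,
    # so hand it (x, y, z) to make x the MRC column axis
    arr = np.ascontiguousarray(data_zyx.transpose(2, 1, 0).astype(np.float32))
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    nx, ny, nz = arr.shape
    m.grid.unit_cell = gemmi.UnitCell(nx * voxel, ny * voxel, nz * voxel, 90, 90, 90)
    m.update_ccp4_header()
    return m


def write_mrc(volume: DensityVolume, path: str) -> None:
    """Write a volume as a float32 (mode 2) MRC map, voxel size in the
    cell parameters."""
    _to_gemmi(volume.grid, volume.voxel).write_ccp4_map(str(path))


def read_mrc_volume(path: str) -> DensityVolume:
    """Read an MRC/CCP4 map as a DensityVolume (z, y, x)."""
    _validate_mrc(str(path))
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True)
    voxel = m.grid.unit_cell.a / m.grid.nu
    return DensityVolume(arr.transpose(2, 1, 0).astype(np.float64), voxel)


def write_stack(stack: SegmentStack, path: str, table_path: str | None = None) -> None:
    """Write segments as an MRC stack (one section per image) plus the
    per-segment metadata table next to it (``<path>.tsv`` by default)."""
    data = stack.images.astype(np.float32)  # (M, B, B) sections on z
    _to_gemmi(data, stack.pixel).write_ccp4_map(str(path))
    write_table(stack.records, table_path or str(path) + ".tsv")


def read_stack(path: str, table_path: str | None = None) -> SegmentStack:
    _validate_mrc(str(path))
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True).transpose(2, 1, 0)
    pixel = m.grid.unit_cell.a / m.grid.nu
    tp = table_path or str(path) + ".tsv"
    if os.path.exists(tp):
        records = read_table(tp)
    else:
        records = pd.DataFrame({"filament": np.zeros(len(arr), dtype=int),
                                "segment": np.arange(len(arr))})
    return SegmentStack(arr.astype(np.float32), pixel, records)


def write_table(df: pd.DataFrame, path: str) -> None:
    """Tab-separated table with a commented header line."""
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_table(path: str) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing commented header line")
        cols = header[1:].strip().split("\t")
    df = pd.read_csv(path, sep="\t", comment="#", names=cols)
    return df
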