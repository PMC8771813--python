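"""Delimited-text input/output for point clouds.

Point clouds travel as plain delimited text: one row per point, comma or
tab separated, with an optional single header row.  The boundary
convention is not stored in the file; callers declare it when reading.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .geometry import PointCloud

__all__ = ["read_point_cloud", "write_point_cloud"]


def _sniff_delimiter(sample: str) -> str:
    first = sample.splitlines()[0] if sample else ""
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return r"\s+"


def read_point_cloud(
    path: Union[str, Path],
    boundary: str = "hard",
    delimiter: Optional[str] = None,
    label: Optional[str] = None,
) -> PointCloud:
    """Read a delimited-text point cloud (optional single header row).

    The delimiter is sniffed from the first line when not given; a header
    row is detected by non-numeric content in the first line.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty point-cloud file")
    sep = delimiter if delimiter is not None else _sniff_delimiter(text)
    first_line = text.lstrip().splitlines()[0]
    probe = pd.read_csv(_io.StringIO(first_line), sep=sep, header=None)
    has_header = probe.dtypes.apply(lambda t: t == object).any()
    frame = pd.read_csv(
        _io.StringIO(text), sep=sep, header=0 if has_header else None
    )
    coords = frame.to_numpy(dtype=float)
    return PointCloud(coords, boundary=boundary, label=label or str(path))


def write_point_cloud(
    cloud: PointCloud, path: Union[str, Path], delimiter: str = ",",
    header: bool = False,
) -> None:
    """Write a point cloud as delimited text, one row per point."""
    if header:
        cols = delimiter.join(f"x{i}" for i in range(cloud.m))
        np.savetxt(path, cloud.coords, delimiter=delimiter, header=cols, comments="")
    else:
        np.savetxt(path, cloud.coords, delimiter=delimiter)
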